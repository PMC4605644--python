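"""Sample QC, batch centering and variance-stabilizing normalization.

The fixed pipeline order is: outlier filtering on raw per-sample medians
(two-sided Tukey fences), per-batch centering on the healthy-control medians,
then a robust arsinh calibration ("vsn"-style generalized-log normalization).
A classical-MDS view on Spearman rank-correlation distance is provided for
visual QC of batch and group structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import rankdata


@dataclass
class VsnFit:
    """Per-sample affine calibration h_ij = arsinh(a_i + b_i * x_ij)."""

    sample_ids: list[str]
    offsets: np.ndarray  # a_i
    scales: np.ndarray  # b_i > 0
    converged: bool
    iterations: int


def flag_outlier_samples(matrix: pd.DataFrame) -> pd.Series:
    """Flag samples whose median intensity falls outside the Tukey fences
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of the per-sample median distribution.

    Quartiles use linear interpolation between order statistics. Requires at
    least 4 samples, otherwise the fences are undefined.
    """
    if matrix.shape[1] < 4:
        raise ValueError("outlier fences undefined for fewer than 4 samples")
    medians = matrix.median(axis=0)
    q1, q3 = np.percentile(medians.to_numpy(), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = (medians < lo) | (medians > hi)
    flags.name = "qc_outlier"
    return flags


def drop_flagged(matrix: pd.DataFrame, sheet: pd.DataFrame, flags: pd.Series):
    """Remove flagged samples from matrix and sheet."""
    keep = [s for s in matrix.columns if not flags.get(s, False)]
    sheet2 = sheet[sheet["sample_id"].isin(keep)].reset_index(drop=True)
    return matrix[keep], sheet2


def batch_center(
    matrix: pd.DataFrame, sheet: pd.DataFrame, control_group: str = "HC"
) -> pd.DataFrame:
    """Center each batch on its healthy-control medians, feature-wise.

    For batch b and feature j the median over that batch's control samples is
    subtracted from every sample of the batch, so the per-feature control
    median becomes 0 in every batch. Errors if a batch has no controls.
    """
    out = matrix.copy()
    sheet_idx = sheet.set_index("sample_id")
    for batch, sub in sheet.groupby("batch"):
        batch_samples = [s for s in matrix.columns if s in set(sub["sample_id"])]
        hc = [s for s in batch_samples if sheet_idx.loc[s, "group"] == control_group]
        if not hc:
            raise ValueError(f"batch {batch!r} contains no {control_group} samples")
        med = matrix[hc].median(axis=1)
        out[batch_samples] = matrix[batch_samples].sub(med, axis=0)
    out.attrs["stage"] = "centered"
    return out


def _profile_negll_and_grad(theta, X, row_mask):
    """Profile negative log-likelihood of the calibration model and its
    gradient with respect to theta = (a_1..a_n, log b_1..log b_n).

    Model: arsinh(a_i + b_i x_ij) = mu_j + Normal(0, c^2); the feature means
    mu_j and the variance c^2 are profiled out analytically, leaving

        F = (N P / 2) log RSS  -  sum_ij [ log b_i - 0.5 log(1 + z_ij^2) ]

    with z_ij = a_i + b_i x_ij. The Jacobian sum is what pins the calibration
    to the variance-stabilizing scale. ``row_mask`` restricts the RSS to the
    untrimmed features (the Jacobian always uses all of them, so trimming
    does not bias the scale).
    """
    p, n = X.shape
    a = theta[:n]
    log_b = np.clip(theta[n:], -50.0, 50.0)
    b = np.exp(log_b)
    Z = a[None, :] + X * b[None, :]
    H = np.arcsinh(Z)
    Hm = H[row_mask]
    R = Hm - Hm.mean(axis=1, keepdims=True)
    rss = float(np.sum(R * R))
    rss = max(rss, 1e-300)
    n_used = int(row_mask.sum()) * n
    dh_dz = 1.0 / np.sqrt(1.0 + Z * Z)
    # dF/dz for the RSS part (row-mean terms cancel: residuals sum to 0 per row)
    coef = n_used / (2.0 * rss)
    dF_dz = np.zeros_like(Z)
    dF_dz[row_mask] = coef * 2.0 * R * dh_dz[row_mask]
    # Jacobian part: -0.5 d log(1+z^2)/dz = -z/(1+z^2), with sign flipped into F
    dF_dz += Z / (1.0 + Z * Z)
    grad_a = dF_dz.sum(axis=0)
    grad_logb = (dF_dz * X).sum(axis=0) * b - p
    F = (n_used / 2.0) * np.log(rss) - float(np.sum(log_b)) * p + 0.5 * float(
        np.sum(np.log1p(Z * Z))
    )
    return F, np.concatenate([grad_a, grad_logb])


def vsn_normalize(
    matrix: pd.DataFrame,
    trim_frac: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 50,
):
    """Robust affine-calibration / generalized-log normalization.

    Fits per-sample calibrations (a_i, b_i) of the model
    arsinh(a_i + b_i * x_ij) = mu_j + Normal(0, c^2) by minimizing the
    profile likelihood (feature means and variance profiled out) with
    L-BFGS, then once re-fits with the 10% of features with the largest
    residuals trimmed (least-trimmed-squares robustness). The transform is
    strictly increasing in x for every sample; under additive-plus-
    multiplicative noise the likelihood's Jacobian term drives b_i toward
    the scale that makes the transformed variance intensity-independent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    from scipy.optimize import minimize

    X = matrix.to_numpy(dtype=float)
    p, n = X.shape

    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0) * 1.4826
    mad = np.where(mad > 0, mad, 1.0)
    theta0 = np.concatenate([-med / mad, -np.log(mad)])

    mask = np.ones(p, dtype=bool)
    res = minimize(
        _profile_negll_and_grad, theta0, args=(X, mask), jac=True,
        method="L-BFGS-B", options={"maxiter": max_iter * 20, "ftol": tol * 1e-3},
    )
    # LTS step: drop the features worst explained by the first fit, refit
    a1, b1 = res.x[:n], np.exp(res.x[n:])
    H = np.arcsinh(a1[None, :] + X * b1[None, :])
    row_res = np.sum((H - H.mean(axis=1, keepdims=True)) ** 2, axis=1)
    k = max(2, int(np.ceil((1 - trim_frac) * p)))
    mask = np.zeros(p, dtype=bool)
    mask[np.argsort(row_res)[:k]] = True
    res = minimize(
        _profile_negll_and_grad, res.x, args=(X, mask), jac=True,
        method="L-BFGS-B", options={"maxiter": max_iter * 20, "ftol": tol * 1e-3},
    )
    converged = bool(res.success)
    it = int(res.nit)
    a, log_b = res.x[:n], res.x[n:]
    if not converged:
        import warnings

        warnings.warn("vsn calibration did not converge; returning best iterate")

    b = np.exp(log_b)
    H = np.arcsinh(a + b * X)
    out = pd.DataFrame(H, index=matrix.index, columns=matrix.columns)
    out.attrs["stage"] = "normalized"
    fit = VsnFit(
        sample_ids=list(matrix.columns),
        offsets=a,
        scales=b,
        converged=converged,
        iterations=it,
    )
    return out, fit


def spearman_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise d(s, t) = 1 - Spearman rho between sample columns."""
    X = matrix.to_numpy(dtype=float)
    for i, s in enumerate(matrix.columns):
        if np.all(X[:, i] == X[0, i]):
            raise ValueError(f"sample {s!r} is constant; rank correlation undefined")
    R = np.apply_along_axis(rankdata, 0, X)
    R = R - R.mean(axis=0)
    norms = np.sqrt((R**2).sum(axis=0))
    rho = (R.T @ R) / np.outer(norms, norms)
    return 1.0 - rho


def mds_coordinates(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Spearman correlation distance."""
    if matrix.shape[1] < 3:
        raise ValueError("MDS requires at least 3 samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = spearman_distance_matrix(matrix)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    return pd.DataFrame(
        coords, index=matrix.columns, columns=[f"dim{i+1}" for i in range(k)]
    )


def preprocess_pipeline(
    matrix: pd.DataFrame, sheet: pd.DataFrame, control_group: str = "HC"
):
    """Full preprocessing: QC filter -> batch centering -> normalization.

    Returns (normalized matrix, filtered sheet with qc flags, VsnFit, qc report).
    """
    flags = flag_outlier_samples(matrix)
    kept_matrix, kept_sheet = drop_flagged(matrix, sheet, flags)
    kept_sheet = kept_sheet.assign(qc_outlier=False)
    centered = batch_center(kept_matrix, kept_sheet, control_group=control_group)
    normalized, fit = vsn_normalize(centered)
    report = {
        "n_input_samples": int(matrix.shape[1]),
        "n_retained_samples": int(kept_matrix.shape[1]),
        "flagged_samples": sorted(flags.index[flags].tolist()),
        "vsn_converged": bool(fit.converged),
        "vsn_iterations": int(fit.iterations),
    }
    return normalized, kept_sheet, fit, report
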