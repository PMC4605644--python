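"""Linear hinge-loss classifiers with sparsity-inducing penalties.

Fits the regularized soft-margin problem

    min_{beta0, beta}  sum_i max(0, 1 - y_i (beta . x_i - beta0)) + p(beta)

for five penalties: ridge ``lam * ||beta||_2^2``, LASSO ``lam * ||beta||_1``,
elastic net ``lam1 * ||beta||_1 + lam2 * ||beta||_2^2``, SCAD (smoothly
clipped absolute deviation) and elastic SCAD (SCAD plus a ridge term).

SCAD is the quadratic spline

    p(b) = lam*|b|                              for |b| <= lam
         = (2*a*lam*|b| - b^2 - lam^2)/(2(a-1)) for lam < |b| <= a*lam
         = (a+1)*lam^2/2                        for |b| > a*lam

with shape constant ``a > 2`` (default 3.7). It penalizes small coefficients
like the LASSO (hence exact zeros / feature selection) but applies a constant
penalty to large coefficients, giving approximately unbiased sparse fits.

Convex problems (ridge/LASSO/elastic net) are solved by accelerated proximal
gradient (FISTA) on a Huber-smoothed hinge; the non-convex SCAD variants use a
local linear approximation (LLA) outer loop of reweighted-L1 subproblems
started from the elastic-net solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_SINGLE_PARAM_KINDS = ("ridge", "lasso", "scad")
_TWO_PARAM_KINDS = ("elasticnet", "elasticscad")
KINDS = _SINGLE_PARAM_KINDS + _TWO_PARAM_KINDS

ZERO_TOL = 1e-8


class PenaltyError(ValueError):
    """Invalid penalty specification."""


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty kind plus its tuning parameters.

    ``lam`` is used by single-parameter kinds (ridge, lasso, scad);
    ``lam1``/``lam2`` by two-parameter kinds (elasticnet, elasticscad).
    ``a`` is the SCAD shape constant (must exceed 2).
    """

    kind: str
    lam: float | None = None
    lam1: float | None = None
    lam2: float | None = None
    a: float = 3.7

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise PenaltyError(f"unknown penalty kind {self.kind!r}")
        if self.kind in _SINGLE_PARAM_KINDS:
            if self.lam is None or self.lam < 0:
                raise PenaltyError(f"kind {self.kind!r} requires lam >= 0")
        else:
            if self.lam1 is None or self.lam1 < 0:
                raise PenaltyError(f"kind {self.kind!r} requires lam1 >= 0")
            if self.lam2 is None or self.lam2 < 0:
                raise PenaltyError(f"kind {self.kind!r} requires lam2 >= 0")
        if self.kind in ("scad", "elasticscad") and not self.a > 2:
            raise PenaltyError("SCAD shape constant a must be > 2")

    @property
    def l1(self) -> float:
        """L1-type parameter (lam for single-parameter kinds, lam1 otherwise)."""
        return float(self.lam if self.kind in _SINGLE_PARAM_KINDS else self.lam1)

    @property
    def l2(self) -> float:
        """Ridge parameter (0 for kinds without one)."""
        if self.kind == "ridge":
            return float(self.lam)
        if self.kind in _TWO_PARAM_KINDS:
            return float(self.lam2)
        return 0.0


@dataclass
class LinearSVMModel:
    """Fitted linear decision rule f(x) = beta . x - beta0.

    Weights are on the standardized feature scale; ``feature_means`` and
    ``feature_scales`` store the training-split standardization so that
    ``decision_scores`` accepts raw-scale inputs.
    """

    weights: np.ndarray
    intercept: float
    penalty: PenaltySpec
    feature_ids: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    objective: float
    n_iter: int = 0
    converged: bool = True

    @property
    def selected_features(self) -> list[str]:
        mask = np.abs(self.weights) > ZERO_TOL
        return [f for f, m in zip(self.feature_ids, mask) if m]

    @property
    def n_selected(self) -> int:
        return int(np.sum(np.abs(self.weights) > ZERO_TOL))

    def to_dict(self) -> dict:
        return {
            "penalty": {
                "kind": self.penalty.kind,
                "lam": self.penalty.lam,
                "lam1": self.penalty.lam1,
                "lam2": self.penalty.lam2,
                "a": self.penalty.a,
            },
            "weights": {f: float(w) for f, w in zip(self.feature_ids, self.weights)},
            "intercept": float(self.intercept),
            "feature_means": {f: float(m) for f, m in zip(self.feature_ids, self.feature_means)},
            "feature_scales": {f: float(s) for f, s in zip(self.feature_ids, self.feature_scales)},
            "objective": float(self.objective),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSVMModel":
        p = d["penalty"]
        spec = PenaltySpec(kind=p["kind"], lam=p["lam"], lam1=p["lam1"], lam2=p["lam2"], a=p["a"])
        fids = list(d["weights"].keys())
        return cls(
            weights=np.array([d["weights"][f] for f in fids]),
            intercept=float(d["intercept"]),
            penalty=spec,
            feature_ids=fids,
            feature_means=np.array([d["feature_means"][f] for f in fids]),
            feature_scales=np.array([d["feature_scales"][f] for f in fids]),
            objective=float(d["objective"]),
        )


def hinge_loss(y, f):
    """Margin-violation cost max(0, 1 - y*f) for labels y in {-1, +1}."""
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be in {-1, +1}")
    return np.maximum(0.0, 1.0 - y * np.asarray(f, dtype=float))


def scad_penalty(beta, lam: float, a: float = 3.7):
    """Per-coefficient SCAD spline, summed over coefficients."""
    b = np.abs(np.asarray(beta, dtype=float))
    inner = b <= lam
    mid = (b > lam) & (b <= a * lam)
    out = np.where(
        inner,
        lam * b,
        np.where(mid, (2 * a * lam * b - b**2 - lam**2) / (2 * (a - 1)), (a + 1) * lam**2 / 2),
    )
    return float(np.sum(out))


def penalty_value(spec: PenaltySpec, beta) -> float:
    """Value of the penalty function at beta."""
    b = np.asarray(beta, dtype=float)
    if spec.kind == "ridge":
        return float(spec.lam * np.sum(b**2))
    if spec.kind == "lasso":
        return float(spec.lam * np.sum(np.abs(b)))
    if spec.kind == "elasticnet":
        return float(spec.lam1 * np.sum(np.abs(b)) + spec.lam2 * np.sum(b**2))
    if spec.kind == "scad":
        return scad_penalty(b, spec.lam, spec.a)
    # elastic SCAD
    return scad_penalty(b, spec.lam1, spec.a) + float(spec.lam2 * np.sum(b**2))


def scad_derivative(beta_abs, lam: float, a: float = 3.7):
    """d/d|b| of the SCAD spline (the LLA reweighting weights)."""
    b = np.asarray(beta_abs, dtype=float)
    return np.where(b <= lam, lam, np.maximum(a * lam - b, 0.0) / (a - 1))


def decision_scores(model: LinearSVMModel, X) -> np.ndarray:
    """Decision values f(x) = beta . x_std - beta0 on raw-scale inputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: model has {model.weights.shape[0]}, X has {X.shape[1]}"
        )
    Xs = (X - model.feature_means) / model.feature_scales
    return Xs @ model.weights - model.intercept


def predict_labels(model: LinearSVMModel, X) -> np.ndarray:
    """Predicted labels sign(f), with sign(0) mapped to +1."""
    f = decision_scores(model, X)
    return np.where(f >= 0, 1, -1)


# ----------------------------------------------------------------------------
# solver internals
# ----------------------------------------------------------------------------

def _smoothed_hinge(z, delta):
    # Huber smoothing of max(0, z): quadratic on (0, delta], linear beyond
    return np.where(z <= 0, 0.0, np.where(z <= delta, z**2 / (2 * delta), z - delta / 2))


def _smoothed_hinge_grad(z, delta):
    return np.clip(z / delta, 0.0, 1.0)


def _objective(Xs, y, beta, beta0, spec: PenaltySpec) -> float:
    f = Xs @ beta - beta0
    return float(np.sum(np.maximum(0.0, 1.0 - y * f))) + penalty_value(spec, beta)


def _fista_core(Xs, y, w_l1, lam2, beta, beta0, delta, tol, max_iter, A_norm2):
    """FISTA inner loop for smoothed-hinge + lam2*||beta||^2 + weighted L1.

    Pure-loop formulation so numba can compile it; see the njit wrapper below.
    Returns (beta, beta0, n_iter, converged_flag).
    """
    # Lipschitz bound for the smooth part: sigma_max([X, -1])^2 / delta + 2*lam2
    L = A_norm2 / delta + 2.0 * lam2
    step = 1.0 / L
    b = beta.copy()
    b0 = beta0
    zb = b.copy()
    zb0 = b0
    t = 1.0
    prev_obj = np.inf
    converged = 0
    it = 0
    while it < max_iter:
        it += 1
        z = 1.0 - y * (Xs @ zb - zb0)
        g = np.minimum(np.maximum(z / delta, 0.0), 1.0)
        yg = y * g
        grad_b = -(Xs.T @ yg) + 2.0 * lam2 * zb
        grad_b0 = np.sum(yg)
        bn = zb - step * grad_b
        bn = np.sign(bn) * np.maximum(np.abs(bn) - step * w_l1, 0.0)
        b0n = zb0 - step * grad_b0
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        zb = bn + ((t - 1.0) / t_next) * (bn - b)
        zb0 = b0n + ((t - 1.0) / t_next) * (b0n - b0)
        b = bn
        b0 = b0n
        t = t_next
        if it % 25 == 0:
            zz = 1.0 - y * (Xs @ b - b0)
            sm = 0.0
            for i in range(zz.shape[0]):
                if zz[i] > delta:
                    sm += zz[i] - delta / 2.0
                elif zz[i] > 0.0:
                    sm += zz[i] * zz[i] / (2.0 * delta)
            obj = sm + np.sum(w_l1 * np.abs(b)) + lam2 * np.sum(b * b)
            if abs(prev_obj - obj) <= tol * max(1.0, abs(obj)):
                converged = 1
                break
            # restart acceleration if the objective went up (non-monotone FISTA)
            if obj > prev_obj:
                zb = b.copy()
                zb0 = b0
                t = 1.0
            prev_obj = obj
    return b, b0, it, converged


try:  # jit the hot loop when numba is present; fall back to the numpy version
    from numba import njit

    _fista_core = njit(cache=False)(_fista_core)
except ImportError:  # pragma: no cover
    pass


def _fista_weighted_l1(Xs, y, w_l1, lam2, beta, beta0, delta, tol, max_iter):
    """Solve the weighted-L1 subproblem with smoothing continuation.

    Runs FISTA at the requested smoothing delta, then polishes at delta/10 and
    delta/100 (warm-started) so the smoothing bias in the hinge, which is at
    most n*delta/2, is negligible against the exact non-smooth optimum.
    """
    A_norm2 = _sq_spectral_norm(Xs)
    b, b0 = np.ascontiguousarray(beta, dtype=float), float(beta0)
    total = 0
    conv = 0
    for d, cap_mult in ((delta, 1), (delta / 10.0, 2), (delta / 100.0, 4)):
        b, b0, it, conv = _fista_core(
            np.ascontiguousarray(Xs), np.ascontiguousarray(y, dtype=float),
            np.ascontiguousarray(w_l1, dtype=float), float(lam2), b, float(b0),
            float(d), float(tol), int(max_iter) * cap_mult, float(A_norm2),
        )
        total += it
    return b, b0, total, bool(conv)


def _sq_spectral_norm(Xs, n_iter: int = 30) -> float:
    """Squared spectral norm of [X, -1] by power iteration (deterministic start)."""
    n, p = Xs.shape
    v = np.ones(p + 1) / np.sqrt(p + 1)
    A = np.hstack([Xs, -np.ones((n, 1))])
    G = A.T @ A
    for _ in range(n_iter):
        v = G @ v
        nv = np.linalg.norm(v)
        if nv == 0:
            return 1.0
        v = v / nv
    return float(v @ G @ v) * 1.01  # small safety margin


def fit_penalized_svm(
    X,
    y,
    spec: PenaltySpec,
    feature_ids: Sequence[str] | None = None,
    delta: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 10000,
    max_outer: int = 20,
    standardize: bool = True,
) -> LinearSVMModel:
    """Fit the penalized hinge-loss problem.

    Features are standardized to training mean 0 / sd 1 internally (penalties
    are scale-sensitive); the returned model stores the transform. SCAD kinds
    run an LLA outer loop started from the matching elastic-net solution and
    keep the iterate with the lowest true (non-convex) objective, so the SCAD
    objective never ends above its convex start.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = np.zeros(p)
        sd = np.ones(p)
    Xs = (X - mu) / sd

    beta = np.zeros(p)
    beta0 = 0.0
    total_iter = 0
    converged = True

    if spec.kind in ("ridge", "lasso", "elasticnet"):
        w_l1 = np.full(p, spec.l1 if spec.kind != "ridge" else 0.0)
        beta, beta0, it, conv = _fista_weighted_l1(
            Xs, y, w_l1, spec.l2, beta, beta0, delta, tol, max_iter
        )
        total_iter, converged = it, conv
    else:
        lam1, lam2 = spec.l1, spec.l2
        # elastic-net start (tiny ridge for plain SCAD keeps the start well posed)
        start_l2 = lam2 if spec.kind == "elasticscad" else 1e-4
        w_l1 = np.full(p, lam1)
        beta, beta0, it, conv = _fista_weighted_l1(
            Xs, y, w_l1, start_l2, beta, beta0, delta, tol, max_iter
        )
        total_iter += it
        best_obj = _objective(Xs, y, beta, beta0, spec)
        best = (beta.copy(), beta0)
        prev_obj = best_obj
        for _ in range(max_outer):
            w_l1 = scad_derivative(np.abs(beta), lam1, spec.a)
            beta, beta0, it, conv = _fista_weighted_l1(
                Xs, y, w_l1, lam2, beta, beta0, delta, tol, max_iter
            )
            total_iter += it
            obj = _objective(Xs, y, beta, beta0, spec)
            if obj < best_obj:
                best_obj = obj
                best = (beta.copy(), beta0)
            if abs(prev_obj - obj) <= tol * max(1.0, abs(obj)):
                break
            prev_obj = obj
        beta, beta0 = best
        converged = conv

    beta = np.where(np.abs(beta) > ZERO_TOL, beta, 0.0)
    return LinearSVMModel(
        weights=beta,
        intercept=float(beta0),
        penalty=spec,
        feature_ids=list(feature_ids),
        feature_means=mu,
        feature_scales=sd,
        objective=_objective(Xs, y, beta, beta0, spec),
        n_iter=total_iter,
        converged=converged,
    )


# ----------------------------------------------------------------------------
# cross-validated tuning
# ----------------------------------------------------------------------------

def default_grid(kind: str) -> list[PenaltySpec]:
    """Fixed lambda grid: powers of two from 2^-10 to 2^4 (both axes for
    two-parameter kinds)."""
    lams = [2.0**k for k in range(-10, 5)]
    if kind in _SINGLE_PARAM_KINDS:
        return [PenaltySpec(kind=kind, lam=l) for l in lams]
    return [PenaltySpec(kind=kind, lam1=l1, lam2=l2) for l1 in lams for l2 in lams]


def tune_parameters(
    X,
    y,
    kind: str,
    grid: Sequence[PenaltySpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    **fit_opts,
) -> PenaltySpec:
    """Pick the grid point with the lowest mean stratified-CV misclassification
    error; ties break toward sparser models (larger lam1, then larger lam2)."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if grid is None:
        grid = default_grid(kind)
    if len(grid) == 0:
        raise ValueError("empty tuning grid")
    if len(grid) == 1:
        return grid[0]
    folds = min(folds, int(min(np.sum(y == 1), np.sum(y == -1))))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    errors = []
    failures = []
    for spec in grid:
        fold_err = []
        try:
            for tr, te in splits:
                model = fit_penalized_svm(X[tr], y[tr], spec, **fit_opts)
                pred = predict_labels(model, X[te])
                fold_err.append(float(np.mean(pred != y[te])))
            errors.append(float(np.mean(fold_err)))
        except Exception as exc:  # noqa: BLE001 - per-point diagnostics
            errors.append(np.inf)
            failures.append((spec, repr(exc)))
    if not np.any(np.isfinite(errors)):
        raise RuntimeError(f"all grid fits failed: {failures}")
    errors = np.asarray(errors)
    best_err = errors.min()
    # ties -> sparser: larger lam1, then larger lam2
    candidates = [g for g, e in zip(grid, errors) if e == best_err]
    candidates.sort(key=lambda s: (s.l1, s.l2), reverse=True)
    return candidates[0]
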