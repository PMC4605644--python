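"""Seeded synthetic microarray datasets with known ground truth.

Emulates the statistical structure of background-subtracted whole-blood
miRNA microarray intensities: a log-normal signal component (multiplicative
noise), additive Gaussian background noise, per-batch affine distortions
(scale and offset), group-specific deregulation of a subset of features on
the log scale, and occasional globally inflated outlier samples.

The generative model for sample i (group g, batch b) and feature j is

    x_ij = a_b + s_b * exp(mu_j + delta_jg * effect + eps_mult) + eps_add

with mu_j ~ Normal(5, 1), eps_mult ~ Normal(0, sigma_mult^2),
eps_add ~ Normal(0, sigma_add^2) and delta_jg in {-1, 0, +1} (sign
alternating across the deregulated features of each case group, so both up-
and down-regulated markers occur). This two-component error model is exactly
the one variance-stabilizing normalization assumes, which makes the
preprocessing step testable against its own premise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class SynthParamsError(ValueError):
    """A generator parameter violates its constraints."""


@dataclass(frozen=True)
class BatchSpec:
    """Per-batch affine distortion: intensities are offset + scale * signal."""

    name: str
    scale: float = 1.0
    offset: float = 0.0


@dataclass
class SynthParams:
    """Generator settings; defaults describe the desk-scale study layout."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CD": 20, "UC": 20, "HC": 20}
    )
    n_features: int = 863
    batches: list[BatchSpec] = field(
        default_factory=lambda: [BatchSpec("b1", 1.0, 0.0), BatchSpec("b2", 1.3, 50.0)]
    )
    control_group: str = "HC"
    frac_deregulated: float = 0.05
    effect_size: float = 1.5
    sigma_mult: float = 0.3
    sigma_add: float = 20.0
    n_outliers: int = 0
    outlier_scale: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise SynthParamsError(f"n_per_group[{g!r}] must be >= 2, got {n}")
        if self.n_features < 1:
            raise SynthParamsError(f"n_features must be >= 1, got {self.n_features}")
        if not 0.0 <= self.frac_deregulated <= 1.0:
            raise SynthParamsError(
                f"frac_deregulated must be in [0, 1], got {self.frac_deregulated}"
            )
        if self.sigma_mult < 0:
            raise SynthParamsError(f"sigma_mult must be >= 0, got {self.sigma_mult}")
        if self.sigma_add < 0:
            raise SynthParamsError(f"sigma_add must be >= 0, got {self.sigma_add}")
        if self.n_outliers < 0:
            raise SynthParamsError(f"n_outliers must be >= 0, got {self.n_outliers}")
        if self.n_outliers and self.outlier_scale < 4:
            raise SynthParamsError(
                f"outlier_scale must be >= 4 so outliers clear the QC fences, got {self.outlier_scale}"
            )
        for b in self.batches:
            if b.scale <= 0:
                raise SynthParamsError(f"batch {b.name!r} scale must be > 0, got {b.scale}")
        if self.control_group not in self.n_per_group:
            raise SynthParamsError(
                f"control_group {self.control_group!r} not in n_per_group"
            )


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset: who was deregulated, how, where."""

    deregulated: dict[str, dict[str, float]]  # group -> feature id -> signed effect
    batch_params: dict[str, tuple[float, float]]  # batch -> (offset, scale)
    outlier_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "deregulated": self.deregulated,
            "batch_params": {k: list(v) for k, v in self.batch_params.items()},
            "outlier_samples": self.outlier_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthTruth":
        return cls(
            deregulated={g: dict(v) for g, v in d["deregulated"].items()},
            batch_params={k: (float(v[0]), float(v[1])) for k, v in d["batch_params"].items()},
            outlier_samples=list(d["outlier_samples"]),
        )


def generate_dataset(params: SynthParams):
    """Draw one dataset.

    Returns ``(matrix, sheet, truth)`` where ``matrix`` is a features-by-samples
    DataFrame of raw intensities, ``sheet`` a sample sheet DataFrame with
    columns sample_id/group/batch, and ``truth`` the generation bookkeeping.
    Identical params (including seed) reproduce the output bit for bit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    feature_ids = [f"mir-{j:04d}" for j in range(params.n_features)]
    groups = list(params.n_per_group)
    sample_ids, sample_group, sample_batch = [], [], []
    for g in groups:
        for i in range(params.n_per_group[g]):
            sample_ids.append(f"{g}_{i:03d}")
            sample_group.append(g)
            # round-robin batch assignment within group keeps batches balanced
            sample_batch.append(params.batches[i % len(params.batches)].name)
    n = len(sample_ids)
    p = params.n_features

    mu = rng.normal(5.0, 1.0, size=p)

    n_dereg = int(np.floor(params.frac_deregulated * p))
    deregulated: dict[str, dict[str, float]] = {}
    delta = {g: np.zeros(p) for g in groups}
    for g in groups:
        if g == params.control_group:
            continue
        idx = rng.choice(p, size=n_dereg, replace=False)
        signs = np.where(np.arange(n_dereg) % 2 == 0, 1.0, -1.0)
        delta[g][idx] = signs
        deregulated[g] = {
            feature_ids[j]: float(s * params.effect_size) for j, s in zip(idx, signs)
        }

    batch_map = {b.name: (b.offset, b.scale) for b in params.batches}
    X = np.empty((p, n))
    for i, (sid, g, bname) in enumerate(zip(sample_ids, sample_group, sample_batch)):
        offset, scale = batch_map[bname]
        eps_mult = rng.normal(0.0, params.sigma_mult, size=p)
        eps_add = rng.normal(0.0, params.sigma_add, size=p)
        log_signal = mu + delta[g] * params.effect_size + eps_mult
        X[:, i] = offset + scale * np.exp(log_signal) + eps_add

    outlier_ids: list[str] = []
    if params.n_outliers:
        chosen = rng.choice(n, size=min(params.n_outliers, n), replace=False)
        for i in chosen:
            X[:, i] *= params.outlier_scale
            outlier_ids.append(sample_ids[i])

    matrix = pd.DataFrame(X, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids)
    matrix.attrs["stage"] = "raw"
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "group": sample_group, "batch": sample_batch}
    )
    truth = SynthTruth(
        deregulated=deregulated,
        batch_params=batch_map,
        outlier_samples=sorted(outlier_ids),
    )
    return matrix, sheet, truth


def write_fixture(matrix: pd.DataFrame, sheet: pd.DataFrame, truth: SynthTruth, directory):
    """Write matrix TSV + sheet CSV + truth JSON; returns the three paths.

    The TSV round-trips exactly (full float repr), so re-reading reproduces
    the generated matrix bit for bit.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("refusing to write an empty expression matrix")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix_path = directory / "matrix.tsv"
    sheet_path = directory / "samples.csv"
    truth_path = directory / "truth.json"
    matrix.to_csv(matrix_path, sep="\t", float_format=None)
    sheet.to_csv(sheet_path, index=False)
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    return matrix_path, sheet_path, truth_path


def read_truth(path) -> SynthTruth:
    return SynthTruth.from_dict(json.loads(Path(path).read_text()))
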