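"""Majority-voting combined multi-class diagnosis and its permutation test.

Binary atomic models (each with its group scheme) vote on every sample: an
atomic model's prediction puts one vote on every class contained in the
predicted side's group set. The class with the most votes wins; vote ties go
to the class with the largest mean absolute decision margin among the models
that voted for it. The combined classification error is benchmarked against
a permutation null (labels shuffled, models fixed) summarized by a
Z-statistic and a one-sided normal p-value: small error rates are evidence
that the combined rule captures real group structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .evalsel import GroupScheme
from .pensvm import LinearSVMModel, decision_scores


@dataclass
class CombinedClassifier:
    classes: tuple[str, ...]
    models: list[tuple[LinearSVMModel, GroupScheme]]

    def __post_init__(self):
        covered = set()
        for _, scheme in self.models:
            covered |= set(scheme.positive) | set(scheme.negative)
        missing = set(self.classes) - covered
        if missing:
            raise ValueError(f"classes not covered by any atomic model: {sorted(missing)}")


@dataclass
class PermutationTestResult:
    observed_error: float
    n_permutations: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    significant: bool


def majority_vote(clf: CombinedClassifier, X) -> list[str]:
    """Predict one class label per row of X (raw feature scale)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[0]
    votes = {c: np.zeros(n) for c in clf.classes}
    # margins[c] collects |f| of every model voting for class c, per sample
    margins = {c: [] for c in clf.classes}
    for model, scheme in clf.models:
        f = decision_scores(model, X)
        side_pos = f >= 0
        for c in clf.classes:
            in_pos = c in scheme.positive
            in_neg = c in scheme.negative
            if not (in_pos or in_neg):
                continue
            voted = side_pos if in_pos else ~side_pos
            votes[c] += voted.astype(float)
            m = np.where(voted, np.abs(f), np.nan)
            margins[c].append(m)
    vote_mat = np.column_stack([votes[c] for c in clf.classes])
    cols = []
    for c in clf.classes:
        if not margins[c]:
            cols.append(np.zeros(n))
            continue
        stack = np.column_stack(margins[c])
        counts = np.sum(~np.isnan(stack), axis=1)
        cols.append(np.where(counts > 0, np.nansum(stack, axis=1) / np.maximum(counts, 1), 0.0))
    mean_margin = np.column_stack(cols)
    labels = []
    for i in range(n):
        best = vote_mat[i].max()
        tied = [j for j in range(len(clf.classes)) if vote_mat[i, j] == best]
        if len(tied) > 1:
            tied.sort(key=lambda j: -mean_margin[i, j])
        labels.append(clf.classes[tied[0]])
    return labels


def vote_table(clf: CombinedClassifier, matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diagnosis table: true group, predicted group."""
    sub = sheet[sheet["group"].isin(clf.classes)]
    X = matrix[sub["sample_id"]].to_numpy(dtype=float).T
    pred = majority_vote(clf, X)
    return pd.DataFrame(
        {"sample_id": sub["sample_id"].to_numpy(), "group": sub["group"].to_numpy(), "predicted": pred}
    )


def combined_error_rate(clf: CombinedClassifier, matrix: pd.DataFrame, sheet: pd.DataFrame):
    """Overall and per-group misclassification rates on the given samples."""
    tab = vote_table(clf, matrix, sheet)
    if tab.empty:
        raise ValueError("no samples belong to the combined classifier's classes")
    wrong = tab["predicted"] != tab["group"]
    overall = float(wrong.mean())
    per_group = {
        g: float(wrong[tab["group"] == g].mean()) for g in clf.classes if (tab["group"] == g).any()
    }
    return overall, per_group


def permutation_z_test(
    clf: CombinedClassifier,
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    retrain_fn=None,
) -> PermutationTestResult:
    """Compare the observed combined error with a label-permutation null.

    By default the fitted models stay fixed and only sample labels are
    permuted, so each permutation just re-scores the fixed predictions
    against shuffled truth. Because the observed error is an in-sample
    quantity of models that were themselves fitted to the labels, the
    fixed-model null is optimistic; passing ``retrain_fn`` (a callable
    mapping a permuted sample sheet to a new CombinedClassifier) rebuilds
    the models under each permutation, which calibrates the null at the
    price of n_perm refits.

    Z = (observed - null mean) / null sd; one-sided p = Phi(Z) (small errors
    are the extreme direction).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tab = vote_table(clf, matrix, sheet)
    true = tab["group"].to_numpy()
    pred = np.asarray(tab["predicted"])
    observed = float(np.mean(pred != true))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if retrain_fn is None:
        for i in range(n_perm):
            null[i] = np.mean(pred != rng.permutation(true))
    else:
        sub = sheet[sheet["group"].isin(clf.classes)].reset_index(drop=True)
        for i in range(n_perm):
            perm_sheet = sub.assign(group=rng.permutation(sub["group"].to_numpy()))
            perm_clf = retrain_fn(perm_sheet)
            ptab = vote_table(perm_clf, matrix, perm_sheet)
            null[i] = np.mean(ptab["predicted"].to_numpy() != ptab["group"].to_numpy())
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate permutation null: zero standard deviation")
    z = (observed - mu) / sd
    p = float(norm.cdf(z))
    return PermutationTestResult(
        observed_error=observed,
        n_permutations=n_perm,
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p=p,
        significant=p < 0.05,
    )
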