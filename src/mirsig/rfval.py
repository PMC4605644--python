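"""Random-forest validation of SVM-derived signatures.

An independent learner is trained on the same holdout partitions that the
penalized SVMs used, in four configurations distinguished by where the
feature set comes from: per-holdout RF selection (r2VIM), per-holdout SVM
selection, the fixed "top" signature (most frequently SVM-selected
features), or the fixed "median" signature (features of the sparsest
median-performing SVM). Comparable AUCs across configurations support the
validity of the SVM-selected markers.

Feature selection inside the RF uses the relative recurrency variable
importance metric (r2VIM): permutation importances from several
independently seeded forests are each scaled by the magnitude of the most
negative importance in that run (an estimate of the noise floor), and a
feature is kept only if its relative importance clears a factor threshold
in every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .evalsel import GroupScheme, roc_auc


@dataclass
class RFParams:
    ntree: int = 500
    nodesize_frac: float = 0.10  # terminal node size as a fraction of n_train
    seed: int | None = None  # None -> drawn uniformly from 1..100000

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not 0 < self.nodesize_frac < 1:
            raise ValueError("nodesize_frac must be in (0, 1)")


@dataclass
class R2VIMParams:
    n_runs: int = 10
    factor: float = 1.0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.factor <= 0:
            raise ValueError("factor must be > 0")


def _make_forest(n_train: int, n_features: int, params: RFParams, seed: int):
    return RandomForestClassifier(
        n_estimators=params.ntree,
        min_samples_leaf=max(1, int(round(params.nodesize_frac * n_train))),
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _resolve_seed(params: RFParams, rng: np.random.Generator) -> int:
    if params.seed is not None:
        return int(params.seed)
    return int(rng.integers(1, 100001))


def r2vim_select(
    X,
    y,
    rf_params: RFParams | None = None,
    r2vim_params: R2VIMParams | None = None,
    seed: int = 0,
    n_repeats: int = 5,
) -> list[int]:
    """Indices of features recurrently important across independent forests.

    Per run: fit a forest, compute permutation importance, divide by the
    absolute value of the most negative importance of that run (falling back
    to the smallest positive magnitude if no importance is negative). Keep
    features whose relative importance >= factor in every run.
    """
    rf_params = rf_params or RFParams()
    r2vim_params = r2vim_params or R2VIMParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("r2VIM requires at least two classes")
    if X.shape[1] < 2:
        raise ValueError("r2VIM requires at least two features")
    rng = np.random.default_rng(seed)
    keep = np.ones(X.shape[1], dtype=bool)
    for _ in range(r2vim_params.n_runs):
        run_seed = _resolve_seed(rf_params, rng)
        forest = _make_forest(X.shape[0], X.shape[1], rf_params, run_seed)
        forest.fit(X, y)
        imp = permutation_importance(
            forest, X, y, n_repeats=n_repeats, random_state=run_seed, n_jobs=1
        ).importances_mean
        m = float(imp.min())
        if m != 0.0:
            floor = abs(m)
        else:
            nonzero = np.abs(imp[imp != 0])
            if nonzero.size == 0:
                raise ValueError("all permutation importances are zero")
            floor = float(nonzero.min())
        rel = imp / floor
        keep &= rel >= r2vim_params.factor
    return [int(i) for i in np.flatnonzero(keep)]


def rf_evaluate(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    problem: GroupScheme,
    feature_source: str,
    splits: list[tuple[list[str], list[str]]],
    rf_params: RFParams | None = None,
    r2vim_params: R2VIMParams | None = None,
    fixed_signature: list[str] | None = None,
    holdout_signatures: list[list[str]] | None = None,
    seed: int = 0,
) -> dict:
    """AUC distribution of forests trained on the shared holdout partitions.

    feature_source:
      - 'rf_holdout': features re-selected per split by r2VIM on the training part
      - 'svm_holdout': per-split feature lists from the SVM evaluation
        (``holdout_signatures``, aligned with ``splits``)
      - 'top_signature' / 'median_signature': one fixed list (``fixed_signature``)

    Splits with an empty feature set are skipped and logged.
    """
    if feature_source not in ("rf_holdout", "svm_holdout", "top_signature", "median_signature"):
        raise ValueError(f"unknown feature_source {feature_source!r}")
    if feature_source == "svm_holdout" and holdout_signatures is None:
        raise ValueError("svm_holdout requires per-split holdout_signatures")
    if feature_source in ("top_signature", "median_signature") and not fixed_signature:
        raise ValueError(f"{feature_source} requires a nonempty fixed_signature")
    rf_params = rf_params or RFParams()

    labels = problem.sample_labels(sheet)
    feat_pos = {f: i for i, f in enumerate(matrix.index)}
    X_all = matrix[labels.index].to_numpy(dtype=float).T
    y_all = labels.to_numpy()
    id_pos = {s: i for i, s in enumerate(labels.index)}

    rng = np.random.default_rng(seed)
    aucs, skipped = [], []
    for k, (train_ids, test_ids) in enumerate(splits):
        tr = [id_pos[s] for s in train_ids]
        te = [id_pos[s] for s in test_ids]
        if feature_source == "rf_holdout":
            try:
                cols = r2vim_select(
                    X_all[tr], y_all[tr], rf_params, r2vim_params,
                    seed=int(rng.integers(0, 2**31)),
                )
            except ValueError:  # degenerate importances on this split
                cols = []
        elif feature_source == "svm_holdout":
            cols = [feat_pos[f] for f in holdout_signatures[k]]
        else:
            cols = [feat_pos[f] for f in fixed_signature]
        if not cols:
            skipped.append(k)
            continue
        forest = _make_forest(len(tr), len(cols), rf_params, _resolve_seed(rf_params, rng))
        forest.fit(X_all[np.ix_(tr, cols)], y_all[tr])
        # ROC score: fraction of trees voting for the positive class
        proba = forest.predict_proba(X_all[np.ix_(te, cols)])
        pos_col = list(forest.classes_).index(1)
        aucs.append(roc_auc(proba[:, pos_col], y_all[te]))
    return {
        "feature_source": feature_source,
        "aucs": np.array(aucs),
        "median_auc": float(np.median(aucs)) if aucs else float("nan"),
        "skipped_splits": skipped,
    }
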