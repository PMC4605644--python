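"""Holdout resampling of the classification problems, performance metrics
and signature extraction.

Sixteen binary problems are formed from the groups CD, UC, HC and the pooled
inflammation controls IC = {COPD, MS, PANC, SARC}: the 2-group pairs, the
3-group one-vs-rest contrasts and the 4-group one-vs-rest contrasts. Each is
evaluated by repeated stratified 5:3 train/test holdout splits; per split,
penalty parameters are tuned by stratified 5-fold cross-validated grid
search on the training part only. The final model for a problem is the
"sparsest median performing" one: among holdout models attaining the median
test AUC, the one selecting the fewest features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pensvm import (
    LinearSVMModel,
    PenaltySpec,
    decision_scores,
    default_grid,
    fit_penalized_svm,
    predict_labels,
    tune_parameters,
)

IC_GROUPS = ("COPD", "MS", "PANC", "SARC")


@dataclass(frozen=True)
class GroupScheme:
    """A binary classification problem: positive group set vs negative set."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self):
        if not self.positive or not self.negative:
            raise ValueError("positive and negative group sets must be nonempty")
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative group sets must be disjoint")

    def label(self, group: str) -> int | None:
        if group in self.positive:
            return 1
        if group in self.negative:
            return -1
        return None

    def sample_labels(self, sheet: pd.DataFrame) -> pd.Series:
        """Labels in {-1, +1} for the sheet's samples in this problem
        (samples outside the problem are dropped)."""
        lab = sheet["group"].map(self.label)
        out = pd.Series(lab.to_numpy(), index=sheet["sample_id"].to_numpy())
        return out.dropna().astype(int)


def _scheme(pos, neg):
    name = "+".join(pos) + "_vs_" + "+".join(neg)
    return GroupScheme(name=name, positive=tuple(pos), negative=tuple(neg))


def standard_problems(ic: tuple[str, ...] = IC_GROUPS) -> dict[str, GroupScheme]:
    """The 16 named problems over CD, UC, HC and the pooled IC groups."""
    IC = list(ic)
    pairs = [
        (["CD"], ["HC"]), (["UC"], ["HC"]), (["CD"], ["UC"]),
        (["CD"], IC), (["UC"], IC), (IC, ["HC"]),
        (["CD"], ["UC", "HC"]), (["UC"], ["CD", "HC"]), (["HC"], ["CD", "UC"]),
        (["CD"], ["UC"] + IC), (["UC"], ["CD"] + IC), (IC, ["CD", "UC"]),
        (["CD"], ["UC", "HC"] + IC), (["UC"], ["CD", "HC"] + IC),
        (["HC"], ["CD", "UC"] + IC), (IC, ["CD", "UC", "HC"]),
    ]
    schemes = {}
    for pos, neg in pairs:
        s = _scheme(pos, neg)
        # canonical short names use IC for the pooled inflammation controls
        short = s.name.replace("+".join(IC), "IC")
        schemes[short] = s
    return schemes


# ----------------------------------------------------------------------------
# splits and metrics
# ----------------------------------------------------------------------------

def stratified_holdout_splits(sheet, problem: GroupScheme, n: int = 500, seed: int = 0):
    """Repeated stratified 5:3 train/test splits, without replacement.

    Per group g, round(5/8 * n_g) samples go to training, with at least one
    training and one test sample guaranteed. Returns a list of
    (train_ids, test_ids) tuples; fully determined by the seed.
    """
    labels = problem.sample_labels(sheet)
    groups = sheet.set_index("sample_id").loc[labels.index, "group"]
    by_group = {g: list(idx) for g, idx in groups.groupby(groups).groups.items()}
    for g, ids in by_group.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n):
        train, test = [], []
        for g, ids in sorted(by_group.items()):
            n_g = len(ids)
            n_train = int(round(5.0 / 8.0 * n_g))
            n_train = min(max(n_train, 1), n_g - 1)
            perm = rng.permutation(n_g)
            train.extend(ids[i] for i in perm[:n_train])
            test.extend(ids[i] for i in perm[n_train:])
        splits.append((sorted(train), sorted(test)))
    return splits


def roc_auc(scores, labels) -> float:
    """Rank-statistic AUC: probability a positive sample outscores a negative
    one, ties counting one half (the Mann-Whitney statistic)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def performance_report(pred_labels, scores, true_labels) -> dict[str, float | None]:
    """The ten confusion-matrix / ROC metrics.

    Ratios with zero denominators are reported as None (missing), not 0.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if len(true) == 0:
        raise ValueError("empty evaluation set")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == -1)))
    tn = int(np.sum((pred == -1) & (true == -1)))
    fn = int(np.sum((pred == -1) & (true == 1)))

    def ratio(num, den):
        return num / den if den > 0 else None

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    return {
        "AUC": roc_auc(scores, true),
        "SN": sn,
        "SP": sp,
        "BAC": (sn + sp) / 2 if sn is not None and sp is not None else None,
        "MCC": mcc,
        "YOUDEN": sn + sp - 1 if sn is not None and sp is not None else None,
        "PPV": ppv,
        "NPV": npv,
        "FDR": 1 - ppv if ppv is not None else None,
        "FOR": 1 - npv if npv is not None else None,
    }


# ----------------------------------------------------------------------------
# holdout evaluation
# ----------------------------------------------------------------------------

@dataclass
class HoldoutRecord:
    split_index: int
    train_ids: list[str]
    test_ids: list[str]
    spec: PenaltySpec
    model: LinearSVMModel
    metrics: dict
    selected: list[str]

    @property
    def sparsity_pct_removed(self) -> float:
        return 100.0 * (1.0 - len(self.selected) / len(self.model.feature_ids))


@dataclass
class HoldoutEvaluation:
    problem: GroupScheme
    penalty_kind: str
    records: list[HoldoutRecord]
    n_failures: int = 0
    failures: list = field(default_factory=list)

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.metrics["AUC"] for r in self.records])

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def median_sparsity_pct_removed(self) -> float:
        return float(np.median([r.sparsity_pct_removed for r in self.records]))


@dataclass
class Signature:
    feature_ids: list[str]
    problem: str
    rule: str  # median | top | holdout
    holdout_index: int | None = None


def evaluate_problem(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    problem: GroupScheme,
    penalty_kind: str = "elasticscad",
    n_holdouts: int = 500,
    grid=None,
    folds: int = 5,
    seed: int = 0,
    tune_opts: dict | None = None,
    fit_opts: dict | None = None,
) -> HoldoutEvaluation:
    """Run the holdout evaluation of one problem.

    Per split: tune the penalty by stratified CV grid search on the training
    part, refit on the full training part, score the untouched test part.
    Failed holdouts (solver or degenerate-split errors) are logged and
    excluded; more than 10% failures aborts.
    """
    labels = problem.sample_labels(sheet)
    X_all = matrix[labels.index].to_numpy(dtype=float).T  # samples x features
    feature_ids = list(matrix.index)
    id_pos = {s: i for i, s in enumerate(labels.index)}
    y_all = labels.to_numpy()

    if grid is None:
        grid = default_grid(penalty_kind)
    tune_opts = dict(tune_opts or {})
    fit_opts = dict(fit_opts or {})

    ss = np.random.SeedSequence(seed)
    split_seed, tune_seed0 = ss.spawn(2)
    splits = stratified_holdout_splits(
        sheet, problem, n=n_holdouts, seed=split_seed.generate_state(1)[0] % (2**31)
    )
    tune_seeds = tune_seed0.generate_state(n_holdouts) % (2**31)

    records, failures = [], []
    for k, (train_ids, test_ids) in enumerate(splits):
        tr = [id_pos[s] for s in train_ids]
        te = [id_pos[s] for s in test_ids]
        try:
            spec = tune_parameters(
                X_all[tr], y_all[tr], penalty_kind, grid=grid, folds=folds,
                seed=int(tune_seeds[k]), **tune_opts,
            )
            model = fit_penalized_svm(
                X_all[tr], y_all[tr], spec, feature_ids=feature_ids, **fit_opts
            )
            scores = decision_scores(model, X_all[te])
            pred = predict_labels(model, X_all[te])
            metrics = performance_report(pred, scores, y_all[te])
            records.append(
                HoldoutRecord(
                    split_index=k,
                    train_ids=train_ids,
                    test_ids=test_ids,
                    spec=spec,
                    model=model,
                    metrics=metrics,
                    selected=model.selected_features,
                )
            )
        except Exception as exc:  # noqa: BLE001 - logged, counted, bounded
            failures.append((k, repr(exc)))
    if len(failures) > 0.1 * n_holdouts:
        raise RuntimeError(
            f"{len(failures)} of {n_holdouts} holdouts failed; first: {failures[0]}"
        )
    return HoldoutEvaluation(
        problem=problem,
        penalty_kind=penalty_kind,
        records=records,
        n_failures=len(failures),
        failures=failures,
    )


def select_sparsest_median(ev: HoldoutEvaluation):
    """The sparsest model among those attaining the median holdout AUC.

    The median is the lower median (the ceil(k/2)-th order statistic), which
    is always attained by at least one model; should floating point leave no
    exact match, the models nearest the median on either side are candidates.
    Remaining ties break toward the smallest holdout index.
    """
    if not ev.records:
        raise ValueError("empty holdout evaluation")
    aucs = ev.aucs
    k = len(aucs)
    med = float(np.sort(aucs)[int(np.ceil(k / 2)) - 1])
    at_median = [r for r in ev.records if r.metrics["AUC"] == med]
    if not at_median:
        gap = np.abs(aucs - med)
        at_median = [r for r, g in zip(ev.records, gap) if g == gap.min()]
    winner = min(at_median, key=lambda r: (len(r.selected), r.split_index))
    sig = Signature(
        feature_ids=sorted(winner.selected),
        problem=ev.problem.name,
        rule="median",
        holdout_index=winner.split_index,
    )
    return winner.model, sig


def selection_counts(ev: HoldoutEvaluation) -> pd.Series:
    """How often each ever-selected feature was chosen across holdouts."""
    counts: dict[str, int] = {}
    for r in ev.records:
        for f in r.selected:
            counts[f] = counts.get(f, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def top_frequency_signature(ev: HoldoutEvaluation, fraction: float = 0.5) -> Signature:
    """The most frequently selected features: the ceil(fraction * k) top ranks
    among the k features ever selected, ties at the boundary included."""
    counts = selection_counts(ev)
    if counts.empty:
        raise ValueError("no feature was ever selected")
    k = len(counts)
    n_top = int(np.ceil(fraction * k))
    cutoff = counts.iloc[n_top - 1]
    chosen = counts[counts >= cutoff].index.tolist()
    return Signature(feature_ids=sorted(chosen), problem=ev.problem.name, rule="top")
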