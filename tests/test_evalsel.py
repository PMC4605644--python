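"""Holdout splits, performance metrics and signature extraction."""

import numpy as np
import pandas as pd
import pytest

from mirsig import evalsel
from mirsig.evalsel import (
    GroupScheme,
    HoldoutEvaluation,
    HoldoutRecord,
    performance_report,
    roc_auc,
    select_sparsest_median,
    standard_problems,
    stratified_holdout_splits,
    top_frequency_signature,
)
from mirsig.pensvm import PenaltySpec

import oracles


def sheet_of(counts):
    rows = []
    for g, n in counts.items():
        for i in range(n):
            rows.append([f"{g}_{i}", g, "b1"])
    return pd.DataFrame(rows, columns=["sample_id", "group", "batch"])


def test_sixteen_standard_problems():
    probs = standard_problems()
    assert len(probs) == 16
    assert "CD_vs_HC" in probs and "IC_vs_CD+UC+HC" in probs
    ic = probs["IC_vs_HC"]
    assert set(ic.positive) == {"COPD", "MS", "PANC", "SARC"}
    for s in probs.values():
        assert not set(s.positive) & set(s.negative)


def test_scheme_validation():
    with pytest.raises(ValueError):
        GroupScheme("bad", ("CD",), ("CD", "HC"))
    with pytest.raises(ValueError):
        GroupScheme("bad", (), ("HC",))


class TestSplits:
    def test_exact_5_3_ratio(self):
        sheet = sheet_of({"CD": 8, "HC": 8})
        scheme = standard_problems()["CD_vs_HC"]
        (train, test), = stratified_holdout_splits(sheet, scheme, n=1, seed=0)
        assert len(train) == 10 and len(test) == 6
        for g in ("CD", "HC"):
            assert sum(s.startswith(g) for s in train) == 5
            assert sum(s.startswith(g) for s in test) == 3

    def test_seed_reproducibility(self):
        sheet = sheet_of({"CD": 9, "HC": 12})
        scheme = standard_problems()["CD_vs_HC"]
        s1 = stratified_holdout_splits(sheet, scheme, n=5, seed=42)
        s2 = stratified_holdout_splits(sheet, scheme, n=5, seed=42)
        assert s1 == s2

    def test_per_group_rounding_study_sized(self):
        # n_g = (37, 92): round(5/8*37)=23 train + 14 test; round(5/8*92)=58 + 34
        sheet = sheet_of({"CD": 37, "HC": 92})
        scheme = standard_problems()["CD_vs_HC"]
        (train, test), = stratified_holdout_splits(sheet, scheme, n=1, seed=1)
        assert sum(s.startswith("CD") for s in train) == 23
        assert sum(s.startswith("CD") for s in test) == 14
        assert sum(s.startswith("HC") for s in train) == 58
        assert sum(s.startswith("HC") for s in test) == 34

    def test_small_group_rejected(self):
        sheet = sheet_of({"CD": 1, "HC": 8})
        with pytest.raises(ValueError, match="CD"):
            stratified_holdout_splits(sheet, standard_problems()["CD_vs_HC"], n=1, seed=0)

    def test_partition_disjoint_and_complete(self):
        sheet = sheet_of({"CD": 7, "HC": 11})
        scheme = standard_problems()["CD_vs_HC"]
        for train, test in stratified_holdout_splits(sheet, scheme, n=20, seed=3):
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(sheet["sample_id"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_pair_counting_example(self):
        # labels (1,0,1,0), scores (.9,.8,.7,.6): 3 of 4 pairs concordant
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_tied_scores(self):
        assert roc_auc([1, 1, 1, 1], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, np.where(labels == 1, 1, -1)) == pytest.approx(
                oracles.auc_pair_counting(scores, labels)
            )


class TestPerformanceReport:
    def test_confusion_matrix_example(self):
        # TP=3, FP=1, TN=2, FN=0
        pred = np.array([1, 1, 1, 1, -1, -1])
        true = np.array([1, 1, 1, -1, -1, -1])
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.2, 0.1])
        rep = performance_report(pred, scores, true)
        assert rep["SN"] == pytest.approx(1.0)
        assert rep["SP"] == pytest.approx(2 / 3)
        assert rep["BAC"] == pytest.approx(5 / 6)
        assert rep["MCC"] == pytest.approx(6 / np.sqrt(72))
        assert rep["YOUDEN"] == pytest.approx(2 / 3)
        assert rep["FDR"] == pytest.approx(1 - rep["PPV"])

    def test_bac_identity(self):
        # SN=1.0, SP=0.9 -> BAC=0.95
        pred = np.r_[np.ones(10), -np.ones(9), [1]]
        true = np.r_[np.ones(10), -np.ones(10)]
        scores = np.r_[np.linspace(0.6, 1, 10), np.linspace(0, 0.55, 10)]
        rep = performance_report(pred, scores, true)
        assert rep["SN"] == pytest.approx(1.0)
        assert rep["SP"] == pytest.approx(0.9)
        assert rep["BAC"] == pytest.approx(0.95)

    def test_perfect_mcc(self):
        pred = np.array([1, 1, -1, -1])
        rep = performance_report(pred, [4, 3, 2, 1], pred)
        assert rep["MCC"] == pytest.approx(1.0)

    def test_undefined_ratio_is_missing(self):
        # no positive predictions -> PPV undefined, reported as None
        rep = performance_report([-1, -1, -1], [1, 2, 3], [1, -1, -1])
        assert rep["PPV"] is None and rep["FDR"] is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            performance_report([], [], [])


def _mock_eval(aucs, sparsities):
    scheme = standard_problems()["CD_vs_HC"]
    records = []
    for i, (auc, k) in enumerate(zip(aucs, sparsities)):
        model = type("M", (), {"feature_ids": [f"f{j}" for j in range(30)]})()
        records.append(
            HoldoutRecord(
                split_index=i, train_ids=[], test_ids=[],
                spec=PenaltySpec("lasso", lam=1.0), model=model,
                metrics={"AUC": auc}, selected=[f"f{j}" for j in range(k)],
            )
        )
    return HoldoutEvaluation(problem=scheme, penalty_kind="lasso", records=records)


class TestSparsestMedian:
    def test_rule_application(self):
        ev = _mock_eval([0.7, 0.8, 0.9, 0.9, 0.9], [9, 4, 5, 3, 7])
        model, sig = select_sparsest_median(ev)
        assert len(sig.feature_ids) == 3
        assert sig.holdout_index == 3

    def test_all_equal_gives_globally_sparsest(self):
        ev = _mock_eval([0.8] * 4, [5, 2, 9, 2])
        _, sig = select_sparsest_median(ev)
        assert len(sig.feature_ids) == 2
        assert sig.holdout_index == 1  # smallest index among ties

    def test_even_count_lower_median(self):
        ev = _mock_eval([0.6, 0.7, 0.8, 0.9], [1, 5, 2, 3])
        _, sig = select_sparsest_median(ev)
        # lower median of 4 AUCs is the 2nd order statistic: 0.7
        assert sig.holdout_index == 1

    def test_empty_rejected(self):
        ev = _mock_eval([], [])
        with pytest.raises(ValueError):
            select_sparsest_median(ev)


class TestTopSignature:
    def test_half_of_three(self):
        ev = _mock_eval([0.9] * 3, [0, 0, 0])
        ev.records[0].selected = ["A"] * 1
        counts = {"A": 400, "B": 300, "C": 10}
        ev.records[0].selected = ["A", "B", "C"]
        ev.records[1].selected = ["A", "B"]
        ev.records[2].selected = ["A"]
        sig = top_frequency_signature(ev, fraction=0.5)
        # counts A:3 B:2 C:1 -> ceil(1.5)=2 -> {A, B}
        assert sorted(sig.feature_ids) == ["A", "B"]

    def test_boundary_tie_included(self):
        ev = _mock_eval([0.9] * 2, [0, 0])
        ev.records[0].selected = ["A", "B"]
        ev.records[1].selected = ["A", "B"]
        sig = top_frequency_signature(ev, fraction=0.5)
        assert sorted(sig.feature_ids) == ["A", "B"]

    def test_nothing_selected_rejected(self):
        ev = _mock_eval([0.9], [0])
        with pytest.raises(ValueError):
            top_frequency_signature(ev)


class TestEvaluateProblem:
    @pytest.fixture(scope="class")
    def evaluation(self, normalized_dataset):
        norm, sheet, truth, _ = normalized_dataset
        grid = [
            PenaltySpec("elasticscad", lam1=float(l1), lam2=l2)
            for l1 in (2, 8) for l2 in (0.0625, 1.0)
        ]
        return evalsel.evaluate_problem(
            norm, sheet, standard_problems()["CD_vs_HC"], "elasticscad",
            n_holdouts=8, grid=grid, seed=11,
        ), truth

    def test_no_leakage_id_audit(self, evaluation):
        ev, _ = evaluation
        for r in ev.records:
            assert not set(r.train_ids) & set(r.test_ids)

    def test_deterministic_rerun(self, normalized_dataset):
        norm, sheet, _, _ = normalized_dataset
        grid = [PenaltySpec("lasso", lam=2.0), PenaltySpec("lasso", lam=8.0)]
        kw = dict(penalty_kind="lasso", n_holdouts=3, grid=grid, seed=5)
        scheme = standard_problems()["CD_vs_HC"]
        e1 = evalsel.evaluate_problem(norm, sheet, scheme, **kw)
        e2 = evalsel.evaluate_problem(norm, sheet, scheme, **kw)
        assert [r.metrics for r in e1.records] == [r.metrics for r in e2.records]
        assert [r.selected for r in e1.records] == [r.selected for r in e2.records]

    def test_strong_signal_high_auc(self, evaluation):
        ev, _ = evaluation
        assert ev.median_auc >= 0.9
        assert ev.n_failures == 0

    def test_median_auc_order_invariant(self, evaluation):
        ev, _ = evaluation
        shuffled = HoldoutEvaluation(
            problem=ev.problem, penalty_kind=ev.penalty_kind,
            records=list(reversed(ev.records)),
        )
        assert shuffled.median_auc == ev.median_auc

    def test_sparsity_statistic(self, evaluation):
        ev, _ = evaluation
        for r in ev.records:
            expected = 100 * (1 - len(r.selected) / 200)
            assert r.sparsity_pct_removed == pytest.approx(expected)
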