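"""Penalty analytics and the penalized hinge-loss solver."""

import numpy as np
import pytest

from mirsig.pensvm import (
    PenaltyError,
    PenaltySpec,
    decision_scores,
    default_grid,
    fit_penalized_svm,
    hinge_loss,
    penalty_value,
    predict_labels,
    scad_penalty,
    tune_parameters,
)

import oracles


@pytest.mark.parametrize(
    "y,f,expected", [(1, 2.0, 0.0), (1, 0.0, 1.0), (-1, 0.5, 1.5), (1, 1.0, 0.0)]
)
def test_hinge_loss_values(y, f, expected):
    assert hinge_loss(y, f) == pytest.approx(expected)


def test_hinge_loss_rejects_bad_labels():
    with pytest.raises(ValueError):
        hinge_loss(0, 1.0)


@pytest.mark.parametrize(
    "spec,beta,expected",
    [
        (PenaltySpec("lasso", lam=0.5), [1.0, -2.0], 1.5),
        (PenaltySpec("ridge", lam=2.0), [1.0, -2.0], 10.0),
        (PenaltySpec("elasticnet", lam1=1.0, lam2=0.5), [1.0, -2.0], 5.5),
        (PenaltySpec("scad", lam=1.0), [1.0], 1.0),
        # |b|=5 > a*lam=3.7: constant piece (a+1)lam^2/2 = 2.35
        (PenaltySpec("scad", lam=1.0), [5.0], 2.35),
    ],
)
def test_penalty_values(spec, beta, expected):
    assert penalty_value(spec, beta) == pytest.approx(expected)


@pytest.mark.parametrize("kind", ["ridge", "lasso", "elasticnet", "scad", "elasticscad"])
def test_zero_weights_zero_penalty(kind):
    spec = (
        PenaltySpec(kind, lam=1.0)
        if kind in ("ridge", "lasso", "scad")
        else PenaltySpec(kind, lam1=1.0, lam2=1.0)
    )
    assert penalty_value(spec, np.zeros(7)) == 0.0


def test_scad_spline_shape(rng):
    """Continuity at both knots, LASSO behavior below lam, constant above
    a*lam, for random (lam, a) pairs."""
    eps = 1e-9
    for _ in range(100):
        lam = float(rng.uniform(0.05, 4.0))
        a = float(rng.uniform(2.1, 8.0))
        # knot 1 at |b| = lam: value lam^2
        below = scad_penalty([lam - eps], lam, a)
        at = scad_penalty([lam], lam, a)
        above = scad_penalty([lam + eps], lam, a)
        assert at == pytest.approx(lam**2, rel=1e-6)
        assert below == pytest.approx(at, abs=1e-6)
        assert above == pytest.approx(at, abs=1e-6)
        # knot 2 at |b| = a*lam: value (a+1) lam^2 / 2
        at2 = scad_penalty([a * lam], lam, a)
        assert at2 == pytest.approx((a + 1) * lam**2 / 2, rel=1e-6)
        assert scad_penalty([a * lam - eps], lam, a) == pytest.approx(at2, abs=1e-6)
        assert scad_penalty([a * lam + eps], lam, a) == pytest.approx(at2, abs=1e-6)
        # below lam: identical to LASSO; far above: constant
        b = float(rng.uniform(0, lam))
        assert scad_penalty([b], lam, a) == pytest.approx(lam * b)
        big = float(rng.uniform(a * lam, 10 * a * lam))
        assert scad_penalty([big], lam, a) == pytest.approx((a + 1) * lam**2 / 2)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(kind="nope", lam=1.0),
        dict(kind="lasso"),
        dict(kind="lasso", lam=-1.0),
        dict(kind="elasticnet", lam1=1.0),
        dict(kind="scad", lam=1.0, a=1.5),
    ],
)
def test_penalty_spec_validation(kwargs):
    with pytest.raises(PenaltyError):
        PenaltySpec(**kwargs)


def _toy_one_informative(rng, n=20):
    """Only feature 1 separates the classes; feature 2 is noise."""
    y = np.r_[np.ones(n // 2), -np.ones(n // 2)]
    X = np.column_stack([y * 2.0 + rng.normal(0, 0.1, n), rng.normal(0, 1.0, n)])
    return X, y


def test_lasso_selects_informative_feature(rng):
    X, y = _toy_one_informative(rng)
    model = fit_penalized_svm(X, y, PenaltySpec("lasso", lam=0.5), standardize=False)
    assert model.weights[1] == 0.0
    assert model.weights[0] != 0.0
    _, _, obj_lp = oracles.lasso_hinge_lp(X, y, 0.5)
    assert model.objective <= obj_lp * (1 + 1e-3) + 1e-6


def test_elasticnet_matches_qp_oracle(rng):
    X = rng.normal(size=(10, 5))
    y = np.r_[np.ones(5), -np.ones(5)]
    model = fit_penalized_svm(
        X, y, PenaltySpec("elasticnet", lam1=0.3, lam2=0.2), standardize=False
    )
    _, _, obj = oracles.elasticnet_hinge_qp(X, y, 0.3, 0.2)
    assert model.objective == pytest.approx(obj, rel=1e-3, abs=1e-3)


def test_symmetric_data_zero_intercept(rng):
    X_half = rng.normal(size=(10, 4)) + 1.0
    X = np.vstack([X_half, -X_half])
    y = np.r_[np.ones(10), -np.ones(10)]
    model = fit_penalized_svm(X, y, PenaltySpec("lasso", lam=0.1), standardize=False)
    assert abs(model.intercept) < 1e-3


def test_fit_rejects_bad_inputs(rng):
    X = rng.normal(size=(6, 3))
    with pytest.raises(ValueError):
        fit_penalized_svm(X, np.ones(6), PenaltySpec("lasso", lam=0.1))
    Xbad = X.copy()
    Xbad[0, 0] = np.nan
    with pytest.raises(ValueError):
        fit_penalized_svm(Xbad, np.r_[np.ones(3), -np.ones(3)], PenaltySpec("lasso", lam=0.1))


def test_decision_scores_and_tie_convention():
    model = fit_penalized_svm(
        np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]),
        np.array([-1.0, -1, 1, 1]),
        PenaltySpec("lasso", lam=0.1),
    )
    model.weights = np.array([1.0, 0.0])
    model.intercept = 1.0
    model.feature_means = np.zeros(2)
    model.feature_scales = np.ones(2)
    assert decision_scores(model, np.array([3.0, 9.0]))[0] == pytest.approx(2.0)
    # f = 0 -> label +1 by convention
    assert predict_labels(model, np.array([1.0, 5.0]))[0] == 1
    # affine in x
    x = np.array([0.3, -2.0])
    d = np.array([1.5, 0.7])
    lhs = decision_scores(model, x + d) - decision_scores(model, x)
    assert lhs[0] == pytest.approx(model.weights @ d)
    with pytest.raises(ValueError):
        decision_scores(model, np.ones(3))


def test_lasso_path_sparsity_monotone(rng):
    X = rng.normal(size=(30, 20))
    X[:15, :3] += 1.5
    y = np.r_[np.ones(15), -np.ones(15)]
    counts = []
    for lam in (0.05, 0.2, 0.8, 3.2, 12.8):
        m = fit_penalized_svm(X, y, PenaltySpec("lasso", lam=lam))
        counts.append(m.n_selected)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_objective_beats_zero_model(rng):
    X = rng.normal(size=(16, 8))
    y = np.r_[np.ones(8), -np.ones(8)]
    spec = PenaltySpec("elasticnet", lam1=0.5, lam2=0.5)
    m = fit_penalized_svm(X, y, spec, standardize=False)
    # zero model with the best constant intercept
    best_zero = min(
        float(np.sum(np.maximum(0, 1 - y * (-b0)))) for b0 in np.linspace(-2, 2, 401)
    )
    assert m.objective <= best_zero + 1e-6


def test_scad_lla_does_not_increase_objective_vs_enet_start(rng):
    """The LLA fixed point's true SCAD objective never exceeds that of its
    elastic-net starting point."""
    for _ in range(5):
        X = rng.normal(size=(14, 8))
        X[:7, :2] += 1.0
        y = np.r_[np.ones(7), -np.ones(7)]
        scad = PenaltySpec("elasticscad", lam1=0.5, lam2=0.1)
        m_scad = fit_penalized_svm(X, y, scad, standardize=False)
        enet = fit_penalized_svm(
            X, y, PenaltySpec("elasticnet", lam1=0.5, lam2=0.1), standardize=False
        )
        f = X @ enet.weights - enet.intercept
        start_obj = float(np.sum(np.maximum(0, 1 - y * f))) + penalty_value(
            scad, enet.weights
        )
        assert m_scad.objective <= start_obj + 1e-6


def test_tune_single_point_and_tie_rule(rng):
    X, y = _toy_one_informative(rng)
    only = [PenaltySpec("lasso", lam=0.5)]
    assert tune_parameters(X, y, "lasso", grid=only, seed=0) == only[0]
    # perfectly separable at both lambdas -> tie -> larger lam wins
    spec = tune_parameters(
        X, y, "lasso",
        grid=[PenaltySpec("lasso", lam=0.1), PenaltySpec("lasso", lam=0.2)], seed=0,
    )
    assert spec.lam == 0.2


def test_tune_cv_errors_match_enumeration(rng):
    """CV error per grid point equals a brute-force recomputation with the
    same stratified folds."""
    from sklearn.model_selection import StratifiedKFold

    X = rng.normal(size=(20, 4))
    X[:10, 0] += 1.2
    y = np.r_[np.ones(10), -np.ones(10)]
    grid = [PenaltySpec("lasso", lam=l) for l in (0.1, 1.0, 8.0)]
    seed = 3
    chosen = tune_parameters(X, y, "lasso", grid=grid, folds=5, seed=seed)

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    errs = []
    for spec in grid:
        fold_err = []
        for tr, te in splits:
            m = fit_penalized_svm(X[tr], y[tr], spec)
            fold_err.append(float(np.mean(predict_labels(m, X[te]) != y[te])))
        errs.append(np.mean(fold_err))
    best = min(errs)
    best_specs = sorted(
        (g for g, e in zip(grid, errs) if e == best), key=lambda s: s.l1, reverse=True
    )
    assert chosen == best_specs[0]


def test_default_grid_shapes():
    assert len(default_grid("lasso")) == 15
    assert len(default_grid("elasticscad")) == 225
    assert all(s.kind == "scad" for s in default_grid("scad"))
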