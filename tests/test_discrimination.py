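"""Logistic IRLS, AUC, BCa bootstrap for ΔAUC, Youden cutpoints, bootstrapped R²."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from staturepgs.discrimination import (
    auc,
    bca_interval,
    delta_auc_bca,
    fit_logistic,
    r2_bootstrap,
    youden_cutpoint,
)
from staturepgs.errors import ConvergenceError, ValidationError


def logistic_2x2():
    """Counts: x=1 -> 40 events / 10 non-events; x=0 -> 20 / 30."""
    x = np.concatenate([np.ones(50), np.zeros(50)])
    y = np.concatenate([np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)])
    return y, pd.DataFrame({"x": x})


def test_logistic_closed_form_2x2():
    y, X = logistic_2x2()
    model = fit_logistic(y, X)
    assert model.params["x"] == pytest.approx(np.log(6.0), abs=1e-8)
    assert model.odds_ratios().loc["x", "or"] == pytest.approx(6.0, rel=1e-6)


def test_logistic_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(21)
    n = 400
    X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
    y = (rng.random(n) < expit(-0.3 + 0.9 * X["a"] - 0.5 * X["b"])).astype(float)
    ours = fit_logistic(y, X)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(ours.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(
        np.sqrt(np.diag(ours.cov)), ref.bse.to_numpy(), atol=1e-6
    )


def test_logistic_duplicated_rows_shrink_se():
    y, X = logistic_2x2()
    m1 = fit_logistic(y, X)
    m2 = fit_logistic(np.tile(y, 2), pd.concat([X, X], ignore_index=True))
    np.testing.assert_allclose(m1.params, m2.params, atol=1e-8)
    se1 = np.sqrt(np.diag(m1.cov))
    se2 = np.sqrt(np.diag(m2.cov))
    np.testing.assert_allclose(se2, se1 / np.sqrt(2.0), rtol=1e-6)


def test_logistic_separation_and_single_class():
    x = np.concatenate([-1 - np.arange(10.0), 1 + np.arange(10.0)])
    y = (x > 0).astype(float)
    with pytest.raises(ConvergenceError):
        fit_logistic(y, pd.DataFrame({"x": x}))
    with pytest.raises(ValidationError):
        fit_logistic(np.ones(20), pd.DataFrame({"x": x}))


def test_logistic_null_slope_shrinks_with_n():
    rng = np.random.default_rng(8)
    n = 20_000
    x = rng.normal(0, 1, n)
    y = (rng.random(n) < 0.5).astype(float)
    model = fit_logistic(y, pd.DataFrame({"x": x}))
    assert abs(model.params["x"]) < 0.05
    assert abs(model.params["const"]) < 0.05


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_examples():
    assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
    assert auc(np.ones(10), [0] * 5 + [1] * 5) == 0.5
    assert auc([0.9, 0.4, 0.7, 0.6], [1, 1, 0, 0]) == 0.5  # 2 concordant of 4 pairs
    with pytest.raises(ValidationError):
        auc([1, 2], [1, 1])


def test_auc_matches_trapezoidal_roc_integration():
    from sklearn.metrics import roc_curve

    rng = np.random.default_rng(31)
    for _ in range(5):
        y = (rng.random(80) < 0.4).astype(int)
        if y.min() == y.max():
            continue
        s = np.round(rng.normal(0, 1, 80) + 0.8 * y, 1)  # rounding induces ties
        fpr, tpr, _ = roc_curve(y, s)
        trapezoid = float(np.trapezoid(tpr, fpr))
        assert auc(s, y) == pytest.approx(trapezoid, abs=1e-12)


def test_auc_complement_symmetry():
    rng = np.random.default_rng(32)
    y = np.array([0, 1] * 20)
    s = rng.normal(0, 1, 40)  # continuous, tie-free
    assert auc(s, y) + auc(-s, y) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# BCa
# ---------------------------------------------------------------------------

def test_bca_reduces_to_percentile_when_symmetric():
    """With half the replicates below the estimate (z0 = 0) and a symmetric
    jackknife (a = 0), BCa equals the plain percentile interval."""
    boot = np.concatenate([np.linspace(-1, -0.01, 500), np.linspace(0.01, 1, 500)])
    jack = np.linspace(-0.5, 0.5, 21)
    lo, hi = bca_interval(0.0, boot, jack, level=0.95)
    assert lo == pytest.approx(float(np.quantile(boot, 0.025)))
    assert hi == pytest.approx(float(np.quantile(boot, 0.975)))


def test_bca_degenerate_bootstrap_collapses():
    lo, hi = bca_interval(0.3, np.full(100, 0.3), None)
    assert (lo, hi) == (0.3, 0.3)


def test_delta_auc_equal_models_is_zero():
    rng = np.random.default_rng(41)
    n = 120
    x = rng.normal(0, 1, n)
    y = (rng.random(n) < expit(x)).astype(float)
    X = pd.DataFrame({"x": x})
    res = delta_auc_bca(y, X, X, n_boot=50, seed=1)
    assert res.delta == 0.0
    assert (res.ci_low, res.ci_high) == (0.0, 0.0)


def test_delta_auc_requires_nested_covariates():
    rng = np.random.default_rng(42)
    n = 60
    Xa = pd.DataFrame({"a": rng.normal(0, 1, n)})
    Xb = pd.DataFrame({"b": rng.normal(0, 1, n)})
    y = (rng.random(n) < 0.5).astype(float)
    with pytest.raises(ValidationError):
        delta_auc_bca(y, Xa, Xb, n_boot=10, seed=0)


def test_delta_auc_in_sample_nonnegative_when_nested():
    """Adding a covariate cannot reduce in-sample ΔAUC below ~0 (ML nesting)."""
    rng = np.random.default_rng(43)
    for _ in range(5):
        n = 150
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = (rng.random(n) < expit(0.8 * x1 + 0.3 * x2)).astype(float)
        res = delta_auc_bca(
            y, pd.DataFrame({"x1": x1}), pd.DataFrame({"x1": x1, "x2": x2}), n_boot=10, seed=2
        )
        assert res.delta >= -1e-10


def test_delta_auc_detects_real_signal():
    rng = np.random.default_rng(44)
    n = 500
    x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
    y = (rng.random(n) < expit(0.3 * x1 + 1.5 * x2)).astype(float)
    res = delta_auc_bca(
        y, pd.DataFrame({"x1": x1}), pd.DataFrame({"x1": x1, "x2": x2}), n_boot=300, seed=3
    )
    assert res.delta > 0.05
    assert res.ci_low > 0.0
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# Youden cutpoint
# ---------------------------------------------------------------------------

def test_youden_worked_example():
    scores = np.array([0.1, 0.2, 0.3, 0.8, 0.4, 0.6, 0.7, 0.9])
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    res = youden_cutpoint(scores, labels, positive_low=False, n_boot=50, seed=0)
    assert res.threshold.value == pytest.approx(0.35)
    assert res.sensitivity.value == pytest.approx(1.0)
    assert res.specificity.value == pytest.approx(0.75)
    assert res.youden_j == pytest.approx(0.75)
    assert res.ppv.value == pytest.approx(4 / 5)
    assert res.npv.value == pytest.approx(1.0)


def test_youden_perfect_separation():
    res = youden_cutpoint([1, 2, 3, 10, 11], [0, 0, 0, 1, 1], n_boot=20, seed=0)
    assert res.youden_j == pytest.approx(1.0)
    assert 3 < res.threshold.value < 10


def test_youden_invariant_under_monotone_transform():
    """Metrics are unchanged by a strictly increasing transform of scores and
    the threshold still induces the same classification of the data."""
    rng = np.random.default_rng(51)
    y = (rng.random(100) < 0.4).astype(float)
    s = rng.normal(0, 1, 100) + y
    res_raw = youden_cutpoint(s, y, n_boot=20, seed=5)
    res_exp = youden_cutpoint(np.exp(s), y, n_boot=20, seed=5)
    assert res_exp.sensitivity.value == pytest.approx(res_raw.sensitivity.value)
    assert res_exp.specificity.value == pytest.approx(res_raw.specificity.value)
    assert res_exp.youden_j == pytest.approx(res_raw.youden_j)
    np.testing.assert_array_equal(np.exp(s) >= res_exp.threshold.value, s >= res_raw.threshold.value)


def test_youden_positive_low_direction():
    # low scores flag the positive class: thresholds become 'score <= t' rules
    scores = np.array([-3.0, -2.5, -2.2, -0.1, 0.0, 0.3])
    labels = np.array([1, 1, 1, 0, 0, 0])
    res = youden_cutpoint(scores, labels, positive_low=True, n_boot=20, seed=0)
    assert res.youden_j == pytest.approx(1.0)
    assert -2.2 < res.threshold.value < -0.1
    np.testing.assert_array_equal(scores <= res.threshold.value, labels.astype(bool))


def test_youden_no_signal_j_near_zero():
    rng = np.random.default_rng(52)
    n = 4000
    s = rng.normal(0, 1, n)
    y = (rng.random(n) < 0.5).astype(float)
    res = youden_cutpoint(s, y, n_boot=10, seed=6)
    assert res.youden_j < 0.1


# ---------------------------------------------------------------------------
# R^2 bootstrap
# ---------------------------------------------------------------------------

def test_r2_exact_fit():
    x = np.linspace(0, 1, 40)
    res = r2_bootstrap(2.0 * x - 1.0, pd.DataFrame({"x": x}), n_boot=50, seed=0)
    assert res.r2 == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)


def test_r2_independent_predictor_near_zero():
    rng = np.random.default_rng(61)
    n = 5000
    res = r2_bootstrap(
        rng.normal(0, 1, n), pd.DataFrame({"x": rng.normal(0, 1, n)}), n_boot=50, seed=1
    )
    assert res.r2 < 0.01
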