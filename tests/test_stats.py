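"""Association statistics: closed forms, calibration, and power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurosem.stats import (breusch_pagan, fdr_bh, fisher_ci, levene_test,
                            partial_correlation, robust_regression,
                            williams_test)


# ------------------------------------------------------------ Williams test
def test_williams_reproduces_reported_statistic():
    res = williams_test(-0.67, -0.29, 0.38, 567)
    assert res.df == 564
    assert abs(res.statistic) == pytest.approx(10.63, abs=0.01)
    # within half a percent of the value computed from unrounded inputs
    assert abs(abs(res.statistic) - 10.66) / 10.66 < 0.005
    assert res.p_value < 1e-5


def test_williams_zero_when_correlations_equal():
    assert williams_test(0.5, 0.5, 0.3, 100).statistic == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-0.8, 0.8), st.floats(-0.8, 0.8), st.floats(-0.5, 0.5),
       st.integers(10, 5000))
def test_williams_antisymmetric(r12, r13, r23, n):
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det <= 1e-3:
        return
    a = williams_test(r12, r13, r23, n)
    b = williams_test(r13, r12, r23, n)
    assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


def test_williams_rejects_invalid_triples():
    with pytest.raises(ValueError):
        williams_test(1.0, 0.2, 0.1, 50)
    with pytest.raises(ValueError, match="positive definite"):
        williams_test(0.9, -0.9, 0.9, 50)


def test_williams_null_calibration():
    """Type-I error near nominal under equal true correlations (trivariate
    normal, n=100, 2000 replications)."""
    rng = np.random.default_rng(1)
    R = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.3], [0.4, 0.3, 1.0]])
    L = np.linalg.cholesky(R)
    rej = 0
    N = 2000
    for _ in range(N):
        X = rng.standard_normal((100, 3)) @ L.T
        C = np.corrcoef(X, rowvar=False)
        rej += williams_test(C[0, 1], C[0, 2], C[1, 2], 100).p_value < 0.05
    assert 0.03 <= rej / N <= 0.07


# ---------------------------------------------------------------- Fisher CI
def test_fisher_ci_closed_forms():
    res = fisher_ci(0.0, 403)
    lo, hi = res.auxiliaries["ci"]
    assert lo == pytest.approx(-np.tanh(1.959963985 / 20), abs=1e-6)
    assert hi == pytest.approx(np.tanh(1.959963985 / 20), abs=1e-6)
    res = fisher_ci(-0.67, 567)
    lo, hi = res.auxiliaries["ci"]
    assert lo == pytest.approx(-0.71, abs=0.005)
    assert hi == pytest.approx(-0.62, abs=0.005)


def test_fisher_ci_coverage():
    rng = np.random.default_rng(2)
    rho = 0.5
    L = np.linalg.cholesky(np.array([[1, rho], [rho, 1]]))
    cover = 0
    N = 2000
    for _ in range(N):
        X = rng.standard_normal((100, 2)) @ L.T
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        lo, hi = fisher_ci(r, 100).auxiliaries["ci"]
        cover += lo <= rho <= hi
    assert 0.93 <= cover / N <= 0.97


# ------------------------------------------------------ partial correlation
def test_partial_correlation_matches_closed_form():
    rng = np.random.default_rng(3)
    z = rng.standard_normal(500)
    x = 0.5 * z + rng.standard_normal(500)
    y = -0.4 * z + 0.3 * x + rng.standard_normal(500)
    res = partial_correlation(x, y, z)
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    assert res.auxiliaries["r"] == pytest.approx(closed, abs=1e-10)
    assert res.df == 497


def test_partial_correlation_independence_limit():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(100000)
    y = 0.4 * x + rng.standard_normal(100000)
    z = rng.standard_normal(100000)  # independent control
    res = partial_correlation(x, y, z)
    assert res.auxiliaries["r"] == pytest.approx(np.corrcoef(x, y)[0, 1],
                                                 abs=0.01)


def test_partial_correlation_degenerate_inputs():
    x = np.random.default_rng(0).standard_normal(50)
    with pytest.raises(ValueError):
        partial_correlation(x, x + 1.0, x)  # x collinear with control
    with pytest.raises(ValueError):
        partial_correlation(np.ones(50), x, x)


# ------------------------------------------------------------ Breusch-Pagan
def test_breusch_pagan_null_calibration():
    rng = np.random.default_rng(5)
    rej = 0
    N = 2000
    for _ in range(N):
        x = rng.standard_normal(567)
        y = 0.5 * x + rng.standard_normal(567)
        rej += breusch_pagan(y, x).p_value < 0.05
    assert 0.03 <= rej / N <= 0.07


def test_breusch_pagan_power_when_sd_proportional_to_predictor():
    rng = np.random.default_rng(6)
    rej = 0
    for _ in range(100):
        x = rng.uniform(0.5, 2.0, 567)
        y = 0.5 * x + x * rng.standard_normal(567)
        rej += breusch_pagan(y, x).p_value < 0.05
    assert rej / 100 > 0.9


def test_breusch_pagan_variants_and_errors():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(200)
    y = x + rng.standard_normal(200)
    koenker = breusch_pagan(y, x)
    original = breusch_pagan(y, x, studentized=False)
    assert koenker.method != original.method
    assert koenker.statistic != original.statistic
    with pytest.raises(ValueError):
        breusch_pagan(np.ones(200), x)


# -------------------------------------------------------- robust regression
def test_hc0_matches_explicit_sandwich_formula():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(300)
    y = 1.0 + 0.5 * x + rng.standard_normal(300) * (1 + 0.5 * np.abs(x))
    res = robust_regression(y, x, hc_type="HC0")
    X = np.column_stack([np.ones(300), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    e = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e**2)[:, None])
    cov = bread @ meat @ bread
    assert res[1].auxiliaries["se"] == pytest.approx(np.sqrt(cov[1, 1]),
                                                     abs=1e-10)
    assert res[1].auxiliaries["coef"] == pytest.approx(beta[1], abs=1e-12)


def test_robust_equals_classical_under_homoscedasticity():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(100000)
    y = 2.0 - 0.3 * x + rng.standard_normal(100000)
    res = robust_regression(y, x)
    ratio = res[1].auxiliaries["se"] / res[1].auxiliaries["se_classical"]
    assert 0.98 < ratio < 1.02


def test_age_slope_recovery_with_heteroscedastic_noise():
    """A per-year slope of -0.034 with age-increasing residual SD is
    recovered by both classical and sandwich estimators."""
    rng = np.random.default_rng(10)
    age = rng.uniform(18, 88, 567)
    sd = 0.8 * (1 + 0.5 * (age - 18) / 70)
    y = -0.034 * age + sd * rng.standard_normal(567)
    res = robust_regression(y, age, hc_type="HC1", names=["age"])
    assert res[1].auxiliaries["coef"] == pytest.approx(-0.034, abs=0.003)
    assert res[1].auxiliaries["se"] == pytest.approx(
        res[1].auxiliaries["se_classical"], rel=0.15)
    with pytest.raises(ValueError):
        robust_regression(y, np.column_stack([age, age]))  # rank deficient


# ------------------------------------------------------------------- Levene
def test_levene_zero_for_identical_groups():
    v = np.concatenate([np.arange(10.0), np.arange(10.0)])
    g = np.array([0] * 10 + [1] * 10)
    assert levene_test(v, g).statistic == pytest.approx(0.0, abs=1e-12)


def test_levene_power_for_doubled_sd():
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(200):
        a = rng.standard_normal(210)
        b = 2.0 * rng.standard_normal(210)
        p = levene_test(np.concatenate([a, b]),
                        np.array([0] * 210 + [1] * 210)).p_value
        hits += p < 0.001
    assert hits / 200 >= 0.95
    with pytest.raises(ValueError):
        levene_test(np.arange(5.0), np.zeros(5))


# ---------------------------------------------------------------------- FDR
def test_fdr_bh_step_up_arithmetic():
    assert list(fdr_bh([0.001, 0.2, 0.8], 0.05)) == [True, False, False]
    with pytest.raises(ValueError):
        fdr_bh([])
    with pytest.raises(ValueError):
        fdr_bh([0.5, 1.2])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
       st.floats(0.01, 0.2), st.floats(0.01, 0.2))
def test_fdr_bh_monotone_and_ordered(ps, q1, q2):
    lo, hi = sorted([q1, q2])
    r_lo, r_hi = fdr_bh(ps, lo), fdr_bh(ps, hi)
    # rejections grow with q
    assert np.all(r_hi[r_lo])
    # never reject a p-value larger than a kept smaller one
    p = np.asarray(ps)
    if r_hi.any() and (~r_hi).any():
        assert p[r_hi].max() <= p[~r_hi].min() + 1e-12
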