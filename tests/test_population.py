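"""Synthetic cohort generator: calibration, determinism, convergence of
sample moments, range invariants, outlier screening, heteroscedasticity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import neurosem as ns
from neurosem.population import (ALL_NEURAL, BEHAV_VARS, CalibrationError,
                                 CohortConfig, build_population_model,
                                 generate_cohort, screen_outliers)
from oracles import loop_implied_cov


def test_default_calibration_reproduces_target_correlations(pop):
    S = pop.implied_covariance()
    assert S.loc["age", "fa_fm"] == pytest.approx(-0.77, abs=1e-10)
    assert S.loc["age", "fa_atr"] == pytest.approx(-0.51, abs=1e-10)
    assert S.loc["age", "gmv_ba10"] == pytest.approx(-0.20, abs=1e-10)
    assert S.loc["age", "gmv_md"] == pytest.approx(-0.18, abs=1e-10)
    V = pop.node_covariance()
    assert V.loc["fluid", "multitask"] == pytest.approx(0.325, abs=1e-10)
    # observed variables are standardized: unit implied variances
    assert np.allclose(np.diag(S.to_numpy()), 1.0, atol=1e-10)


def test_zero_path_config_gives_identity_covariance():
    cfg = CohortConfig()
    cfg.age_to_neural = {v: 0.0 for v in ALL_NEURAL}
    cfg.neural_to_fluid = {}
    cfg.neural_to_multitask = {}
    cfg.neural_residual_corr = {}
    cfg.age_to_fluid = 0.0
    cfg.age_to_multitask = 0.0
    cfg.factor_corr = 0.0
    cfg.loadings_fluid = (0.0, 0.0, 0.0, 0.0)
    cfg.loadings_multitask = (0.0, 0.0)
    model = build_population_model(cfg)
    assert np.allclose(model.implied_covariance().to_numpy(),
                       np.eye(13), atol=1e-12)


def test_implied_covariance_matches_loop_oracle(pop):
    lam, b, psi, th = pop.matrices()
    assert np.allclose(pop.implied_covariance().to_numpy(),
                       loop_implied_cov(lam, b, psi, th), atol=1e-12)


def test_nonpd_calibration_raises_naming_minor():
    cfg = CohortConfig()
    cfg.neural_residual_corr = dict(cfg.neural_residual_corr)
    # force an impossible triple among the WM tracts
    cfg.neural_residual_corr[("fa_fm", "fa_atr")] = 0.98
    cfg.neural_residual_corr[("fa_fm", "fa_forceps_major")] = 0.98
    cfg.neural_residual_corr[("fa_atr", "fa_forceps_major")] = -0.9
    with pytest.raises(CalibrationError, match="minor"):
        build_population_model(cfg)


def test_invalid_correlation_rejected():
    cfg = CohortConfig(factor_corr=1.2)
    with pytest.raises(CalibrationError):
        build_population_model(cfg)


def test_unit_variances_without_heteroscedasticity():
    cfg = CohortConfig(heteroscedasticity_slope=0.0)
    model = build_population_model(cfg)
    assert np.allclose(np.diag(model.implied_covariance().to_numpy()), 1.0,
                       atol=1e-8)


def test_same_seed_bit_identical_different_seed_differs(pop):
    a = generate_cohort(pop, 200, seed=5)
    b = generate_cohort(pop, 200, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(pop, 200, seed=6)
    stochastic = BEHAV_VARS + ALL_NEURAL + ["age"]
    for col in stochastic:
        assert not np.array_equal(a[col].to_numpy(), c[col].to_numpy()), col


def test_range_and_completeness_invariants(cohort567):
    t = cohort567
    assert not t.isna().to_numpy().any()
    assert t["hotel_ntasks"].between(1, 5).all()
    assert t["hotel_ttm"].between(0, 960).all()
    for c in ("fa_fm", "fa_atr", "fa_forceps_major"):
        assert ((t[c] > 0) & (t[c] < 1)).all()
    assert len(t) == 567


def test_minimum_n_enforced(pop):
    with pytest.raises(ValueError):
        generate_cohort(pop, 9, seed=1)


def test_moment_convergence_within_monte_carlo_error(pop, cohort200k):
    """Every pairwise sample correlation at n=200000 sits within 3 MC
    standard errors of the implied value (TTM compared on the reversed
    model orientation)."""
    imp = pop.implied_covariance()
    obs = pop.observed
    dat = pd.DataFrame({v: (-cohort200k["hotel_ttm"] if v == "hotel_ttm"
                            else cohort200k[v]) for v in obs})
    emp = dat.corr().to_numpy()
    th = imp.to_numpy()
    n = len(dat)
    for i in range(len(obs)):
        for j in range(i):
            se = (1 - th[i, j] ** 2) / np.sqrt(n)
            assert abs(emp[i, j] - th[i, j]) < 3 * se, (obs[i], obs[j])


def test_factor_score_age_correlations_match_targets(frame200k, cohort200k):
    res = ns.fit(ns.build("two_factor_cfa"), frame200k)
    sc = ns.factor_scores(res, frame200k)
    age = cohort200k["age"].to_numpy()
    assert np.corrcoef(age, sc["fluid"])[0, 1] == pytest.approx(-0.67, abs=0.02)
    assert np.corrcoef(age, sc["multitask"])[0, 1] == pytest.approx(-0.29, abs=0.02)


# ------------------------------------------------------------- screening
def test_planted_extreme_value_dropped(pop):
    t = generate_cohort(pop, 300, seed=8)
    t.loc[7, "gmv_ba10"] = t["gmv_ba10"].mean() + 5 * t["gmv_ba10"].std()
    kept = screen_outliers(t)
    assert 7 not in kept["participant_id"].to_numpy() - 1
    assert len(kept) >= 298


def test_clean_table_unchanged(pop):
    t = generate_cohort(pop, 300, seed=12)
    # force a clean table by clipping, then screening is the identity
    for c in ALL_NEURAL:
        m, s = t[c].mean(), t[c].std()
        t[c] = t[c].clip(m - 3.5 * s, m + 3.5 * s)
    pd.testing.assert_frame_equal(screen_outliers(t), t.reset_index(drop=True))


def test_screening_571_with_four_planted_leaves_567(pop):
    t = generate_cohort(pop, 571, seed=1, n_outliers=4)
    assert len(screen_outliers(t)) == 567


def test_zero_sd_column_raises(pop):
    t = generate_cohort(pop, 50, seed=3)
    t["fa_fm"] = 0.4
    with pytest.raises(ValueError, match="fa_fm"):
        screen_outliers(t)


def test_screening_single_pass_not_iterated(pop):
    """z-scores come from the input table's own moments: a value at z=4.5
    that would only become extreme after removal of a bigger outlier is
    kept."""
    t = generate_cohort(pop, 400, seed=9)
    m, s = t["fa_atr"].mean(), t["fa_atr"].std()
    t.loc[0, "fa_atr"] = m + 30 * s  # inflates the SD massively
    t.loc[1, "fa_atr"] = m + 4.5 * s  # extreme w.r.t. the clean SD only
    kept = screen_outliers(t)
    ids = kept["participant_id"].to_numpy()
    assert 1 not in ids  # the huge outlier (participant_id 1) goes
    assert 2 in ids  # the moderate one survives the single pass


# ------------------------------------------------- heteroscedasticity
def test_breusch_pagan_null_uniform_without_heteroscedasticity():
    """With slope 0 the BP p-values on behaviour~age are uniform across
    repeated generation."""
    cfg = CohortConfig(heteroscedasticity_slope=0.0)
    model = build_population_model(cfg)
    ps = []
    for rep in range(200):
        t = generate_cohort(model, 4000, seed=40000 + rep)
        ps.append(ns.breusch_pagan(t["cattell_1"], t["age"]).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_breusch_pagan_detects_generator_heteroscedasticity(pop):
    rej = 0
    for rep in range(40):
        t = generate_cohort(pop, 567, seed=50000 + rep)
        p = min(ns.breusch_pagan(t["cattell_1"], t["age"]).p_value,
                ns.breusch_pagan(-t["hotel_ttm"], t["age"]).p_value)
        rej += p < 0.05
    assert rej / 40 > 0.8  # age-increasing residual SD is detectable


def test_population_yaml_roundtrip_fields(pop):
    text = pop.to_yaml()
    import yaml
    doc = yaml.safe_load(text)
    assert doc["age_distribution"] == [18.0, 88.0]
    assert doc["structural_paths"]["fa_fm~age"] == pytest.approx(-0.77)
    assert "hotel_ttm" in doc["loadings"]
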