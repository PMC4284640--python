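"""Engine estimates and fit statistics against independent oracles on small
models: closed forms where they exist, naive numerically-optimized ML fits
elsewhere (estimates to 1e-4, fit indices to 1e-2)."""

import numpy as np
import pandas as pd
import pytest

import neurosem as ns
from neurosem.spec import SemModelSpec
from oracles import naive_fit

RTOL_EST = 1e-4


def _rmsea(chi2, df, n):
    return np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0


def _sim_factor_data(seed, lam_blocks, phi, n):
    """lam_blocks: list of per-factor loading lists."""
    rng = np.random.default_rng(seed)
    k = len(lam_blocks)
    p = sum(len(b) for b in lam_blocks)
    lam = np.zeros((p, k))
    r = 0
    for j, b in enumerate(lam_blocks):
        lam[r:r + len(b), j] = b
        r += len(b)
    th = 1 - np.sum(lam**2, axis=1)
    F = rng.multivariate_normal(np.zeros(k), phi, size=n, method="cholesky")
    Y = F @ lam.T + rng.standard_normal((n, p)) * np.sqrt(th)
    return pd.DataFrame(Y, columns=[f"y{i}" for i in range(p)])


def test_three_indicator_cfa_matches_tetrad_closed_form():
    df = _sim_factor_data(11, [[0.9, 0.7, 0.5]], np.eye(1), 4000)
    S = np.cov(df.to_numpy(), rowvar=False, ddof=1)
    l1 = np.sqrt(S[0, 1] * S[0, 2] / S[1, 2])
    l2 = np.sqrt(S[0, 1] * S[1, 2] / S[0, 2])
    l3 = np.sqrt(S[0, 2] * S[1, 2] / S[0, 1])
    spec = SemModelSpec(["y0", "y1", "y2"], ["f"])
    for v in ("y0", "y1", "y2"):
        spec.add_loading("f", v)
    spec.add_variance("f", free=False, value=1.0)
    res = ns.fit(spec, df)
    est = res.theta_hat.as_dict()
    for lab, oracle in zip(("l:y0~f", "l:y1~f", "l:y2~f"), (l1, l2, l3)):
        assert est[lab] == pytest.approx(oracle, rel=RTOL_EST)
    for i, lab in enumerate(("v:y0", "v:y1", "v:y2")):
        assert est[lab] == pytest.approx(S[i, i] - (l1, l2, l3)[i] ** 2,
                                         abs=1e-6)
    assert abs(res.chi2_ml) < 1e-8  # just-identified


def test_observed_path_model_matches_ols():
    rng = np.random.default_rng(4)
    n = 1500
    x = rng.standard_normal(n)
    m = 0.5 * x + 0.8 * rng.standard_normal(n)
    y = 0.3 * m - 0.2 * x + 0.7 * rng.standard_normal(n)
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    spec = SemModelSpec(["x", "m", "y"])
    spec.add_regression("m", "x")
    spec.add_regression("y", "m")
    spec.add_regression("y", "x")
    spec.set_fixed_x(["x"])
    res = ns.fit(spec, df)
    X1 = np.column_stack([np.ones(n), x])
    bm = np.linalg.lstsq(X1, m, rcond=None)[0][1]
    X2 = np.column_stack([np.ones(n), m, x])
    by = np.linalg.lstsq(X2, y, rcond=None)[0]
    assert res.estimate("b:m~x") == pytest.approx(bm, rel=RTOL_EST)
    assert res.estimate("b:y~m") == pytest.approx(by[1], rel=RTOL_EST)
    assert res.estimate("b:y~x") == pytest.approx(by[2], rel=RTOL_EST)
    assert res.df == 0 and abs(res.chi2_ml) < 1e-8


def _compare_with_naive(spec, df, template, x0, label_of, bounds=None,
                        n_groups=1):
    res = ns.fit(spec, df)
    X = df[spec.observed].to_numpy(float)
    S = np.cov(X, rowvar=False, ddof=1)
    n = len(df)
    x_hat, chi2_naive = naive_fit(S, n, template, x0, bounds)
    assert res.chi2_ml == pytest.approx(chi2_naive, abs=2e-4)
    est = res.theta_hat.as_dict()
    for k, lab in enumerate(label_of):
        if lab is None:
            continue
        assert est[lab] == pytest.approx(x_hat[k], abs=2e-4), lab
    # fit indices from the naive chi2
    assert res.rmsea == pytest.approx(_rmsea(chi2_naive, res.df, n), abs=1e-2)
    return res


def test_one_factor_six_indicators_vs_naive_numeric():
    df = _sim_factor_data(21, [[0.8, 0.75, 0.7, 0.65, 0.6, 0.55]], np.eye(1), 2000)

    def template(x):
        lam = x[:6]
        return np.outer(lam, lam) + np.diag(x[6:12])

    labels = [f"l:y{i}~f" for i in range(6)] + [f"v:y{i}" for i in range(6)]
    spec = SemModelSpec([f"y{i}" for i in range(6)], ["f"])
    for i in range(6):
        spec.add_loading("f", f"y{i}")
    spec.add_variance("f", free=False, value=1.0)
    x0 = np.concatenate([0.7 * np.ones(6), 0.5 * np.ones(6)])
    bounds = [(None, None)] * 6 + [(1e-6, None)] * 6
    _compare_with_naive(spec, df, template, x0, labels, bounds)


def test_two_factor_cfa_vs_naive_numeric():
    phi = np.array([[1.0, 0.4], [0.4, 1.0]])
    df = _sim_factor_data(31, [[0.8, 0.75, 0.7], [0.8, 0.7, 0.6]], phi, 2000)

    def template(x):
        lam = np.zeros((6, 2))
        lam[:3, 0] = x[:3]
        lam[3:, 1] = x[3:6]
        ph = np.array([[1.0, x[12]], [x[12], 1.0]])
        return lam @ ph @ lam.T + np.diag(x[6:12])

    labels = ([f"l:y{i}~f1" for i in range(3)] + [f"l:y{i}~f2" for i in (3, 4, 5)]
              + [f"v:y{i}" for i in range(6)] + ["c:f1~~f2"])
    spec = SemModelSpec([f"y{i}" for i in range(6)], ["f1", "f2"])
    for i in range(3):
        spec.add_loading("f1", f"y{i}")
    for i in (3, 4, 5):
        spec.add_loading("f2", f"y{i}")
    spec.add_variance("f1", free=False, value=1.0)
    spec.add_variance("f2", free=False, value=1.0)
    spec.add_covariance("f1", "f2")
    x0 = np.concatenate([0.7 * np.ones(6), 0.5 * np.ones(6), [0.2]])
    bounds = [(None, None)] * 6 + [(1e-6, None)] * 6 + [(None, None)]
    _compare_with_naive(spec, df, template, x0, labels, bounds)


def test_small_mimic_vs_naive_numeric():
    """One latent (3 indicators) regressed on two fixed-x predictors."""
    rng = np.random.default_rng(41)
    n = 2000
    x = rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 1.0]], size=n)
    eta = 0.4 * x[:, 0] - 0.3 * x[:, 1] + np.sqrt(0.6) * rng.standard_normal(n)
    lam = np.array([1.0, 0.8, 0.7])
    Y = eta[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt([0.4, 0.5, 0.6])
    df = pd.DataFrame(np.column_stack([Y, x]),
                      columns=["y0", "y1", "y2", "x0", "x1"])
    X = df.to_numpy()
    S = np.cov(X, rowvar=False, ddof=1)
    Sxx = S[3:, 3:]

    def template(p):
        # p = (l1, l2, g0, g1, psi, th0, th1, th2)
        lam_ = np.array([1.0, p[0], p[1]])
        g = np.array([p[2], p[3]])
        var_eta = g @ Sxx @ g + p[4]
        cov_xy = Sxx @ g
        sig = np.zeros((5, 5))
        sig[:3, :3] = np.outer(lam_, lam_) * var_eta + np.diag(p[5:8])
        sig[:3, 3:] = np.outer(lam_, cov_xy)
        sig[3:, :3] = sig[:3, 3:].T
        sig[3:, 3:] = Sxx
        return sig

    spec = SemModelSpec(["y0", "y1", "y2", "x0", "x1"], ["eta"])
    spec.add_loading("eta", "y0", free=False, value=1.0)
    spec.add_loading("eta", "y1")
    spec.add_loading("eta", "y2")
    spec.add_regression("eta", "x0")
    spec.add_regression("eta", "x1")
    spec.add_variance("eta")
    spec.set_fixed_x(["x0", "x1"])
    labels = ["l:y1~eta", "l:y2~eta", "b:eta~x0", "b:eta~x1", "v:eta",
              "v:y0", "v:y1", "v:y2"]
    x0 = np.array([0.7, 0.7, 0.0, 0.0, 0.5, 0.5, 0.5, 0.5])
    bounds = [(None, None)] * 4 + [(1e-6, None)] * 4
    res = _compare_with_naive(spec, df, template, x0, labels, bounds)
    assert res.df == 4  # 15 moments - 3 fixed-x moments - 8 free parameters
    # true structural paths recovered
    assert res.estimate("b:eta~x0") == pytest.approx(0.4, abs=0.06)


def test_full_mediation_structure_vs_naive_numeric(pop):
    tab = ns.generate_cohort(pop, 2000, seed=51)
    from neurosem.models import mediation_multitask, prepare_model_frame
    frame = prepare_model_frame(tab)
    spec = mediation_multitask()
    X = frame[spec.observed].to_numpy(float)
    S = np.cov(X, rowvar=False, ddof=1)

    def template(p):
        # p = (a, b, c, l, psi_m, psi_eta, th0, th1); order: age, atr, ttm, ntasks
        a, b, c, l, psi_m, psi_eta, th0, th1 = p
        v_age = S[0, 0]
        v_atr = a * a * v_age + psi_m
        c_age_atr = a * v_age
        v_eta = (b * b * v_atr + c * c * v_age + 2 * b * c * c_age_atr
                 + psi_eta)
        c_eta_age = b * c_age_atr + c * v_age
        c_eta_atr = b * v_atr + c * c_age_atr
        lamv = np.array([1.0, l])
        sig = np.zeros((4, 4))
        sig[0, 0] = v_age
        sig[1, 1] = v_atr
        sig[0, 1] = sig[1, 0] = c_age_atr
        sig[2:, 2:] = np.outer(lamv, lamv) * v_eta + np.diag([th0, th1])
        sig[2:, 0] = sig[0, 2:] = lamv * c_eta_age
        sig[2:, 1] = sig[1, 2:] = lamv * c_eta_atr
        return sig

    labels = ["a", "b", "c", "l:hotel_ntasks~multitask", "v:fa_atr",
              "v:multitask", "v:hotel_ttm_rev", "v:hotel_ntasks"]
    x0 = np.array([-0.3, 0.1, -0.2, 0.7, 0.5, 0.5, 0.5, 0.5])
    bounds = [(None, None)] * 4 + [(1e-6, None)] * 4
    _compare_with_naive(spec, frame, template, x0, labels, bounds)
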