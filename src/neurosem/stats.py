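"""Association statistics used alongside the latent-variable models:
dependent-correlation (Williams/Steiger) tests, Fisher confidence intervals,
partial correlations, Breusch-Pagan heteroscedasticity tests,
heteroscedasticity-consistent regression, Levene tests and
Benjamini-Hochberg FDR control.

Standard procedures delegate to scipy/statsmodels; the Williams test and the
Fisher interval are closed forms implemented directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    df: float | tuple | None
    p_value: float
    method: str
    auxiliaries: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


def williams_test(r12: float, r13: float, r23: float, n: int) -> TestResult:
    """Williams (Steiger-form) t test for two dependent correlations sharing
    variable 1: H0 rho12 = rho13, t on n-3 degrees of freedom."""
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1 < r < 1:
            raise ValueError(f"{name}={r} outside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError("correlation triple is not positive definite")
    rbar = (r12 + r13) / 2
    denom = 2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), "Williams test for dependent correlations")


def fisher_ci(r: float, n: int, level: float = 0.95) -> TestResult:
    """Correlation with Fisher-z confidence interval and two-sided p."""
    if not -1 < r < 1:
        raise ValueError("r outside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z = np.arctanh(r)
    se = 1 / np.sqrt(n - 3)
    q = stats.norm.ppf((1 + level) / 2)
    lo, hi = np.tanh(z - q * se), np.tanh(z + q * se)
    p = 2 * stats.norm.sf(abs(z) / se)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return TestResult(float(t), n - 2, float(p), "Pearson correlation with Fisher CI",
                      {"r": float(r), "ci": (float(lo), float(hi)), "level": level})


def partial_correlation(x, y, control) -> TestResult:
    """Correlation of x and y after regressing both on the control variable."""
    x, y, c = (np.asarray(v, float) for v in (x, y, control))
    n = len(x)
    if n <= 4:
        raise ValueError("need more than 4 observations")
    for name, v in (("x", x), ("y", y), ("control", c)):
        if np.std(v) == 0:
            raise ValueError(f"{name} is constant")
    X = sm.add_constant(c)
    rx = sm.OLS(x, X).fit().resid
    ry = sm.OLS(y, X).fit().resid
    if (np.std(rx) <= 1e-10 * np.std(x)
            or np.std(ry) <= 1e-10 * np.std(y)):
        raise ValueError("zero residual variance: variable collinear with control")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), "partial correlation",
                      {"r": r})


def breusch_pagan(response, predictor, studentized: bool = True) -> TestResult:
    """Heteroscedasticity test of the response-on-predictor regression.

    The default is the studentized (Koenker) Lagrange-multiplier form,
    n * R^2 of the squared residuals on the predictor; ``studentized=False``
    gives the original normal-theory scaling.
    """
    y = np.asarray(response, float)
    x = np.asarray(predictor, float)
    if x.ndim == 1:
        x = x[:, None]
    if len(y) <= 10:
        raise ValueError("need more than 10 observations")
    if np.std(y) == 0:
        raise ValueError("constant response")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    if np.allclose(resid, 0):
        raise ValueError("zero residual variance")
    lm, lm_p, fstat, f_p = het_breuschpagan(resid, X)
    k = x.shape[1]
    if studentized:
        return TestResult(float(lm), k, float(lm_p), "Breusch-Pagan (Koenker studentized)")
    # original scaling: explained SS of u = e^2/sigma^2 on X, divided by 2
    u = resid**2 / np.mean(resid**2)
    fitu = sm.OLS(u, X).fit()
    stat = float(fitu.ess / 2)
    return TestResult(stat, k, float(stats.chi2.sf(stat, k)), "Breusch-Pagan (original)")


def robust_regression(response, predictors, hc_type: str = "HC1",
                      names: list[str] | None = None) -> list[TestResult]:
    """OLS point estimates with heteroscedasticity-consistent sandwich SEs.

    Returns one result per coefficient (constant first); point estimates are
    identical to OLS, only the standard errors differ.
    """
    if hc_type not in {"HC0", "HC1", "HC3"}:
        raise ValueError("hc_type must be HC0, HC1 or HC3")
    y = np.asarray(response, float)
    x = np.asarray(predictors, float)
    if x.ndim == 1:
        x = x[:, None]
    X = sm.add_constant(x)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    ols = sm.OLS(y, X).fit()
    rob = ols.get_robustcov_results(cov_type=hc_type)
    labels = names or [f"x{i}" for i in range(x.shape[1])]
    labels = ["const"] + labels
    out = []
    for i, lab in enumerate(labels):
        z = float(rob.tvalues[i])
        out.append(TestResult(z, None, float(rob.pvalues[i]),
                              f"robust regression ({hc_type})",
                              {"coef": float(rob.params[i]),
                               "se": float(rob.bse[i]),
                               "se_classical": float(ols.bse[i]),
                               "name": lab}))
    return out


def levene_test(values, groups) -> TestResult:
    """Levene's homogeneity-of-variance test on absolute deviations from the
    group means."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    stat, p = stats.levene(*samples, center="mean")
    df = (len(levels) - 1, len(values) - len(levels))
    return TestResult(float(stat), df, float(p), "Levene test (mean-centered)")


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
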