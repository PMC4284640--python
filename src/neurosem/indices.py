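"""Fit indices (RMSEA with noncentral CI, CFI, SRMR, AIC) and nested model
comparison with the Satorra-Bentler scaled difference test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class FitIndices:
    rmsea: float
    rmsea_ci90: tuple[float, float]
    cfi: float
    srmr: float | None
    aic: float | None


@dataclass
class ComparisonResult:
    chi2_diff_scaled: float
    df_diff: int
    p_value: float
    delta_aic: float
    scaling_correction: float


def _rmsea_point(chi2: float, df: int, nm1: float, n_groups: int = 1) -> float:
    if df <= 0:
        return 0.0
    return float(np.sqrt(n_groups * max(chi2 - df, 0.0) / (df * nm1)))


def _rmsea_ci(chi2: float, df: int, nm1: float, n_groups: int = 1,
              level: float = 0.90) -> tuple[float, float]:
    """CI by inverting the noncentral chi-square distribution."""
    if df <= 0:
        return (0.0, 0.0)
    lo_p = (1 + level) / 2  # 0.95
    hi_p = (1 - level) / 2  # 0.05

    def ncp_for(prob: float) -> float:
        # find lam with ncx2.cdf(chi2, df, lam) = prob
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2
        return optimize.brentq(f, 0.0, hi, xtol=1e-10)

    lam_lo = ncp_for(lo_p)
    lam_hi = ncp_for(hi_p)
    scale = lambda lam: float(np.sqrt(n_groups * lam / (df * nm1)))
    return (scale(lam_lo), scale(lam_hi))


def fit_indices(chi2: float, df: int, n: int,
                baseline: tuple[float, int] | None = None,
                residuals: np.ndarray | None = None,
                logL: float | None = None, npar: int | None = None,
                n_groups: int = 1) -> FitIndices:
    """Indices from summary quantities.

    ``baseline`` is (chi2_b, df_b) of the independence model; ``residuals``
    a matrix of standardized covariance residuals (including the diagonal)
    from which SRMR is the root mean square over the lower triangle.

    The RMSEA denominator uses the total sample size (df * n), which is what
    reproduces published values computed with standard SEM software.
    """
    nm1 = float(n)
    rmsea = _rmsea_point(chi2, df, nm1, n_groups)
    ci = _rmsea_ci(chi2, df, nm1, n_groups)
    cfi = np.nan
    if baseline is not None:
        chi2_b, df_b = baseline
        denom = max(chi2_b - df_b, chi2 - df, 0.0)
        cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    srmr = None
    if residuals is not None:
        i, j = np.tril_indices(residuals.shape[0])
        srmr = float(np.sqrt(np.mean(np.asarray(residuals)[i, j] ** 2)))
    aic = None
    if logL is not None and npar is not None:
        aic = -2.0 * logL + 2.0 * npar
    return FitIndices(rmsea, ci, float(cfi), srmr, aic)


def independence_baseline(Ss: list[np.ndarray], ns: list[int]) -> tuple[float, int]:
    """chi2 and df of the diagonal (free variances, zero covariances) model."""
    chi2 = 0.0
    p = Ss[0].shape[0]
    for S, n in zip(Ss, ns):
        sign, logdetS = np.linalg.slogdet(S)
        chi2 += (n - 1) * (np.sum(np.log(np.diag(S))) - logdetS)
    df = len(Ss) * p * (p - 1) // 2
    return float(chi2), df


def fit_indices_from_fit(chi2: float, df: int, ns: list[int],
                         Ss: list[np.ndarray], Sigmas: list[np.ndarray]):
    nm1 = float(sum(ns))
    G = len(ns)
    rmsea = _rmsea_point(chi2, df, nm1, G)
    ci = _rmsea_ci(chi2, df, nm1, G) if df > 0 else (0.0, 0.0)
    chi2_b, df_b = independence_baseline(Ss, ns)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    sq = 0.0
    wtot = 0.0
    for S, Sig, n in zip(Ss, Sigmas, ns):
        d = np.sqrt(np.diag(S))
        res = (S - Sig) / np.outer(d, d)
        i, j = np.tril_indices(S.shape[0])
        sq += (n - 1) * np.sum(res[i, j] ** 2) / len(i)
        wtot += n - 1
    srmr = float(np.sqrt(sq / wtot))
    return rmsea, ci, float(cfi), srmr


def compare_nested(fit_restricted, fit_full) -> ComparisonResult:
    """Satorra-Bentler scaled chi-square difference test.

    The restricted model must be nested in the full one; nesting is verified
    by label containment when the two specs share a label namespace, and by
    degrees of freedom otherwise.  A non-positive scaling correction falls
    back to the unscaled difference.
    """
    r, f = fit_restricted, fit_full
    if set(r.spec.observed) != set(f.spec.observed):
        raise ValueError("models are fit to different observed variables")
    df_diff = r.df - f.df
    if df_diff < 1:
        raise ValueError("models are not nested (df difference < 1)")
    rl, fl = r.spec.free_labels(), f.spec.free_labels()
    if rl <= fl and len(fl - rl) != df_diff:
        raise ValueError("free-parameter labels inconsistent with nesting")
    cd = (r.df * r.sb_scaling_factor - f.df * f.sb_scaling_factor) / df_diff
    if cd <= 0:
        cd = 1.0
    T = (r.chi2_ml - f.chi2_ml) / cd
    T = max(T, 0.0)
    p = float(stats.chi2.sf(T, df_diff))
    delta_aic = float(r.aic - f.aic)  # restricted model has the larger df
    return ComparisonResult(float(T), int(df_diff), p, delta_aic, float(cd))
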