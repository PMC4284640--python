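"""Maximum-likelihood estimation of covariance-structure models.

The fit function minimizes the ML discrepancy

    F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

(summed over groups with weights ``n_g - 1``), giving the likelihood-ratio
test statistic ``chi2 = sum_g (n_g - 1) F_g`` against the saturated model.
Optimization is quasi-Newton (L-BFGS-B with the analytic gradient, variance
parameters bounded below) followed by Fisher-scoring polish; non-converged
runs are retried from jittered starts.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .spec import CompiledModel, SemModelSpec


class FitError(RuntimeError):
    pass


class NotPositiveDefiniteError(FitError):
    def __init__(self, name: str):
        super().__init__(f"matrix {name!r} is not positive definite")
        self.name = name


# --------------------------------------------------------------------- basics
def _chol_logdet(a: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    try:
        c = linalg.cholesky(a, lower=True)
    except linalg.LinAlgError:
        raise NotPositiveDefiniteError(name)
    return c, 2.0 * float(np.sum(np.log(np.diag(c))))


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy between a sample and a model covariance."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    if S.shape != Sigma.shape:
        raise ValueError("dimension mismatch between S and Sigma")
    cS, logdetS = _chol_logdet(S, "S")
    cM, logdetM = _chol_logdet(Sigma, "Sigma")
    x = linalg.cho_solve((cM, True), S)
    return float(logdetM + np.trace(x) - logdetS - p)


def implied_covariance(model: CompiledModel | SemModelSpec, theta: np.ndarray,
                       group: int = 0) -> np.ndarray:
    """Model-implied covariance Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda' + Theta."""
    if isinstance(model, SemModelSpec):
        model = model.compile()
    lam, b, psi, th = model.matrices(np.asarray(theta, float), group)
    m = b.shape[0]
    try:
        g = linalg.solve(np.eye(m) - b, np.eye(m))
    except linalg.LinAlgError:
        raise FitError("(I - B) is singular: structural paths form a cycle")
    vn = g @ psi @ g.T
    return lam @ vn @ lam.T + th


# ------------------------------------------------------------------ internals
class _GroupWork:
    """Per-group quantities at a given theta."""

    __slots__ = ("lam", "b", "psi", "theta_m", "G", "C", "Vn", "Sigma",
                 "Sigma_inv", "logdet")

    def __init__(self, model: CompiledModel, theta: np.ndarray, group: int):
        self.lam, self.b, self.psi, self.theta_m = model.matrices(theta, group)
        m = self.b.shape[0]
        eye = np.eye(m)
        try:
            self.G = linalg.solve(eye - self.b, eye)
        except linalg.LinAlgError:
            raise FitError("(I - B) is singular: structural paths form a cycle")
        self.C = self.lam @ self.G
        self.Vn = self.G @ self.psi @ self.G.T
        self.Sigma = self.C @ self.psi @ self.C.T + self.theta_m
        c, self.logdet = _chol_logdet(self.Sigma, "Sigma(theta)")
        self.Sigma_inv = linalg.cho_solve((c, True), np.eye(self.Sigma.shape[0]))


def _objective_grad(model: CompiledModel, theta: np.ndarray,
                    Ss: list[np.ndarray], weights: list[float],
                    logdetS: list[float]):
    """Weighted discrepancy sum_g w_g F_g and its analytic gradient."""
    total = 0.0
    grad = np.zeros(model.npar)
    for g, (S, w) in enumerate(zip(Ss, weights)):
        wk = _GroupWork(model, theta, g)
        p = S.shape[0]
        SinvS = wk.Sigma_inv @ S
        F = wk.logdet + np.trace(SinvS) - logdetS[g] - p
        total += w * F
        # dF = tr(Wg dSigma), Wg = Sigma^-1 (Sigma - S) Sigma^-1
        Wg = wk.Sigma_inv - SinvS @ wk.Sigma_inv
        A = wk.lam @ wk.Vn                      # p x m
        WLV = Wg @ A                            # p x m
        grad_lam = 2.0 * WLV
        grad_b = 2.0 * (wk.C.T @ Wg @ A)        # m x m
        CtWC = wk.C.T @ Wg @ wk.C
        for k, fp in enumerate(model.params):
            acc = 0.0
            for (gg, mat, i, j) in fp.cells:
                if gg != g:
                    continue
                if mat == "lam":
                    acc += grad_lam[i, j]
                elif mat == "b":
                    acc += grad_b[i, j]
                elif mat == "psi":
                    acc += (1.0 if i == j else 2.0) * CtWC[i, j]
                else:
                    acc += (1.0 if i == j else 2.0) * Wg[i, j]
            grad[k] += w * acc
    return total, grad


def _dsigma(model: CompiledModel, theta: np.ndarray, group: int,
            extra_cells: list[tuple[str, int, int]] | None = None) -> np.ndarray:
    """Derivative matrices dSigma/dtheta_k for one group.

    Returns an array of shape (npar + n_extra, p, p); ``extra_cells`` appends
    derivatives for individual (matrix, i, j) cells, used for fixed-x
    pseudo-parameters and modification-index candidates.
    """
    wk = _GroupWork(model, theta, group)
    p = model.p
    A = wk.lam @ wk.Vn

    def cell_dsigma(mat: str, i: int, j: int) -> np.ndarray:
        d = np.zeros((p, p))
        if mat == "lam":
            d[i, :] += A[:, j]
            d[:, i] += A[:, j]
        elif mat == "b":
            outer = np.outer(wk.C[:, i], A[:, j])
            d += outer + outer.T
        elif mat == "psi":
            if i == j:
                d += np.outer(wk.C[:, i], wk.C[:, i])
            else:
                outer = np.outer(wk.C[:, i], wk.C[:, j])
                d += outer + outer.T
        else:  # theta
            d[i, j] += 1.0
            if i != j:
                d[j, i] += 1.0
        return d

    cells_per_param: list[np.ndarray] = []
    for fp in model.params:
        d = np.zeros((p, p))
        for (gg, mat, i, j) in fp.cells:
            if gg == group:
                d += cell_dsigma(mat, i, j)
        cells_per_param.append(d)
    for (mat, i, j) in (extra_cells or []):
        cells_per_param.append(cell_dsigma(mat, i, j))
    return np.array(cells_per_param)


def expected_information(model: CompiledModel, theta: np.ndarray,
                         weights: list[float]) -> np.ndarray:
    """Weighted expected information of the discrepancy: H_uv = sum_g w_g
    tr(Sigma^-1 dSigma_u Sigma^-1 dSigma_v)."""
    H = np.zeros((model.npar, model.npar))
    for g, w in enumerate(weights):
        wk = _GroupWork(model, theta, g)
        ds = _dsigma(model, theta, g)
        Q = np.einsum("ij,ujk,kl->uil", wk.Sigma_inv, ds, wk.Sigma_inv,
                      optimize=True)
        H += w * np.einsum("uij,vji->uv", Q, ds, optimize=True)
    return H


# -------------------------------------------------------------------- results
@dataclass
class ParameterVector:
    values: np.ndarray
    labels: list[str]
    lower: np.ndarray

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {l: float(v) for l, v in zip(self.labels, self.values)}


@dataclass
class FitResult:
    spec: SemModelSpec
    model: CompiledModel
    theta_hat: ParameterVector
    Sigma_hat: list[np.ndarray]
    S: list[np.ndarray]
    ns: list[int]
    logL: float
    logL_saturated: float
    npar: int
    df: int
    chi2_ml: float
    sb_scaling_factor: float
    chi2_scaled: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    cfi: float
    srmr: float
    aic: float
    se: np.ndarray | None
    se_robust: np.ndarray | None
    cov: np.ndarray | None
    cov_robust: np.ndarray | None
    converged: bool
    grad_norm: float
    warnings: list[str] = field(default_factory=list)
    from_raw_data: bool = False
    standardized_solution: dict[str, float] | None = None

    @property
    def n_total(self) -> int:
        return int(sum(self.ns))

    def estimate(self, label: str) -> float:
        return self.theta_hat[label]

    def z(self, label: str, robust: bool = True) -> float:
        se = self.se_robust if (robust and self.se_robust is not None) else self.se
        if se is None:
            raise FitError("standard errors unavailable")
        k = self.theta_hat.labels.index(label)
        return float(self.theta_hat.values[k] / se[k])

    def p_value(self) -> float:
        from scipy.stats import chi2 as chi2_dist
        if self.df <= 0:
            return 1.0
        return float(chi2_dist.sf(self.chi2_scaled, self.df))

    def summary(self) -> str:
        lines = [
            f"chi2={self.chi2_ml:.3f}  scaled chi2={self.chi2_scaled:.3f}  "
            f"(scaling factor {self.sb_scaling_factor:.3f})  df={self.df}",
            f"RMSEA={self.rmsea:.3f} ({self.rmsea_ci90[0]:.3f}-{self.rmsea_ci90[1]:.3f})  "
            f"CFI={self.cfi:.3f}  SRMR={self.srmr:.3f}  AIC={self.aic:.1f}",
            f"converged={self.converged} (|grad|={self.grad_norm:.2e})  n={self.ns}",
            "",
            f"{'parameter':<34}{'est':>10}{'se':>10}{'se.rob':>10}{'std':>10}",
        ]
        std = self.standardized_solution or {}
        for k, lab in enumerate(self.theta_hat.labels):
            se = f"{self.se[k]:.4f}" if self.se is not None else "-"
            ser = f"{self.se_robust[k]:.4f}" if self.se_robust is not None else "-"
            sv = f"{std[lab]:.4f}" if lab in std else "-"
            lines.append(f"{lab:<34}{self.theta_hat.values[k]:>10.4f}{se:>10}"
                         f"{ser:>10}{sv:>10}")
        if self.warnings:
            lines += [""] + [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "estimates": self.theta_hat.as_dict(),
            "se": None if self.se is None else dict(zip(self.theta_hat.labels, map(float, self.se))),
            "se_robust": None if self.se_robust is None else dict(zip(self.theta_hat.labels, map(float, self.se_robust))),
            "standardized": self.standardized_solution,
            "chi2": self.chi2_ml, "chi2_scaled": self.chi2_scaled,
            "scaling_factor": self.sb_scaling_factor,
            "df": self.df, "p": self.p_value(), "n": self.ns,
            "rmsea": self.rmsea, "rmsea_ci90": list(self.rmsea_ci90),
            "cfi": self.cfi, "srmr": self.srmr, "aic": self.aic,
            "logL": self.logL, "npar": self.npar,
            "converged": self.converged, "warnings": self.warnings,
        }


# ------------------------------------------------------------------- the fit
def _prepare_data(model: CompiledModel, data, group_var: str | None):
    """Return (Ss, ns, Zs) with Zs the centered raw data per group (or None)."""
    spec = model.spec
    if isinstance(data, pd.DataFrame):
        missing = [c for c in spec.observed if c not in data.columns]
        if missing:
            raise FitError(f"data is missing model columns: {missing}")
        if group_var is None and spec.group_var is not None:
            group_var = spec.group_var
        if model.n_groups > 1:
            if group_var is None or group_var not in data.columns:
                raise FitError("multigroup model needs a grouping column")
            levels = sorted(pd.unique(data[group_var]))
            if len(levels) != 2:
                raise FitError(f"grouping column must have exactly 2 levels, got {len(levels)}")
            frames = [data.loc[data[group_var] == lv, spec.observed] for lv in levels]
        else:
            frames = [data[spec.observed]]
        Ss, ns, Zs = [], [], []
        for fr in frames:
            x = fr.to_numpy(float)
            if np.isnan(x).any():
                raise FitError("missing values in model columns (complete cases required)")
            Ss.append(np.atleast_2d(np.cov(x, rowvar=False, ddof=1)))
            ns.append(x.shape[0])
            Zs.append(x - x.mean(axis=0))
        return Ss, ns, Zs
    # covariance input: (S, n) or [(S1, n1), (S2, n2)]
    if isinstance(data, tuple):
        data = [data]
    if len(data) != model.n_groups:
        raise FitError("number of covariance inputs does not match number of groups")
    Ss = [np.asarray(S, float) for S, _ in data]
    ns = [int(n) for _, n in data]
    for S in Ss:
        if S.shape != (model.p, model.p):
            raise FitError("covariance matrix does not match the model's observed variables")
        if not np.allclose(S, S.T, atol=1e-8):
            raise FitError("covariance input is not symmetric")
    return Ss, ns, None


def fit(spec: SemModelSpec, data, group_var: str | None = None,
        robust: bool = True, max_restarts: int = 5,
        se: bool = True) -> FitResult:
    """Fit a model to raw data (DataFrame) or covariance input ``(S, n)``.

    With raw data, robust (sandwich) standard errors and the Satorra-Bentler
    mean-scaled test statistic are computed; covariance-only input falls back
    to normal-theory quantities with a recorded downgrade note.
    """
    model = spec.compile()
    Ss, ns, Zs = _prepare_data(model, data, group_var)
    warn: list[str] = []
    if sum(ns) <= model.npar:
        warn.append(f"sample size {sum(ns)} does not exceed npar {model.npar}")

    # freeze fixed-x moments at the sample values
    if model.fixedx_obs_idx:
        for g, S in enumerate(Ss):
            idx = np.array(model.fixedx_obs_idx)
            model.set_fixed_x_values(g, S[np.ix_(idx, idx)])

    weights = [float(n - 1) for n in ns]
    wsum = sum(weights)
    logdetS = []
    for S in Ss:
        _, ld = _chol_logdet(S, "S")
        logdetS.append(ld)
    sds = np.sqrt(np.diag(Ss[0]))
    theta0 = model.start_values(sds)

    def fun(th):
        try:
            val, gr = _objective_grad(model, th, Ss, weights, logdetS)
        except NotPositiveDefiniteError:
            return 1e12, np.zeros_like(th)
        return val, gr

    bounds = [(lo if np.isfinite(lo) else None, None) for lo in model.lower]
    rng = np.random.default_rng(20140567)
    best = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 * (1 + 0.3 * rng.standard_normal(model.npar)) + 0.1 * rng.standard_normal(model.npar)
        start = np.maximum(start, model.lower + 1e-8, where=np.isfinite(model.lower),
                           out=start.copy())
        res = optimize.minimize(fun, start, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 3000, "ftol": 1e-14, "gtol": 1e-10})
        th, val, grad = _polish(model, res.x, Ss, weights, logdetS, wsum)
        gnorm = np.max(np.abs(_projected_grad(grad, th, model.lower))) / wsum
        if best is None or val < best[1] - 1e-12:
            best = (th, val, gnorm)
        if gnorm < 1e-6:
            best = min(best, (th, val, gnorm), key=lambda t: t[1])
            break
    theta_hat, obj, gnorm = best
    converged = bool(gnorm < 1e-6)
    if not converged:
        warn.append(f"optimizer did not reach gradient tolerance (|grad|={gnorm:.2e})")

    heywood = [model.labels[k] for k in range(model.npar)
               if model.params[k].is_variance
               and theta_hat[k] <= model.VARIANCE_FLOOR * 1.01]
    if heywood:
        warn.append(f"Heywood case: variance at lower bound for {heywood}")

    return _assemble_result(spec, model, theta_hat, obj, gnorm, converged,
                            Ss, ns, Zs, warn, robust=robust, want_se=se)


def _projected_grad(grad, theta, lower):
    g = grad.copy()
    at_bound = np.isfinite(lower) & (theta <= lower + 1e-10) & (g > 0)
    g[at_bound] = 0.0
    return g


def _polish(model, theta, Ss, weights, logdetS, wsum, iters: int = 60):
    """Fisher-scoring refinement with step-halving."""
    th = theta.copy()
    val, grad = _objective_grad(model, th, Ss, weights, logdetS)
    for _ in range(iters):
        pg = _projected_grad(grad, th, model.lower)
        if np.max(np.abs(pg)) / wsum < 1e-8:
            break
        H = expected_information(model, th, weights)
        H += 1e-10 * wsum * np.eye(model.npar)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.linalg.norm(grad + 1e-30)
        improved = False
        alpha = 1.0
        for _ in range(30):
            cand = th - alpha * step
            cand = np.maximum(cand, model.lower, where=np.isfinite(model.lower),
                              out=cand.copy())
            try:
                v2, g2 = _objective_grad(model, cand, Ss, weights, logdetS)
            except NotPositiveDefiniteError:
                alpha *= 0.5
                continue
            if v2 < val - 1e-14 * max(1.0, abs(val)):
                th, val, grad = cand, v2, g2
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    return th, val, grad


def _assemble_result(spec, model, theta_hat, obj, gnorm, converged,
                     Ss, ns, Zs, warn, robust=True, want_se=True) -> FitResult:
    from .indices import fit_indices_from_fit
    from .robust import sandwich_cov, sb_scaling
    from .standardize import standardized_solution

    weights = [float(n - 1) for n in ns]
    p = model.p
    Sigma_hat = [implied_covariance(model, theta_hat, g) for g in range(model.n_groups)]
    chi2_ml = float(obj)
    npar = model.npar
    df = spec.count_df()

    # Wishart-consistent log-likelihoods (chi2 = 2*(logL_sat - logL))
    logL = 0.0
    logL_sat = 0.0
    for g, (S, w) in enumerate(zip(Ss, weights)):
        _, ldS = _chol_logdet(S, "S")
        _, ldM = _chol_logdet(Sigma_hat[g], "Sigma")
        tr = np.trace(linalg.solve(Sigma_hat[g], S, assume_a="pos"))
        logL += -0.5 * w * (p * np.log(2 * np.pi) + ldM + tr)
        logL_sat += -0.5 * w * (p * np.log(2 * np.pi) + ldS + p)
    aic = -2.0 * logL + 2.0 * npar

    se_naive = se_rob = None
    cov_naive = cov_rob = None
    if want_se and converged:
        try:
            H = expected_information(model, theta_hat, weights)
            # T = 2(logL_sat - logL), so the observed information is H/2
            cov_naive = 2.0 * np.linalg.pinv(H)
            se_naive = np.sqrt(np.clip(np.diag(cov_naive), 0, None))
        except Exception as exc:  # pragma: no cover
            warn.append(f"naive standard errors failed: {exc}")
    scaling = 1.0
    if Zs is not None and robust and converged:
        try:
            cov_rob = sandwich_cov(model, theta_hat, Ss, ns, Zs)
            se_rob = np.sqrt(np.clip(np.diag(cov_rob), 0, None))
        except Exception as exc:
            warn.append(f"robust standard errors failed: {exc}")
        try:
            scaling = sb_scaling(model, theta_hat, Ss, ns, Zs, df)
        except Exception as exc:
            warn.append(f"Satorra-Bentler scaling failed: {exc}")
    elif Zs is None:
        warn.append("covariance-only input: robust corrections downgraded "
                    "(naive SEs, scaling factor 1)")
    chi2_scaled = chi2_ml / scaling if scaling > 0 else chi2_ml

    rmsea, ci, cfi, srmr = fit_indices_from_fit(chi2_ml, df, ns, Ss, Sigma_hat)
    if df == 0:
        warn.append("df=0: RMSEA undefined, reported as 0")

    std = None
    if converged:
        try:
            std = standardized_solution(model, theta_hat)
        except Exception as exc:
            warn.append(f"standardization failed: {exc}")

    return FitResult(
        spec=spec, model=model,
        theta_hat=ParameterVector(theta_hat, list(model.labels), model.lower.copy()),
        Sigma_hat=Sigma_hat, S=Ss, ns=[int(n) for n in ns],
        logL=float(logL), logL_saturated=float(logL_sat),
        npar=npar, df=df, chi2_ml=chi2_ml,
        sb_scaling_factor=float(scaling), chi2_scaled=float(chi2_scaled),
        rmsea=rmsea, rmsea_ci90=ci, cfi=cfi, srmr=srmr, aic=float(aic),
        se=se_naive, se_robust=se_rob, cov=cov_naive, cov_robust=cov_rob,
        converged=converged,
        grad_norm=float(gnorm), warnings=warn, from_raw_data=Zs is not None,
        standardized_solution=std,
    )
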