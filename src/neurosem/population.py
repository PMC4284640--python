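"""Synthetic lifespan-cohort generation.

The generator emulates a population-based adult-lifespan cohort in which two
executive-function factors (fluid intelligence, measured by four Cattell
sub-scores; multitasking, measured by two Hotel-task indices) decline with
age, four prefrontal structure measures (GMV in BA10 and the MD system, FA in
the forceps minor and anterior thalamic radiations) decline with age at
different rates, and a subset of the neural measures carries unique variance
of the cognitive factors.  Two control measures (GMV in the temporal pole, FA
in the forceps major) decline with age but carry no cognitive paths.

The population is a standardized structural equation model

    neural_k = a_k * age + e_k
    factor_j = c_j * age + sum_k gamma_jk * neural_k + zeta_j
    indicator_i = lambda_ij * factor_j + eps_i

calibrated so that (i) the observed age-neural correlations equal the target
values, (ii) the latent factor correlation equals its target, and (iii) the
correlation between age and Thomson regression factor scores (which is
attenuated relative to the latent correlation) equals the target age-factor
correlations.  Behavioural residual standard deviations may grow linearly
with age (variance-normalized, so the marginal covariance structure is
unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

NEURAL_VARS = ["gmv_ba10", "gmv_md", "fa_fm", "fa_atr"]
CONTROL_VARS = ["gmv_temporal_pole", "fa_forceps_major"]
ALL_NEURAL = NEURAL_VARS + CONTROL_VARS
CATTELL_VARS = ["cattell_1", "cattell_2", "cattell_3", "cattell_4"]
HOTEL_VARS = ["hotel_ttm", "hotel_ntasks"]
BEHAV_VARS = CATTELL_VARS + HOTEL_VARS

# raw-unit scales: mean, sd per column (hotel_ttm is stored raw: higher =
# more time misallocated = worse; its model orientation is reversed)
RAW_SCALES = {
    "cattell_1": (8.0, 2.2), "cattell_2": (7.0, 2.0),
    "cattell_3": (8.5, 2.3), "cattell_4": (5.5, 1.8),
    "hotel_ttm": (420.0, 130.0), "hotel_ntasks": (3.0, 0.6),
    "gmv_ba10": (0.55, 0.06), "gmv_md": (0.52, 0.05),
    "fa_fm": (0.45, 0.04), "fa_atr": (0.40, 0.035),
    "gmv_temporal_pole": (0.58, 0.06), "fa_forceps_major": (0.47, 0.045),
}


class CalibrationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Calibration targets and generator settings (all standardized scales)."""

    age_range: tuple[float, float] = (18.0, 88.0)
    age_to_neural: dict = field(default_factory=lambda: {
        "gmv_ba10": -0.20, "gmv_md": -0.18, "fa_fm": -0.77, "fa_atr": -0.51,
        "gmv_temporal_pole": -0.30, "fa_forceps_major": -0.55,
    })
    neural_to_fluid: dict = field(default_factory=lambda: {
        "gmv_ba10": 0.156, "fa_fm": 0.131,
    })
    neural_to_multitask: dict = field(default_factory=lambda: {
        "fa_atr": 0.155,
    })
    # residual (beyond-age) correlations between neural measures; keyed by
    # sorted variable pairs.  GM regions and WM tracts correlate within
    # modality well beyond what shared ageing induces.
    neural_residual_corr: dict = field(default_factory=lambda: {
        ("gmv_ba10", "gmv_md"): 0.50,
        ("fa_fm", "fa_atr"): 0.45,
        ("gmv_ba10", "gmv_temporal_pole"): 0.35,
        ("gmv_md", "gmv_temporal_pole"): 0.35,
        ("fa_fm", "fa_forceps_major"): 0.30,
        ("fa_atr", "fa_forceps_major"): 0.30,
    })
    # targets for corr(age, Thomson factor score); None disables attenuation
    # solving and treats them as latent correlations directly
    age_fluid_corr: float = -0.67
    age_multitask_corr: float = -0.29
    score_attenuation: bool = True
    factor_corr: float = 0.325
    loadings_fluid: tuple = (0.80, 0.75, 0.70, 0.65)
    loadings_multitask: tuple = (0.80, 0.55)  # (ttm reversed, ntasks)
    heteroscedasticity_slope: float = 0.5
    # direct age->factor overrides (bypass the correlation targets)
    age_to_fluid: float | None = None
    age_to_multitask: float | None = None

    def validate(self) -> None:
        for name, r in [("age_fluid_corr", self.age_fluid_corr),
                        ("age_multitask_corr", self.age_multitask_corr),
                        ("factor_corr", self.factor_corr),
                        *self.age_to_neural.items()]:
            if not -1 < r < 1:
                raise CalibrationError(f"correlation {name}={r} outside (-1, 1)")
        if self.heteroscedasticity_slope < 0:
            raise CalibrationError("heteroscedasticity_slope must be >= 0")


@dataclass
class PopulationModel:
    """The generating structural model, on the standardized scale."""

    loadings: dict  # indicator -> (factor, loading)
    structural_paths: dict  # (target, source) -> coefficient
    residual_variances: dict  # variable -> residual variance
    neural_residual_cov: dict  # (var1, var2) -> residual covariance
    factor_disturbance_cov: float
    age_distribution: tuple[float, float]
    heteroscedasticity_slope: float
    config: CohortConfig

    # observed ordering used by implied_covariance
    @property
    def observed(self) -> list[str]:
        return ["age"] + BEHAV_VARS + ALL_NEURAL

    @property
    def nodes(self) -> list[str]:
        return ["age"] + ALL_NEURAL + ["fluid", "multitask"]

    def matrices(self):
        """(Lambda, B, Psi, Theta) of the standardized population model."""
        obs, nodes = self.observed, self.nodes
        p, m = len(obs), len(nodes)
        oi = {o: i for i, o in enumerate(obs)}
        ni = {n: i for i, n in enumerate(nodes)}
        lam = np.zeros((p, m))
        for v in ["age"] + ALL_NEURAL:
            lam[oi[v], ni[v]] = 1.0
        for ind, (fac, lo) in self.loadings.items():
            lam[oi[ind], ni[fac]] = lo
        B = np.zeros((m, m))
        for (tgt, src), val in self.structural_paths.items():
            B[ni[tgt], ni[src]] = val
        psi = np.zeros((m, m))
        psi[ni["age"], ni["age"]] = 1.0
        for v in ALL_NEURAL + ["fluid", "multitask"]:
            psi[ni[v], ni[v]] = self.residual_variances[v]
        for (v1, v2), cov in self.neural_residual_cov.items():
            psi[ni[v1], ni[v2]] = psi[ni[v2], ni[v1]] = cov
        psi[ni["fluid"], ni["multitask"]] = self.factor_disturbance_cov
        psi[ni["multitask"], ni["fluid"]] = self.factor_disturbance_cov
        theta = np.zeros((p, p))
        for v in BEHAV_VARS:
            theta[oi[v], oi[v]] = self.residual_variances[v]
        return lam, B, psi, theta

    def implied_covariance(self) -> pd.DataFrame:
        """Standardized implied covariance (= correlation) of the observed variables."""
        lam, B, psi, theta = self.matrices()
        m = B.shape[0]
        G = np.linalg.solve(np.eye(m) - B, np.eye(m))
        sigma = lam @ G @ psi @ G.T @ lam.T + theta
        return pd.DataFrame(sigma, index=self.observed, columns=self.observed)

    def node_covariance(self) -> pd.DataFrame:
        lam, B, psi, _ = self.matrices()
        m = B.shape[0]
        G = np.linalg.solve(np.eye(m) - B, np.eye(m))
        vn = G @ psi @ G.T
        return pd.DataFrame(vn, index=self.nodes, columns=self.nodes)

    def to_yaml(self) -> str:
        doc = {
            "loadings": {k: [v[0], float(v[1])] for k, v in self.loadings.items()},
            "structural_paths": {f"{t}~{s}": float(v)
                                 for (t, s), v in self.structural_paths.items()},
            "residual_variances": {k: float(v) for k, v in self.residual_variances.items()},
            "neural_residual_cov": {f"{a}~~{b}": float(v)
                                    for (a, b), v in self.neural_residual_cov.items()},
            "factor_disturbance_cov": float(self.factor_disturbance_cov),
            "age_distribution": list(self.age_distribution),
            "heteroscedasticity_slope": float(self.heteroscedasticity_slope),
            "config": {
                k: ({"~~".join(kk): vv for kk, vv in v.items()}
                    if isinstance(v, dict) and any(isinstance(kk, tuple) for kk in v)
                    else (list(v) if isinstance(v, tuple) else v))
                for k, v in asdict(self.config).items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _thomson_attenuation(lam_b: np.ndarray, theta_b: np.ndarray,
                         phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (M, sd) with corr(age, score_k) = (M rho)_k / sd_k, where rho is
    the vector of latent age-factor correlations."""
    Phi = np.array([[1.0, phi], [phi, 1.0]])
    Sigma_b = lam_b @ Phi @ lam_b.T + np.diag(theta_b)
    W = np.linalg.solve(Sigma_b, lam_b @ Phi)  # 6 x 2 Thomson weights
    M = W.T @ lam_b  # 2 x 2
    sd = np.sqrt(np.diag(W.T @ Sigma_b @ W))
    return M, sd


def build_population_model(config: CohortConfig | None = None) -> PopulationModel:
    """Solve the calibration for a :class:`PopulationModel`.

    The solution is analytic (a 2x2 linear solve for the latent age-factor
    correlations plus variance bookkeeping); a non-positive-definite implied
    covariance raises :class:`CalibrationError` naming the offending leading
    minor.
    """
    config = config or CohortConfig()
    config.validate()
    lam_f = np.asarray(config.loadings_fluid, float)
    lam_m = np.asarray(config.loadings_multitask, float)
    lam_b = np.zeros((6, 2))
    lam_b[:4, 0] = lam_f
    lam_b[4:, 1] = lam_m
    theta_b = 1.0 - np.concatenate([lam_f, lam_m]) ** 2
    if np.any(theta_b <= 0):
        raise CalibrationError("a loading >= 1 leaves no residual variance")

    a = np.array([config.age_to_neural[v] for v in ALL_NEURAL])
    g1 = np.array([config.neural_to_fluid.get(v, 0.0) for v in ALL_NEURAL])
    g2 = np.array([config.neural_to_multitask.get(v, 0.0) for v in ALL_NEURAL])

    phi = config.factor_corr
    targets = np.array([config.age_fluid_corr, config.age_multitask_corr])
    if config.age_to_fluid is not None and config.age_to_multitask is not None:
        c = np.array([config.age_to_fluid, config.age_to_multitask])
        rho = None
    else:
        if config.score_attenuation:
            M, sd = _thomson_attenuation(lam_b, theta_b, phi)
            rho = np.linalg.solve(M / sd[:, None], targets)
        else:
            rho = targets.copy()
        if np.any(np.abs(rho) >= 1):
            raise CalibrationError(
                f"latent age-factor correlations {rho} leave the unit interval; "
                "weaken the targets or strengthen the loadings")
        c = rho - np.array([g1 @ a, g2 @ a])

    # residual covariance of the neural variables (beyond shared age)
    k = len(ALL_NEURAL)
    e_sd = np.sqrt(1.0 - a ** 2)
    E = np.diag(1.0 - a ** 2)
    idx = {v: i for i, v in enumerate(ALL_NEURAL)}
    resid_cov = {}
    for (v1, v2), r in config.neural_residual_corr.items():
        if not -1 < r < 1:
            raise CalibrationError(f"neural residual correlation {v1}~{v2}={r} outside (-1, 1)")
        i, j = idx[v1], idx[v2]
        cov = r * e_sd[i] * e_sd[j]
        E[i, j] = E[j, i] = cov
        resid_cov[(v1, v2)] = float(cov)
    # correlation matrix of (age, neural)
    R = np.empty((k + 1, k + 1))
    R[0, 0] = 1.0
    R[0, 1:] = R[1:, 0] = a
    R[1:, 1:] = np.outer(a, a) + E
    b1 = np.concatenate([[c[0]], g1])
    b2 = np.concatenate([[c[1]], g2])
    q1, q2 = b1 @ R @ b1, b2 @ R @ b2
    psi_f, psi_m = 1.0 - q1, 1.0 - q2
    if psi_f <= 0 or psi_m <= 0:
        raise CalibrationError(
            f"factor disturbance variance non-positive (fluid={psi_f:.4f}, "
            f"multitask={psi_m:.4f}): paths explain more than unit variance")
    zeta_cov = phi - b1 @ R @ b2
    if abs(zeta_cov) >= np.sqrt(psi_f * psi_m):
        raise CalibrationError(
            "factor correlation target incompatible with the structural paths "
            f"(needed disturbance correlation {zeta_cov / np.sqrt(psi_f * psi_m):.3f})")

    loadings = {v: ("fluid", lam_f[i]) for i, v in enumerate(CATTELL_VARS)}
    loadings["hotel_ttm"] = ("multitask", lam_m[0])
    loadings["hotel_ntasks"] = ("multitask", lam_m[1])
    paths = {(v, "age"): a[i] for i, v in enumerate(ALL_NEURAL)}
    paths[("fluid", "age")] = c[0]
    paths[("multitask", "age")] = c[1]
    for i, v in enumerate(ALL_NEURAL):
        if g1[i]:
            paths[("fluid", v)] = g1[i]
        if g2[i]:
            paths[("multitask", v)] = g2[i]
    resid = {v: 1.0 - a[i] ** 2 for i, v in enumerate(ALL_NEURAL)}
    resid["fluid"], resid["multitask"] = psi_f, psi_m
    for i, v in enumerate(BEHAV_VARS):
        resid[v] = theta_b[i]

    model = PopulationModel(
        loadings=loadings, structural_paths=paths, residual_variances=resid,
        neural_residual_cov=resid_cov,
        factor_disturbance_cov=float(zeta_cov),
        age_distribution=config.age_range,
        heteroscedasticity_slope=config.heteroscedasticity_slope,
        config=config,
    )
    sigma = model.implied_covariance().to_numpy()
    _check_pd(sigma, model.observed)
    return model


def _check_pd(sigma: np.ndarray, names: list[str]) -> None:
    for k in range(1, sigma.shape[0] + 1):
        if np.linalg.det(sigma[:k, :k]) <= 0:
            raise CalibrationError(
                f"implied covariance not positive definite: leading minor of "
                f"order {k} (through {names[k - 1]!r}) is non-positive")


def generate_cohort(model: PopulationModel, n: int = 567, seed: int = 0,
                    n_outliers: int = 0) -> pd.DataFrame:
    """Draw a cohort table from the population model.

    Identical seeds give bit-identical tables.  ``n_outliers`` rows receive a
    planted extreme neural value (|z| about 6) for screening tests.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    rng = np.random.default_rng(seed)
    lo, hi = model.age_distribution
    age = rng.uniform(lo, hi, n)
    z_age = (age - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12.0))

    vals = {"age": z_age}
    E = np.diag([model.residual_variances[v] for v in ALL_NEURAL])
    nidx = {v: i for i, v in enumerate(ALL_NEURAL)}
    for (v1, v2), cov in model.neural_residual_cov.items():
        E[nidx[v1], nidx[v2]] = E[nidx[v2], nidx[v1]] = cov
    eps = rng.multivariate_normal(np.zeros(len(ALL_NEURAL)), E, size=n,
                                  method="cholesky")
    for v in ALL_NEURAL:
        a = model.structural_paths[(v, "age")]
        vals[v] = a * z_age + eps[:, nidx[v]]
    zeta_cov = np.array([
        [model.residual_variances["fluid"], model.factor_disturbance_cov],
        [model.factor_disturbance_cov, model.residual_variances["multitask"]],
    ])
    zeta = rng.multivariate_normal([0.0, 0.0], zeta_cov, size=n,
                                   method="cholesky")
    for j, f in enumerate(["fluid", "multitask"]):
        acc = model.structural_paths[(f, "age")] * z_age + zeta[:, j]
        for v in ALL_NEURAL:
            acc = acc + model.structural_paths.get((f, v), 0.0) * vals[v]
        vals[f] = acc

    slope = model.heteroscedasticity_slope
    u = (age - lo) / (hi - lo)
    mult = (1.0 + slope * u) / np.sqrt(1.0 + slope + slope ** 2 / 3.0)
    for v in BEHAV_VARS:
        fac, lo_ = model.loadings[v]
        theta = model.residual_variances[v]
        if v == "hotel_ntasks":
            # quantization-noise accounting: integer rounding adds ~1/12 raw
            # variance, removed here so the rounded column matches the model
            sd_raw = RAW_SCALES[v][1]
            theta = theta - 1.0 / (12.0 * sd_raw ** 2)
            if theta <= 0:
                raise CalibrationError("hotel_ntasks residual too small for rounding noise")
        vals[v] = lo_ * vals[fac] + np.sqrt(theta) * mult * rng.standard_normal(n)

    df = pd.DataFrame({"participant_id": np.arange(1, n + 1), "age": age})
    for v in BEHAV_VARS + ALL_NEURAL:
        mean, sd = RAW_SCALES[v]
        if v == "hotel_ttm":  # stored raw: higher = worse
            col = mean - sd * vals[v]
            col = np.clip(col, 0.0, 960.0)
        elif v == "hotel_ntasks":
            col = np.clip(np.rint(mean + sd * vals[v]), 1, 5)
        else:
            col = mean + sd * vals[v]
            if v.startswith("fa_"):
                col = np.clip(col, 1e-6, 1 - 1e-6)
        df[v] = col

    if n_outliers:
        rows = rng.choice(n, size=n_outliers, replace=False)
        for k, r in enumerate(rows):
            col = ALL_NEURAL[k % len(ALL_NEURAL)]
            mean, sd = df[col].mean(), df[col].std()
            df.loc[r, col] = mean + (6.0 if k % 2 == 0 else -6.0) * sd
    return df


def screen_outliers(table: pd.DataFrame, z_threshold: float = 4.0,
                    columns: list[str] | None = None) -> pd.DataFrame:
    """Drop rows whose neural measures are extreme.

    z-scores use the input table's own mean/SD per column, in a single pass
    (no re-screening of the reduced table).
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    cols = columns if columns is not None else [c for c in ALL_NEURAL
                                                if c in table.columns]
    keep = np.ones(len(table), bool)
    for c in cols:
        x = table[c].to_numpy(float)
        sd = x.std(ddof=1)
        if sd <= 1e-12 * (1.0 + abs(x.mean())):
            raise ValueError(f"column {c!r} has zero standard deviation")
        keep &= np.abs((x - x.mean()) / sd) <= z_threshold
    return table.loc[keep].reset_index(drop=True)
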