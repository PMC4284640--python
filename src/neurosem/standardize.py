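"""Fully standardized solutions and delta-method covariances for them."""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .spec import CompiledModel


def _node_and_obs_sd(model: CompiledModel, theta: np.ndarray, group: int):
    lam, b, psi, th = model.matrices(theta, group)
    m = b.shape[0]
    G = linalg.solve(np.eye(m) - b, np.eye(m))
    Vn = G @ psi @ G.T
    Sigma = lam @ Vn @ lam.T + th
    sd_node = np.sqrt(np.diag(Vn))
    sd_obs = np.sqrt(np.diag(Sigma))
    if np.any(sd_node <= 0) or np.any(sd_obs <= 0):
        raise ValueError("zero implied variance: cannot standardize")
    return lam, b, psi, th, sd_node, sd_obs


def standardized_solution(model: CompiledModel, theta: np.ndarray) -> dict[str, float]:
    """Every declared loading/path/(co)variance rescaled to unit-SD variables.

    Keys are parameter labels; in multigroup models per-group values carry an
    ``@g<k>`` suffix unless the parameter itself is tied across groups (tied
    parameters may still standardize differently per group, in which case the
    suffixed keys are used).
    """
    spec = model.spec
    out: dict[str, float] = {}
    per_group: list[dict[str, float]] = []
    oi = {o: i for i, o in enumerate(model.obs)}
    ni = {n: i for i, n in enumerate(model.nodes)}
    for g in range(model.n_groups):
        lam, b, psi, th, sd_node, sd_obs = _node_and_obs_sd(model, theta, g)
        vals: dict[str, float] = {}
        for e in spec._completed_entries():
            mat, i, j = model._locate(e, oi, ni)
            if mat == "lam":
                v = lam[i, j] * sd_node[j] / sd_obs[i]
            elif mat == "b":
                v = b[i, j] * sd_node[j] / sd_node[i]
            elif mat == "psi":
                v = psi[i, j] / (sd_node[i] * sd_node[j])
            else:
                v = th[i, j] / (sd_obs[i] * sd_obs[j])
            vals[e.label] = float(v)
        per_group.append(vals)
    if model.n_groups == 1:
        return per_group[0]
    for g, vals in enumerate(per_group):
        for lab, v in vals.items():
            out[f"{lab}@g{g}"] = v
    return out


def standardized_values(model: CompiledModel, theta: np.ndarray,
                        labels: list[str], group: int = 0) -> np.ndarray:
    """Standardized estimates for selected labels (single group)."""
    sol = standardized_solution(model, theta) if model.n_groups == 1 else None
    if sol is None:
        full = standardized_solution(model, theta)
        sol = {k[: -len(f"@g{group}")]: v for k, v in full.items()
               if k.endswith(f"@g{group}")}
    return np.array([sol[l] for l in labels])


def standardized_cov(fit, labels: list[str], group: int = 0,
                     robust: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method covariance of standardized estimates.

    The Jacobian of the standardization map is obtained by central finite
    differences on the free-parameter vector; the parameter covariance is the
    robust sandwich when available, otherwise the naive ML covariance.
    """
    model = fit.model
    theta = fit.theta_hat.values
    cov = fit.cov_robust if (robust and fit.cov_robust is not None) else fit.cov
    if cov is None:
        raise ValueError("fit carries no parameter covariance")
    est = standardized_values(model, theta, labels, group)
    J = np.zeros((len(labels), model.npar))
    h = 1e-6 * np.maximum(1.0, np.abs(theta))
    for k in range(model.npar):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] -= h[k]
        J[:, k] = (standardized_values(model, tp, labels, group)
                   - standardized_values(model, tm, labels, group)) / (2 * h[k])
    return est, J @ cov @ J.T
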