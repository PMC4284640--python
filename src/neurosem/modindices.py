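"""Modification indices: 1-df score tests for fixed or equality-constrained
parameters, with expected parameter changes.

For a candidate direction ``e`` in the expanded (per-cell) parameter space,
with ``g`` the gradient of the test statistic T = sum_g (n_g-1) F_g along
``e`` at the restricted optimum and ``H`` the expected Hessian of T over the
free parameters augmented with ``e``,

    MI  = g^2 / (2 * (H_ee - H_ef H_ff^-1 H_fe))
    EPC = -g / (H_ee - H_ef H_ff^-1 H_fe)

which approximates the chi-square drop from freeing the candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import FitResult, _GroupWork, _dsigma, expected_information
from .spec import CompiledModel


@dataclass
class ModificationIndex:
    parameter_id: str
    mi: float
    expected_parameter_change: float

    def __repr__(self):  # pragma: no cover
        return (f"ModificationIndex({self.parameter_id!r}, mi={self.mi:.3f}, "
                f"epc={self.expected_parameter_change:.4f})")


def _candidate_cells(model: CompiledModel):
    """Enumerate sensible fixed cells and equality-split directions.

    Yields (name, group, [(matrix, i, j), ...]) where the cell list carries
    the derivative direction (always a single cell here).
    """
    spec = model.spec
    occupied: set[tuple[int, str, int, int]] = set()
    for fp in model.params:
        for (g, mat, i, j) in fp.cells:
            occupied.add((g, mat, i, j))
            if mat in ("psi", "theta"):
                occupied.add((g, mat, j, i))
    fixedx = set(model.fixedx_idx)
    lat = range(len(spec.latents))
    struct_obs_cols = set(range(len(spec.latents), model.m))
    existing_b = {(g, i, j) for (g, m_, i, j) in occupied if m_ == "b"}
    base = model._base

    for g in range(model.n_groups):
        gsuf = f"@g{g}" if model.n_groups > 1 else ""
        # cross-loadings: indicator x latent cells fixed at zero
        for i in range(model.p):
            for j in lat:
                if (g, "lam", i, j) in occupied or base[g]["lam"][i, j] != 0:
                    continue
                if model.obs[i] in spec.structural_observed:
                    continue
                yield (f"lam:{model.obs[i]}~{model.nodes[j]}{gsuf}", g,
                       ("lam", i, j))
        # structural paths among nodes
        for i in range(model.m):
            for j in range(model.m):
                if i == j or i in fixedx:
                    continue
                if (g, "b", i, j) in occupied or base[g]["b"][i, j] != 0:
                    continue
                if (g, j, i) in existing_b or base[g]["b"][j, i] != 0:
                    continue  # avoid trivially reversed paths
                yield (f"b:{model.nodes[i]}~{model.nodes[j]}{gsuf}", g,
                       ("b", i, j))
        # residual covariances
        for i in range(model.p):
            for j in range(i):
                if (g, "theta", i, j) in occupied or base[g]["theta"][i, j] != 0:
                    continue
                if (model.obs[i] in spec.structural_observed
                        or model.obs[j] in spec.structural_observed):
                    continue
                yield (f"theta:{model.obs[i]}~~{model.obs[j]}{gsuf}", g,
                       ("theta", i, j))
        # disturbance covariances among non-fixed-x nodes
        for i in range(model.m):
            for j in range(i):
                if i in fixedx or j in fixedx:
                    continue
                if (g, "psi", i, j) in occupied or base[g]["psi"][i, j] != 0:
                    continue
                yield (f"psi:{model.nodes[i]}~~{model.nodes[j]}{gsuf}", g,
                       ("psi", i, j))


def _equality_split_candidates(model: CompiledModel):
    """Directions that free one cell of a multi-cell (tied) parameter."""
    for fp in model.params:
        if len(fp.cells) < 2:
            continue
        # only ties across groups or across distinct cells are splittable
        for (g, mat, i, j) in fp.cells:
            name = f"split:{fp.label}[{mat}:{i},{j}@g{g}]"
            yield (name, g, (mat, i, j))


def modification_indices(fit: FitResult, include_splits: bool = True,
                         sort: bool = True) -> list[ModificationIndex]:
    """Score-test modification indices for a converged fit."""
    if not fit.converged:
        raise ValueError("modification indices need a converged fit")
    model = fit.model
    theta = fit.theta_hat.values
    weights = [float(n - 1) for n in fit.ns]
    H_ff = expected_information(model, theta, weights)
    H_ff_inv = np.linalg.pinv(H_ff)

    cands = list(_candidate_cells(model))
    if include_splits:
        cands += list(_equality_split_candidates(model))
    if not cands:
        return []

    # per-group gradient weight matrices and cross-information
    out: list[ModificationIndex] = []
    per_group = []
    for g, w in enumerate(weights):
        wk = _GroupWork(model, theta, g)
        Wg = wk.Sigma_inv - wk.Sigma_inv @ fit.S[g] @ wk.Sigma_inv
        ds_free = _dsigma(model, theta, g)
        Q_free = np.einsum("ij,ujk,kl->uil", wk.Sigma_inv, ds_free,
                           wk.Sigma_inv, optimize=True)
        per_group.append((wk, Wg, Q_free))

    for name, g, cell in cands:
        wk, Wg, Q_free = per_group[g]
        d = _dsigma(model, theta, g, extra_cells=[cell])[-1]
        grad = weights[g] * float(np.sum(Wg * d))
        Qc = wk.Sigma_inv @ d @ wk.Sigma_inv
        H_cc = weights[g] * float(np.sum(Qc * d.T))
        H_cf = weights[g] * np.einsum("uij,ji->u", Q_free, d, optimize=True)
        denom = H_cc - H_cf @ H_ff_inv @ H_cf
        if denom <= 1e-6 * max(H_cc, 1e-12):
            continue  # direction not identified at this solution
        mi = grad * grad / (2.0 * denom)
        epc = -grad / denom
        out.append(ModificationIndex(name, float(mi), float(epc)))
    if sort:
        out.sort(key=lambda m: -m.mi)
    return out
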