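"""Robust (sandwich) standard errors and the Satorra-Bentler scaled statistic.

Both corrections need raw data: the sandwich uses the empirical covariance of
per-observation score contributions, the mean-scaling factor uses the
empirical fourth-moment matrix of the centered data.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .spec import CompiledModel


def duplication_matrix(p: int) -> np.ndarray:
    """D with D @ vech(A) = vec(A) for symmetric A (lower-triangle vech)."""
    rows, cols = np.tril_indices(p)
    pstar = len(rows)
    D = np.zeros((p * p, pstar))
    for k, (i, j) in enumerate(zip(rows, cols)):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D


def vech(a: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(a.shape[0])
    return a[i, j]


def _group_quantities(model: CompiledModel, theta: np.ndarray, group: int):
    from .fit import _GroupWork, _dsigma
    wk = _GroupWork(model, theta, group)
    # fixed-x moments behave as trivially estimated parameters; append their
    # derivative matrices so projections account for them
    extra = []
    for a_i, i in enumerate(model.fixedx_idx):
        for j in model.fixedx_idx[:a_i + 1]:
            extra.append(("psi", max(i, j), min(i, j)))
    ds = _dsigma(model, theta, group, extra_cells=extra)
    return wk, ds


def _scores(model: CompiledModel, theta: np.ndarray, Zs: list[np.ndarray]):
    """Per-observation score contributions of the Gaussian log-likelihood."""
    out = []
    for g, Z in enumerate(Zs):
        wk, ds = _group_quantities(model, theta, g)
        ds = ds[: model.npar]
        Sinv = wk.Sigma_inv
        n = Z.shape[0]
        s = np.empty((n, model.npar))
        for u in range(model.npar):
            R = Sinv @ ds[u] @ Sinv
            quad = np.einsum("ni,ij,nj->n", Z, R, Z, optimize=True)
            s[:, u] = 0.5 * (quad - np.trace(Sinv @ ds[u]))
        out.append(s)
    return out


def sandwich_cov(model: CompiledModel, theta: np.ndarray,
                 Ss: list[np.ndarray], ns: list[int],
                 Zs: list[np.ndarray]) -> np.ndarray:
    """Huber-White covariance A^-1 B A^-1 with A the expected information."""
    from .fit import expected_information
    # observed information of -logL is half the discrepancy Hessian
    A = 0.5 * expected_information(model, theta, [float(n) for n in ns])
    B = np.zeros((model.npar, model.npar))
    for s in _scores(model, theta, Zs):
        B += s.T @ s
    Ainv = np.linalg.pinv(A)
    return Ainv @ B @ Ainv


def fourth_moment_matrix(Z: np.ndarray) -> np.ndarray:
    """Empirical covariance (divisor n) of vech(z z') -- the Gamma matrix."""
    n, p = Z.shape
    i, j = np.tril_indices(p)
    W = Z[:, i] * Z[:, j]
    W = W - W.mean(axis=0)
    return (W.T @ W) / n


def sb_scaling(model: CompiledModel, theta: np.ndarray,
               Ss: list[np.ndarray], ns: list[int], Zs: list[np.ndarray],
               df: int) -> float:
    """Mean-scaling factor c = tr(U Gamma) / df.

    U is the normal-theory residual weight matrix after projecting out the
    model derivatives (including the fixed-x pseudo-parameters); Gamma is the
    empirical fourth-moment matrix.  Groups enter block-diagonally with their
    moment derivatives scaled by sqrt(n_g - 1).
    """
    if df <= 0:
        return 1.0
    G = model.n_groups
    p = model.p
    D = duplication_matrix(p)
    Ws, Gammas, Deltas = [], [], []
    n_extra = len(model.fixedx_idx) * (len(model.fixedx_idx) + 1) // 2
    for g in range(G):
        wk, ds = _group_quantities(model, theta, g)
        Sinv = wk.Sigma_inv
        Wg = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
        Ws.append(Wg)
        Gammas.append(fourth_moment_matrix(Zs[g]))
        # Delta columns: free params then this group's fixed-x pseudo-params
        cols = [vech(d) for d in ds]
        Delta_free = np.array(cols[: model.npar]).T
        Delta_fx = np.array(cols[model.npar:]).T if n_extra else np.zeros((len(cols[0]), 0))
        Deltas.append((Delta_free, Delta_fx))

    pstar = p * (p + 1) // 2
    total_cols = model.npar + n_extra * G
    bigW = linalg.block_diag(*Ws)
    bigGamma = linalg.block_diag(*Gammas)
    bigDelta = np.zeros((pstar * G, total_cols))
    for g in range(G):
        w = np.sqrt(ns[g] - 1.0)
        r = slice(g * pstar, (g + 1) * pstar)
        bigDelta[r, : model.npar] = w * Deltas[g][0]
        if n_extra:
            c0 = model.npar + g * n_extra
            bigDelta[r, c0: c0 + n_extra] = w * Deltas[g][1]
    WD = bigW @ bigDelta
    middle = np.linalg.pinv(bigDelta.T @ WD)
    U = bigW - WD @ middle @ WD.T
    c = float(np.trace(U @ bigGamma)) / df
    if not np.isfinite(c) or c <= 0:
        return 1.0
    return c
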