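"""Independent oracles for the covariance-structure engine.

Everything here deliberately avoids the package's linear-algebra paths:
implied covariances are assembled with explicit Python loops, and maximum
likelihood is obtained by numerically minimizing the discrepancy with
finite-difference gradients on a naive per-model parameterization.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def loop_matmul(A, B):
    """Matrix product with explicit loops (oracle-grade, no numpy dot)."""
    n, k = len(A), len(A[0])
    m = len(B[0])
    out = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for t in range(k):
                s += A[i][t] * B[t][j]
            out[i][j] = s
    return np.array(out)


def loop_implied_cov(lam, b, psi, theta):
    """Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta by direct steps."""
    m = b.shape[0]
    G = np.linalg.inv(np.eye(m) - b)  # the one permitted solver call
    t1 = loop_matmul(lam.tolist(), G.tolist())
    t2 = loop_matmul(t1.tolist(), psi.tolist())
    t3 = loop_matmul(t2.tolist(), G.T.tolist())
    t4 = loop_matmul(t3.tolist(), lam.T.tolist())
    return t4 + theta


def ml_f(S, Sigma):
    sign, ld = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e10
    _, lds = np.linalg.slogdet(S)
    return float(ld + np.trace(np.linalg.solve(Sigma, S)) - lds - S.shape[0])


def gaussian_loglik(S, n, Sigma):
    """Wishart-consistent Gaussian log-likelihood of a sample covariance."""
    p = S.shape[0]
    _, ld = np.linalg.slogdet(Sigma)
    tr = np.trace(np.linalg.solve(Sigma, S))
    return -0.5 * (n - 1) * (p * np.log(2 * np.pi) + ld + tr)


def naive_fit(S, n, template, x0, bounds=None):
    """Minimize (n-1) * F_ML over a naive parameterization.

    ``template(x)`` returns the implied covariance for parameter vector x.
    Two-stage numeric optimization (BFGS with 2-point gradients, then
    Nelder-Mead polish); returns (x_hat, chi2).
    """
    fun = lambda x: ml_f(S, template(x))
    r1 = minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                  options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    r2 = minimize(fun, r1.x, method="Nelder-Mead",
                  options={"maxiter": 200000, "maxfev": 200000,
                           "xatol": 1e-12, "fatol": 1e-15})
    best = r2 if r2.fun <= r1.fun else r1
    return best.x, (n - 1) * best.fun
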