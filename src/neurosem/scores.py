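"""Thomson (regression-method) factor scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from .fit import FitResult


def factor_scores(fit: FitResult, data: pd.DataFrame,
                  latents: list[str] | None = None) -> pd.DataFrame:
    """Regression-method factor scores: E[eta | y] weights Cov(eta, y) Sigma^-1.

    ``data`` must contain the model's observed columns on the scale the model
    was fitted on; scores are centered at zero.
    """
    model = fit.model
    if model.n_groups != 1:
        raise ValueError("factor scores are computed per single-group fit")
    theta = fit.theta_hat.values
    lam, b, psi, th = model.matrices(theta, 0)
    m = b.shape[0]
    G = linalg.solve(np.eye(m) - b, np.eye(m))
    Vn = G @ psi @ G.T
    Sigma = lam @ Vn @ lam.T + th
    names = latents or fit.spec.latents
    idx = [model.nodes.index(l) for l in names]
    weights = linalg.solve(Sigma, lam @ Vn[:, idx], assume_a="pos")  # p x k
    X = data[fit.spec.observed].to_numpy(float)
    Z = X - X.mean(axis=0)
    return pd.DataFrame(Z @ weights, columns=names, index=data.index)
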