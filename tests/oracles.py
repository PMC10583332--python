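"""Independent oracles shared by the test modules."""

import numpy as np
from scipy.special import expit


def penalized_loglik_at(X, y, beta):
    """Direct evaluation of the Jeffreys-penalized logistic log-likelihood."""
    eta = X @ beta
    p = expit(eta)
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    info = X.T @ (X * (p * (1 - p))[:, None])
    return ll + 0.5 * np.linalg.slogdet(info)[1]


def grid_search_penalized(X, y, bounds, steps=41, refinements=4):
    """Coarse-to-fine grid maximizer of the penalized likelihood surface."""
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    best = None
    for _ in range(refinements):
        axes = [np.linspace(lo[j], hi[j], steps) for j in range(len(bounds))]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.array([penalized_loglik_at(X, y, b) for b in flat])
        best = flat[np.argmax(vals)]
        span = (hi - lo) / (steps - 1)
        lo, hi = best - 2 * span, best + 2 * span
    return best
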