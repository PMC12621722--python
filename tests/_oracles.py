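"""Independent numerical oracles used by the test suite.

Kept deliberately separate from the package: these recompute quantities by
brute force (dense-grid integration, exact enumeration) so that the
particle-filter implementation can be checked against them.
"""

import numpy as np
import pandas as pd

from pglearn import PGParams
from pglearn.trials import RegressorMatrix


def make_1d_problem(T=8, alpha=0.3, beta=-0.2, qdiag=0.01, sigma=0.25,
                    w1_mean=0.2, w1_sd=0.5, seed=0):
    """A tiny one-regressor learning problem with simulated choices.

    The single covariate is a bias (x = 1); the correct side alternates so
    rewards depend on the choice.  Returns (trials, regressors, params).
    """
    rng = np.random.default_rng(seed)
    params = PGParams(variant="scalar_pg", m=1, alpha=alpha, beta=beta,
                      qdiag=qdiag, sigma=sigma, sigma_day=sigma,
                      w1_mean=w1_mean, w1_sd=w1_sd)
    w = rng.normal(w1_mean, w1_sd)
    side = np.where(rng.random(T) < 0.5, 1, -1)
    y = np.empty(T, int)
    r = np.empty(T)
    ws = np.empty(T)
    for t in range(T):
        ws[t] = w
        p = 1 / (1 + np.exp(-w))
        y[t] = 1 if rng.random() < p else -1
        r[t] = 1.0 if y[t] == side[t] else 0.0
        p_y = p if y[t] > 0 else 1 - p
        drift = alpha * (r[t] - beta) * (1 - p_y) * y[t] - qdiag * w
        w = w + drift + sigma * rng.normal()
    trials = pd.DataFrame({
        "session": np.ones(T, int), "trial": np.arange(T),
        "contrast_left": np.where(side < 0, 1.0, 0.0),
        "contrast_right": np.where(side > 0, 1.0, 0.0),
        "correct_side": np.where(side > 0, "R", "L"),
        "choice": np.where(y > 0, "R", "L"),
        "reward": r})
    reg = RegressorMatrix(x=np.ones((T, 1)), names=("bias",),
                          session=np.ones(T, int))
    return trials, reg, params


def grid_marginal_loglik(trials, params, lo=-8.0, hi=8.0, n=3001):
    """Dense-grid quadrature of the 1-D marginal choice log-likelihood.

    Exact (up to quadrature error) evaluation of the latent-weight
    integral: alternate Bernoulli updates with Gaussian transition
    convolutions over a fixed grid.  Only supports the one-regressor
    scalar model from :func:`make_1d_problem`.
    """
    y = np.where(trials["choice"].to_numpy() == "R", 1, -1)
    r = trials["reward"].to_numpy(float)
    T = y.size
    alpha = float(params.alpha[0])
    beta = float(params.beta[0])
    q = float(params.qdiag[0])
    sigma = float(params.sigma[0])

    grid = np.linspace(lo, hi, n)
    dw = grid[1] - grid[0]
    dens = np.exp(-0.5 * ((grid - params.w1_mean[0]) / params.w1_sd) ** 2)
    dens /= dens.sum() * dw
    loglik = 0.0
    for t in range(T):
        p = 1 / (1 + np.exp(-grid))
        lik = p if y[t] > 0 else 1 - p
        incr = (dens * lik).sum() * dw
        loglik += np.log(incr)
        dens = dens * lik / incr
        if t < T - 1:
            p_y = p if y[t] > 0 else 1 - p
            g = grid + alpha * (r[t] - beta) * (1 - p_y) * y[t] - q * grid
            # transition kernel N(grid' - g(w), sigma^2)
            diff = grid[:, None] - g[None, :]
            k = np.exp(-0.5 * (diff / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
            dens = (k * dens[None, :]).sum(axis=1) * dw
            dens /= dens.sum() * dw
    return float(loglik)
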