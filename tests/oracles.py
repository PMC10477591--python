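"""Independent numerical oracles the implementation is checked against."""

import numpy as np


def grid_poe_moments(mus, sigmas, n_points=200001, span=12.0):
    """Mean and variance of prior × experts by normalizing the pointwise
    density product on a fine 1-D grid (trapezoid integration)."""
    mus = np.asarray(mus, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    x = np.linspace(-span, span, n_points)
    log_density = -0.5 * x ** 2  # the N(0, 1) prior, up to a constant
    for mu, sigma in zip(mus, sigmas):
        log_density = log_density - 0.5 * ((x - mu) / sigma) ** 2
    density = np.exp(log_density - log_density.max())
    z = np.trapezoid(density, x)
    mean = np.trapezoid(x * density, x) / z
    var = np.trapezoid((x - mean) ** 2 * density, x) / z
    return mean, var


def monte_carlo_kl(mu, sigma, n_draws, rng):
    """KL(q || N(0, I)) estimated as the sample mean of log q(z) - log p(z)
    under z ~ q; returns (estimate, standard error)."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    z = mu + sigma * rng.standard_normal((n_draws, mu.size))
    log_q = (-0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma)).sum(axis=1)
    log_p = (-0.5 * z ** 2).sum(axis=1)
    diffs = log_q - log_p  # the (2*pi) terms cancel
    return diffs.mean(), diffs.std(ddof=1) / np.sqrt(n_draws)


def concordance_auc(scores, labels):
    """Pairwise-concordance AUC: fraction of positive-negative pairs ranked
    correctly, ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)
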