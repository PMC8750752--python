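"""Deterministic grid-quadrature posterior for small cells.

Independent cross-check for the MCMC sampler: on cells with at most two
active disease groups the posterior over (mu_d, log sigma2_d) is a 2- or
4-dimensional integral that can be evaluated on a dense tensor-product
grid. The integration walks the same parameterization as the sampler
(x = log sigma2 with its Normal prior, the exact transform of the
LogNormal prior on sigma2), so both target the identical posterior
measure.

The grid self-refines: after a wide first pass, each axis is re-gridded
to the weighted mean +/- 8 weighted sds and the integral recomputed.
"""

from __future__ import annotations

import numpy as np

from .severity import PriorSpec, _CellStats

__all__ = ["grid_posterior"]


def _evaluate(stats: _CellStats, prior: PriorSpec, axes: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Log-target tensor over the outer product of 1-D axes (mu..., x...)."""
    D = stats.n_params
    mesh = np.meshgrid(*axes, indexing="ij", sparse=True)
    mu_axes, x_axes = mesh[:D], mesh[D:]
    logp = np.zeros(np.broadcast_shapes(*(a.shape for a in mesh)))
    # likelihood accumulated pattern by pattern to keep broadcasting cheap
    for p_vec, n_p, s_p, ss_p in zip(stats.patterns, stats.n_p, stats.s_p, stats.ss_p):
        m = sum(a * w for a, w in zip(mu_axes, p_vec))
        v = sum(np.exp(a) * w for a, w in zip(x_axes, p_vec))
        logp = logp - 0.5 * (n_p * (np.log(2 * np.pi * v)) + (ss_p - 2 * s_p * m + n_p * m * m) / v)
    for a in mu_axes:
        logp = logp - 0.5 * ((a - prior.mu_loc) / prior.mu_sd) ** 2
    for a in x_axes:
        logp = logp - 0.5 * ((a - prior.logvar_loc) / prior.logvar_sd) ** 2
    return logp, mesh


def _moments(logp: np.ndarray, axes: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    w = np.exp(logp - logp.max())
    total = w.sum()
    means, sds = [], []
    for k, axis in enumerate(axes):
        other = tuple(i for i in range(logp.ndim) if i != k)
        w_k = w.sum(axis=other)
        m = (w_k * axis).sum() / total
        v = (w_k * (axis - m) ** 2).sum() / total
        means.append(m)
        sds.append(np.sqrt(max(v, 1e-300)))
    return np.array(means), np.array(sds)


def grid_posterior(
    y: np.ndarray,
    indicators: np.ndarray,
    prior: PriorSpec = PriorSpec(),
    n_points: int = 60,
    n_refine: int = 2,
) -> dict:
    """Posterior means of (mu_d, sigma2_d) for a cell with <= 2 active diseases.

    Returns a dict with ``diseases``, ``mu_mean`` and ``var_mean`` arrays.
    Raises ValueError for cells with more than two active diseases (the
    grid would be 6-dimensional or larger; use the sampler there).
    """
    stats = _CellStats(y, indicators)
    D = stats.n_params
    if D > 2:
        raise ValueError("grid quadrature supports at most 2 active diseases")

    # wide initial axes from a crude per-disease moment fit
    P, n_p, s_p = stats.patterns, stats.n_p, stats.s_p
    xtx = (P.T * n_p) @ P + 1e-2 * np.eye(D)
    mu0 = np.linalg.solve(xtx, P.T @ s_p)
    m = P @ mu0
    rss = (stats.ss_p - 2 * s_p * m + n_p * m * m).sum()
    v0 = max(rss / stats.n_obs, 1e-3)
    n_d = n_p @ P  # records involving each disease
    half_mu = 12.0 * np.sqrt(v0 / np.maximum(n_d, 1.0)) + 0.5
    axes = [np.linspace(mu0[j] - half_mu[j], mu0[j] + half_mu[j], n_points) for j in range(D)]
    half_x = 12.0 * np.sqrt(2.0 / np.maximum(n_d, 1.0)) + 1.5
    axes += [np.linspace(np.log(v0) - half_x[j], np.log(v0) + half_x[j], n_points) for j in range(D)]

    for _ in range(n_refine):
        logp, _mesh = _evaluate(stats, prior, axes)
        means, sds = _moments(logp, axes)
        axes = [np.linspace(mu - 8 * sd, mu + 8 * sd, n_points) for mu, sd in zip(means, sds)]

    logp, _mesh = _evaluate(stats, prior, axes)
    w = np.exp(logp - logp.max())
    total = w.sum()
    mu_mean = np.empty(D)
    var_mean = np.empty(D)
    for j in range(D):
        other = tuple(i for i in range(logp.ndim) if i != j)
        mu_mean[j] = (w.sum(axis=other) * axes[j]).sum() / total
        k = D + j
        other = tuple(i for i in range(logp.ndim) if i != k)
        var_mean[j] = (w.sum(axis=other) * np.exp(axes[k])).sum() / total
    return {"diseases": stats.diseases, "mu_mean": mu_mean, "var_mean": var_mean}
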