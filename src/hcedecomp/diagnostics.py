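"""MCMC convergence diagnostics."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["rhat"]


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (classic PSRF).

    ``draws`` has shape (n_chains, n_draws). Each chain is split in half
    (an odd trailing draw is dropped), giving 2C sequences of length n;
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-sequence
    variance and B the between-sequence variance. This is the classic
    split-R-hat, not the rank-normalized variant.

    Chains with zero total variance are a degenerate limit: the statistic
    is defined as 1.0 and a warning is emitted.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws >= 2) draw matrix")
    c, n = draws.shape
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    scale = float(np.mean(split * split))
    if w <= 1e-12 * max(scale, 1e-300):  # constant chains up to rounding residue
        if np.allclose(split, split.ravel()[0]):
            warnings.warn("zero-variance chains: R-hat defined as 1.0", stacklevel=2)
            return 1.0
        return np.inf
    b = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))
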