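"""MCMC convergence diagnostics: rank-normalized split R-hat and bulk/tail
effective sample size.

Implements the rank-normalization methodology that has become the standard
for reporting chain convergence: chains are split in half, draws are
replaced by normal scores of their pooled ranks, and the classic potential
scale reduction factor / autocorrelation-based ESS are computed on the
transformed draws.  The reported R-hat is the maximum of the bulk
(rank-normalized) and folded (around the median) statistics; tail ESS is
the minimum ESS of the 5% and 95% quantile exceedance indicators.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = ["rhat", "ess_bulk", "ess_tail", "DiagnosticsError"]


class DiagnosticsError(ValueError):
    """Raised for degenerate inputs (constant chains, too few draws)."""


def _validate(chains: np.ndarray) -> np.ndarray:
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise DiagnosticsError("chains must be a 2-D (chain, draw) array")
    m, n = x.shape
    if n < 4:
        raise DiagnosticsError("need at least 4 draws per chain")
    return x


def _split(chains: np.ndarray) -> np.ndarray:
    m, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, half : 2 * half]])


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    """Normal scores of pooled ranks (average ranks for ties)."""
    flat = chains.ravel()
    ranks = rankdata(flat, method="average")
    size = flat.size
    z = ndtri((ranks - 3.0 / 8.0) / (size + 1.0 / 4.0))
    return z.reshape(chains.shape)


def _rhat_base(chains: np.ndarray) -> float:
    """Classic split-R-hat on already-split chains."""
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    chain_vars = chains.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        raise DiagnosticsError("R-hat undefined for constant chains")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat (max of bulk and folded variants).

    ``chains`` has shape (n_chains, n_draws); at least 2 chains and 4 draws
    are required.  Values near 1 indicate the chains are mixing over the
    same distribution.
    """
    x = _validate(chains)
    if x.shape[0] < 2:
        raise DiagnosticsError("R-hat requires at least 2 chains")
    if np.allclose(x, x.ravel()[0]):
        raise DiagnosticsError("R-hat undefined for constant chains")
    bulk = _rhat_base(_rank_normalize(_split(x)))
    folded = _rhat_base(_rank_normalize(_split(np.abs(x - np.median(x)))))
    return max(bulk, folded)


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance per chain via FFT; shape (m, n)."""
    m, n = x.shape
    centered = x - x.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real
    return acov / n


def _ess_base(chains: np.ndarray) -> float:
    """Autocorrelation ESS on already-split chains (Geyer initial sequence)."""
    m, n = chains.shape
    if np.allclose(chains, chains.ravel()[0]):
        raise DiagnosticsError("ESS undefined for constant chains")
    acov = _autocovariance(chains)
    chain_vars = acov[:, 0] * n / (n - 1.0)
    mean_var = chain_vars.mean()
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += chains.mean(axis=1).var(ddof=1)
    if var_plus <= 0:
        raise DiagnosticsError("ESS undefined: zero variance")

    # estimated autocorrelations, rho[0] = 1 by construction
    rho = np.zeros(n)
    rho[0] = 1.0
    rho[1:] = 1.0 - (mean_var - acov[:, 1:].mean(axis=0)) / var_plus

    # Geyer initial positive sequence: keep pair sums while positive
    rho_hat = np.zeros(n)
    rho_hat[0] = rho[0]
    rho_hat[1] = rho[1]
    even, odd = rho[0], rho[1]
    t = 1
    while t < n - 3 and (even + odd) > 0.0:
        even, odd = rho[t + 1], rho[t + 2]
        if even + odd >= 0:
            rho_hat[t + 1] = even
            rho_hat[t + 2] = odd
        t += 2
    max_t = t - 2
    if even > 0:
        rho_hat[max_t + 1] = even

    # Geyer initial monotone sequence: pair sums never increase
    t = 1
    while t <= max_t - 2:
        if rho_hat[t + 1] + rho_hat[t + 2] > rho_hat[t - 1] + rho_hat[t]:
            rho_hat[t + 1] = (rho_hat[t - 1] + rho_hat[t]) / 2.0
            rho_hat[t + 2] = rho_hat[t + 1]
        t += 2

    size = m * n
    tau = -1.0 + 2.0 * float(np.sum(rho_hat[: max_t + 2]))
    tau = max(tau, 1.0 / np.log10(size))
    return float(min(size / tau, size * np.log10(size)))


def ess_bulk(chains: np.ndarray) -> float:
    """Bulk effective sample size (rank-normalized split chains)."""
    x = _validate(chains)
    return _ess_base(_rank_normalize(_split(x)))


def ess_tail(chains: np.ndarray) -> float:
    """Tail effective sample size.

    Minimum of the ESS of the 5% and 95% quantile indicator sequences,
    reflecting sampling stability in the distribution tails.
    """
    x = _validate(chains)
    out = []
    for q in (0.05, 0.95):
        indicator = (x <= np.quantile(x, q)).astype(float)
        out.append(_ess_base(_rank_normalize(_split(indicator))))
    return float(min(out))


def ess(chains: np.ndarray) -> Tuple[float, float]:
    """(bulk ESS, tail ESS) of a (chain, draw) array."""
    return ess_bulk(chains), ess_tail(chains)
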