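"""MCMC convergence diagnostics: split R-hat, autocorrelation ESS, MCSE.

Implements the classic potential scale reduction factor on split chains and
the Stan-style effective sample size built from Geyer's initial monotone
positive sequence of autocorrelations.  The convergence contract used
throughout the package is: R-hat <= 1.01, ESS > 400 and MCSE below 5% of
the posterior standard deviation for every parameter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_chains", "rhat", "ess", "mcse"]


def _as_chains(draws) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    if draws.ndim != 2:
        raise ValueError("draws must be a (chains, iterations) array for one parameter")
    return draws


def split_chains(draws) -> np.ndarray:
    """Split each chain into halves (dropping one draw if the length is odd)."""
    draws = _as_chains(draws)
    n = draws.shape[1] // 2
    return np.vstack([draws[:, :n], draws[:, n : 2 * n]])


def rhat(draws) -> float:
    """Split-chain potential scale reduction factor.

    A single chain is accepted and diagnosed on its split halves.  Constant
    chains have no within variance and return NaN.
    """
    chains = split_chains(draws)
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least 2 draws per split chain")
    if np.ptp(chains) == 0.0:
        return float("nan")  # constant chains: no within variance
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess(draws) -> float:
    """Effective sample size from combined-chain autocorrelations.

    Follows the Stan reference estimator: per-chain autocovariances (FFT),
    combined with the between-chain variance, truncated by Geyer's initial
    monotone positive-pair sequence.  A zero-variance chain is degenerate
    and reports 0.
    """
    chains = split_chains(draws)
    m, n = chains.shape
    if n < 4:
        raise ValueError("need at least 4 draws per split chain for ESS")
    if np.ptp(chains) == 0.0:
        return 0.0  # zero-variance chain is degenerate
    W = chains.var(axis=1, ddof=1).mean()
    means = chains.mean(axis=1)
    var_plus = (n - 1) / n * W + (means.var(ddof=1) if m > 1 else 0.0)
    if var_plus == 0.0 or W == 0.0:
        return 0.0

    acov = np.array([_autocov(c) for c in chains])  # (m, n)
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0

    # Geyer initial positive/monotone sequence on paired sums
    # tau = -1 + 2 * sum_k P_k with P_k = rho_{2k} + rho_{2k+1}
    pair_sums = []
    prev = np.inf
    for k in range(n // 2):
        s = rho[2 * k] + (rho[2 * k + 1] if 2 * k + 1 < n else 0.0)
        if s < 0:
            break
        s = min(s, prev)  # enforce monotonicity
        prev = s
        pair_sums.append(s)
    tau = max(-1.0 + 2.0 * sum(pair_sums), 1e-12)
    return float(m * n / tau)


def mcse(draws) -> float:
    """Monte-Carlo standard error of the mean, sd / sqrt(ESS)."""
    chains = _as_chains(draws)
    n_eff = ess(chains)
    if n_eff <= 0:
        return 0.0
    return float(chains.std(ddof=1) / np.sqrt(n_eff))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT."""
    n = x.size
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real / n
    return acov
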