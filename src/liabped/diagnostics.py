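"""Single-chain MCMC diagnostics: effective sample size and HPD intervals.

ESS uses the autocorrelation-time estimator n / (1 + 2 * sum rho_k) with
Geyer's initial-positive-sequence truncation: consecutive autocorrelations
are summed in pairs Gamma_m = rho_{2m} + rho_{2m+1}, and the sum stops at
the first non-positive pair.  HPD intervals are the empirical
shortest-interval (Chen-Shao) construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["PosteriorSummary", "effective_sample_size", "hpd_interval", "summarize"]

MIN_CHAIN = 100


@dataclass
class PosteriorSummary:
    parameter: str
    posterior_mean: float
    hpd_low: float
    hpd_high: float
    ess: float
    hpd_level: float = 0.95

    def to_dict(self) -> dict:
        return asdict(self)


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocorrelation via FFT."""
    n = len(x)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    return acov / acov[0]


def effective_sample_size(samples) -> float:
    """ESS of a (possibly autocorrelated) chain.

    A constant chain is degenerate: its ESS is reported as n with a warning
    flag rather than an error.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d chain")
    n = len(x)
    if n < MIN_CHAIN:
        raise ValueError(f"chain too short for ESS ({n} < {MIN_CHAIN})")
    if np.ptp(x) == 0:
        warnings.warn("degenerate (constant) chain; ESS reported as n", stacklevel=2)
        return float(n)
    rho = _autocorr(x)
    # Geyer initial positive sequence on pair sums
    tau = 0.0
    max_pairs = (n - 1) // 2
    for m in range(max_pairs):
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0:
            break
        tau += gamma
    tau = 2.0 * tau - 1.0  # Gamma_0 counts rho_0 = 1 once
    tau = max(tau, 1e-12)
    return float(n / tau)


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest empirical interval containing ``level`` of the samples.

    Scans windows of ceil(level * n) consecutive order statistics and keeps
    the narrowest (leftmost on ties).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < MIN_CHAIN:
        raise ValueError(f"chain too short for HPD ({n} < {MIN_CHAIN})")
    k = int(np.ceil(level * n))
    k = min(k, n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (leftmost) minimum
    return float(x[i]), float(x[i + k - 1])


def summarize(samples, name: str = "parameter", hpd_level: float = 0.95) -> PosteriorSummary:
    """Posterior mean, HPD interval and ESS of one stored chain."""
    x = np.asarray(samples, dtype=float)
    if len(x) < MIN_CHAIN:
        raise ValueError(f"chain too short to summarise ({len(x)} < {MIN_CHAIN})")
    lo, hi = hpd_interval(x, hpd_level)
    if np.ptp(x) == 0:
        ess = float(len(x))
    else:
        ess = effective_sample_size(x)
    return PosteriorSummary(
        parameter=name,
        posterior_mean=float(x.mean()),
        hpd_low=lo,
        hpd_high=hi,
        ess=ess,
        hpd_level=hpd_level,
    )
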