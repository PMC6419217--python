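"""Shared time-correlation container and FFT correlation kernels.

Every estimator in the package (MSD, velocity ACF, dipole ACF, H-bond
survival) reports its result as a :class:`CorrelationSeries`: a uniformly
spaced lag axis in ps, one value per lag, and bookkeeping about how many
time origins and independent blocks went into each point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

__all__ = ["CorrelationSeries", "autocorr_sum", "autocorrelation"]


@dataclass
class CorrelationSeries:
    """A lag-indexed real correlation function.

    lags      : ps, uniform, starting at 0
    values    : correlation at each lag (units depend on the source signal)
    n_origins : number of time origins averaged at each lag
    n_blocks  : number of independent trajectory blocks averaged
    meta      : free-form provenance (estimator name, selection, flags)
    """

    lags: np.ndarray
    values: np.ndarray
    n_origins: np.ndarray | None = None
    n_blocks: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have matching shapes")
        if self.lags.size == 0 or self.lags[0] != 0.0:
            raise ValueError("lag axis must start at 0")
        if self.lags.size > 1:
            d = np.diff(self.lags)
            if np.any(np.abs(d - d[0]) > 1e-9 * max(d[0], 1.0)):
                raise ValueError("lag axis must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")
        if self.n_origins is not None:
            self.n_origins = np.asarray(self.n_origins, dtype=int)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0

    def normalized(self) -> "CorrelationSeries":
        """Divide by the lag-0 value (which must be nonzero)."""
        c0 = self.values[0]
        if c0 == 0:
            raise ValueError("cannot normalize: zero value at lag 0")
        return CorrelationSeries(
            lags=self.lags,
            values=self.values / c0,
            n_origins=self.n_origins,
            n_blocks=self.n_blocks,
            meta={**self.meta, "normalized": True},
        )


def autocorr_sum(x: np.ndarray) -> np.ndarray:
    """Raw origin sums S[k] = sum_t x[t]*x[t+k] for k = 0..n-1, via FFT.

    This is the Wiener–Khinchin kernel shared by the MSD and ACF
    estimators; dividing S[k] by (n-k) gives the multiple-origin average.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    nfft = next_fast_len(2 * n)
    f = rfft(x, nfft, axis=0)
    s = irfft(f * np.conj(f), nfft, axis=0)[:n]
    return s


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Multiple-origin autocorrelation <x(0)x(k)> of a 1-D or (n, ...) signal.

    Components beyond the first axis (e.g. Cartesian components, atoms) are
    summed, matching the dot-product correlations used throughout.
    """
    s = autocorr_sum(x)
    n = s.shape[0]
    if s.ndim > 1:
        s = s.reshape(n, -1).sum(axis=1)
    return s / (n - np.arange(n))
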