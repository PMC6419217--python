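"""Translational diffusion and the vibrational density of states.

The mean-square displacement uses the Einstein relation D = MSD slope / 6;
the VDOS is the one-sided cosine transform of the velocity autocorrelation
function.  Both correlation estimators average over all time origins via
the Wiener–Khinchin FFT decomposition and are checked elsewhere against
O(N²) brute-force sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.fft import dct

from .correlation import CorrelationSeries, autocorr_sum
from .trajectory import Trajectory

__all__ = [
    "DiffusionResult",
    "VDOSSpectrum",
    "msd",
    "diffusion_coefficient",
    "vacf",
    "vdos",
]


@dataclass(frozen=True)
class DiffusionResult:
    """Diffusion coefficient from a linear MSD fit.

    d          : Å²/ps
    d_relative : d/d0 if a reference d0 was supplied, else None
    fit_window : (t_min, t_max) ps actually used
    fit_r2     : R² of the unweighted linear fit
    """

    d: float
    fit_window: tuple[float, float]
    fit_r2: float
    d_relative: float | None = None


@dataclass(frozen=True)
class VDOSSpectrum:
    """Vibrational density of states on a uniform THz grid (arbitrary units)."""

    frequencies: np.ndarray
    intensities: np.ndarray


def _resolve_selection(n_atoms: int, atom_selection) -> np.ndarray:
    if atom_selection is None:
        return np.arange(n_atoms)
    sel = np.asarray(atom_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("atom selection is empty")
    return sel


def _max_lag(n_frames: int, max_lag: int | None) -> int:
    # cap at half the series length to bound origin-count imbalance
    cap = max(1, n_frames // 2)
    if max_lag is None:
        return cap
    return min(int(max_lag), n_frames - 1)


def msd(
    trajectory: Trajectory,
    atom_selection=None,
    max_lag: int | None = None,
) -> CorrelationSeries:
    """Mean-square displacement ⟨|r(t0+τ)−r(t0)|²⟩, Å².

    Averages over every time origin and every selected atom using the FFT
    decomposition MSD(τ) = S1(τ) − 2·S2(τ), where S2 is the position
    autocorrelation.  The trajectory must be unwrapped; if any per-step jump
    exceeds half the box a warning is emitted (the estimator cannot repair
    wrapped data).
    """
    sel = _resolve_selection(trajectory.n_atoms, atom_selection)
    pos = trajectory.positions[:, sel, :]  # (T, A, 3)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least two frames for an MSD")
    steps = np.abs(np.diff(pos, axis=0))
    half_box = trajectory.boxes[1:, None, :] / 2.0
    if np.any(steps > half_box):
        warnings.warn(
            "per-step displacement exceeds half the box: trajectory looks "
            "wrapped; unwrap() it before computing an MSD",
            stacklevel=2,
        )
    lag_count = _max_lag(n, max_lag) + 1

    # S2 via FFT, summed over atoms and components
    s2 = autocorr_sum(pos.reshape(n, -1)).sum(axis=1)
    # S1 via the telescoping sum
    d2 = (pos**2).reshape(n, -1).sum(axis=1)  # Σ_atoms |r(t)|²
    q = 2.0 * d2.sum()
    s1 = np.empty(n)
    for m in range(n):
        if m > 0:
            q -= d2[m - 1] + d2[n - m]
        s1[m] = q
    n_origins = n - np.arange(n)
    msd_vals = (s1 - 2.0 * s2) / (n_origins * sel.size)
    msd_vals[0] = 0.0  # exact by definition; guards rounding
    lags = np.arange(lag_count) * trajectory.dt
    return CorrelationSeries(
        lags=lags,
        values=msd_vals[:lag_count],
        n_origins=n_origins[:lag_count],
        meta={"estimator": "msd", "n_atoms": int(sel.size)},
    )


def diffusion_coefficient(
    msd_series: CorrelationSeries,
    fit_window: tuple[float, float] | None = None,
    d0: float | None = None,
) -> DiffusionResult:
    """Einstein relation: D = slope/6 of an unweighted linear MSD fit.

    ``fit_window`` is a (t_min, t_max) interval in ps; the default covers
    10–50% of the maximum lag (reported in the result so the choice is
    always visible).  ``d0`` reports d/d0 alongside, e.g. against a bulk
    reference.
    """
    lags = msd_series.lags
    if fit_window is None:
        fit_window = (0.1 * lags[-1], 0.5 * lags[-1])
    lo, hi = fit_window
    mask = (lags >= lo) & (lags <= hi) & (lags > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"fit window {fit_window} contains {int(mask.sum())} points; need >= 3"
        )
    res = stats.linregress(lags[mask], msd_series.values[mask])
    d = res.slope / 6.0
    return DiffusionResult(
        d=float(d),
        fit_window=(float(lags[mask][0]), float(lags[mask][-1])),
        fit_r2=float(res.rvalue**2),
        d_relative=None if d0 is None else float(d / d0),
    )


def vacf(
    trajectory: Trajectory,
    atom_selection=None,
    max_lag: int | None = None,
    normalize: bool = False,
) -> CorrelationSeries:
    """Velocity autocorrelation ⟨v(t0)·v(t0+τ)⟩ averaged over origins and
    selected atoms ((Å/ps)², or unitless if ``normalize``)."""
    vel = trajectory.velocities
    if vel is None:
        raise ValueError("trajectory has no velocities")
    sel = _resolve_selection(trajectory.n_atoms, atom_selection)
    v = vel[:, sel, :]
    n = v.shape[0]
    lag_count = _max_lag(n, max_lag) + 1
    s = autocorr_sum(v.reshape(n, -1)).sum(axis=1)
    n_origins = n - np.arange(n)
    vals = s / (n_origins * sel.size)
    series = CorrelationSeries(
        lags=np.arange(lag_count) * trajectory.dt,
        values=vals[:lag_count],
        n_origins=n_origins[:lag_count],
        meta={"estimator": "vacf", "n_atoms": int(sel.size)},
    )
    return series.normalized() if normalize else series


def vdos(vacf_series: CorrelationSeries, window: str | None = None) -> VDOSSpectrum:
    """VDOS(ν) as the real one-sided Fourier transform of the VACF.

    Computed as a type-I cosine transform (even extension of the VACF) times
    dt/2, so the frequency grid runs from 0 to the Nyquist frequency
    1/(2·dt) in steps of 1/(2·M·dt), with M = n_lags − 1.  ``window="hann"``
    applies a half-Hann taper before the transform to suppress truncation
    ripple; the default is the raw transform.
    """
    c = vacf_series.values.copy()
    if c.size < 2:
        raise ValueError("need at least two lags for a spectrum")
    dt = vacf_series.dt
    if window is not None:
        if window != "hann":
            raise ValueError(f"unknown window {window!r}")
        m = c.size
        c *= 0.5 * (1.0 + np.cos(np.pi * np.arange(m) / (m - 1)))
    intens = 0.5 * dt * dct(c, type=1)
    big_m = c.size - 1
    freqs = np.arange(c.size) / (2.0 * big_m * dt)  # THz since dt is ps
    return VDOSSpectrum(frequencies=freqs, intensities=intens)
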