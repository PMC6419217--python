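"""MSD / Einstein diffusion, VACF, and the VDOS transform."""

import numpy as np
import pytest

from nanothz.correlation import CorrelationSeries
from nanothz.dynamics import diffusion_coefficient, msd, vacf, vdos
from nanothz.synthetic import gen_brownian, gen_harmonic_velocities
from nanothz.trajectory import Frame, Trajectory, unwrap


def brute_force_msd(pos):
    """O(N²) multiple-origin MSD, averaged over atoms."""
    n = pos.shape[0]
    out = np.zeros(n)
    for lag in range(n):
        acc = 0.0
        for t0 in range(n - lag):
            acc += np.sum((pos[t0 + lag] - pos[t0]) ** 2)
        out[lag] = acc / ((n - lag) * pos.shape[1])
    return out


def brute_force_vacf(vel):
    n = vel.shape[0]
    out = np.zeros(n)
    for lag in range(n):
        acc = 0.0
        for t0 in range(n - lag):
            acc += np.sum(vel[t0] * vel[t0 + lag])
        out[lag] = acc / ((n - lag) * vel.shape[1])
    return out


def traj_from_positions(pos, dt=0.1, box=(1e4, 1e4, 1e4)):
    return Trajectory(
        [Frame(time=i * dt, box=box, positions=p) for i, p in enumerate(pos)]
    )


def traj_from_velocities(vel, dt=0.1):
    pos = np.zeros_like(vel)
    return Trajectory(
        [
            Frame(time=i * dt, box=(1e4,) * 3, positions=pos[i], velocities=vel[i])
            for i in range(vel.shape[0])
        ]
    )


class TestMSD:
    def test_stationary_zero(self):
        pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (20, 1, 1))
        series = msd(traj_from_positions(pos))
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_ballistic_quadratic(self):
        v = np.array([0.3, -0.4, 1.2])
        t = np.arange(30)[:, None, None] * 0.1
        pos = v[None, None, :] * t
        series = msd(traj_from_positions(pos, dt=0.1))
        expect = np.sum(v**2) * series.lags**2
        assert np.allclose(series.values, expect, rtol=1e-10, atol=1e-12)

    def test_matches_brute_force(self, rng):
        pos = np.cumsum(rng.normal(0, 0.3, size=(50, 4, 3)), axis=0)
        series = msd(traj_from_positions(pos), max_lag=49)
        expect = brute_force_msd(pos)
        assert np.allclose(series.values, expect, rtol=1e-10, atol=1e-12)

    def test_wrapped_input_warns(self, rng):
        traj = gen_brownian(0.5, 10, 0.1, 200, box=(5.0, 5.0, 5.0), seed=8)
        with pytest.warns(UserWarning, match="wrapped"):
            msd(traj)

    def test_origin_counts_non_increasing(self, rng):
        pos = np.cumsum(rng.normal(0, 0.3, size=(40, 2, 3)), axis=0)
        series = msd(traj_from_positions(pos))
        assert np.all(np.diff(series.n_origins) <= 0)


class TestDiffusion:
    def test_exact_line(self):
        lags = np.arange(100) * 0.1
        series = CorrelationSeries(lags=lags, values=6 * 0.5 * lags)
        res = diffusion_coefficient(series, (1.0, 8.0))
        assert res.d == pytest.approx(0.5, rel=1e-12)
        assert res.fit_r2 == pytest.approx(1.0)

    def test_offset_invariance(self):
        lags = np.arange(100) * 0.1
        base = CorrelationSeries(lags=lags, values=6 * 0.5 * lags)
        shifted = CorrelationSeries(lags=lags, values=6 * 0.5 * lags + 3.0)
        d1 = diffusion_coefficient(base, (1.0, 8.0)).d
        d2 = diffusion_coefficient(shifted, (1.0, 8.0)).d
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_brownian_recovery(self):
        d_true = 0.23
        traj = gen_brownian(d_true, 500, 0.1, 2000, seed=3)
        series = msd(unwrap(traj))
        res = diffusion_coefficient(series, (10.0, 50.0))
        assert res.d == pytest.approx(d_true, rel=0.10)

    def test_mean_recovery_over_seeds(self):
        d_true = 0.23
        ds = []
        for seed in range(10):
            traj = gen_brownian(d_true, 120, 0.1, 1200, seed=seed)
            series = msd(unwrap(traj))
            ds.append(diffusion_coefficient(series, (6.0, 30.0)).d)
            assert ds[-1] == pytest.approx(d_true, rel=0.15)
        assert np.mean(ds) == pytest.approx(d_true, rel=0.05)

    def test_relative_value(self):
        lags = np.arange(100) * 0.1
        series = CorrelationSeries(lags=lags, values=6 * 0.1 * lags)
        res = diffusion_coefficient(series, (1.0, 8.0), d0=0.23)
        assert res.d_relative == pytest.approx(0.1 / 0.23, rel=1e-9)

    def test_short_window_rejected(self):
        lags = np.arange(100) * 0.1
        series = CorrelationSeries(lags=lags, values=lags)
        with pytest.raises(ValueError):
            diffusion_coefficient(series, (5.0, 5.05))


class TestVACF:
    def test_constant_velocity(self):
        v0 = np.array([1.0, 2.0, -1.0])
        vel = np.tile(v0, (30, 1, 1))
        series = vacf(traj_from_velocities(vel))
        assert np.allclose(series.values, np.sum(v0**2), rtol=1e-12)

    def test_cosine_autocorrelation(self):
        nu, dt = 1.0, 0.05
        t = np.arange(2000) * dt
        vel = np.cos(2 * np.pi * nu * t)[:, None, None] * np.array([1.0, 0, 0])
        series = vacf(traj_from_velocities(vel[:, :, :], dt=dt), max_lag=200)
        expect = 0.5 * np.cos(2 * np.pi * nu * series.lags)
        # finite-series estimator: agreement to a few percent of the amplitude
        assert np.allclose(series.values, expect, atol=0.02)

    def test_matches_brute_force(self, rng):
        vel = rng.normal(0, 1, size=(100, 3, 3))
        series = vacf(traj_from_velocities(vel), max_lag=99)
        expect = brute_force_vacf(vel)
        assert np.allclose(series.values, expect, rtol=1e-10, atol=1e-12)

    def test_missing_velocities_rejected(self, rng):
        pos = rng.normal(0, 1, size=(10, 2, 3))
        with pytest.raises(ValueError, match="velocities"):
            vacf(traj_from_positions(pos))


class TestVDOS:
    def test_single_mode_peak(self):
        traj = gen_harmonic_velocities([1.0], 298.15, [16.0] * 32, 0.1, 2048,
                                       seed=7)
        spec = vdos(vacf(traj))
        peak = spec.frequencies[np.argmax(spec.intensities)]
        grid_step = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak - 1.0) <= grid_step + 1e-12

    def test_constant_vacf_all_weight_at_zero(self):
        series = CorrelationSeries(lags=np.arange(64) * 0.1,
                                   values=np.full(64, 2.5))
        spec = vdos(series)
        assert np.argmax(np.abs(spec.intensities)) == 0

    def test_two_modes_two_maxima(self):
        traj = gen_harmonic_velocities([0.5, 2.0], 298.15, [16.0] * 32,
                                       0.1, 2048, seed=7)
        spec = vdos(vacf(traj))
        grid_step = spec.frequencies[1] - spec.frequencies[0]
        top = spec.frequencies[np.argsort(spec.intensities)[::-1][:6]]
        for nu in (0.5, 2.0):
            assert np.min(np.abs(top - nu)) <= grid_step + 1e-12

    def test_parseval_normalization(self, rng):
        vals = np.exp(-np.arange(128) * 0.05) * np.cos(np.arange(128) * 0.3)
        series = CorrelationSeries(lags=np.arange(128) * 0.1, values=vals)
        spec = vdos(series)
        m = len(vals) - 1
        total = (0.5 * spec.intensities[0] + spec.intensities[1:-1].sum()
                 + 0.5 * spec.intensities[-1]) / (m * series.dt)
        # documented normalization: half-end-weighted spectral sum over the
        # grid recovers half the lag-0 VACF value
        assert total == pytest.approx(vals[0] / 2, rel=1e-6)

    def test_blue_shift_ordering(self):
        nu = 1.0
        peaks = []
        for factor in (1.0, 1.1):
            traj = gen_harmonic_velocities([nu * factor], 298.15, [16.0] * 16,
                                           0.1, 4096, seed=3)
            spec = vdos(vacf(traj))
            peaks.append(spec.frequencies[np.argmax(spec.intensities)])
        assert peaks[1] > peaks[0]

    def test_hann_window_reduces_ripple(self):
        # truncated cosine: the raw transform rings, the windowed one less so
        t = np.arange(256) * 0.1
        series = CorrelationSeries(lags=t, values=np.cos(2 * np.pi * 1.0 * t))
        raw = vdos(series)
        win = vdos(series, window="hann")
        off_peak = np.abs(raw.frequencies - 1.0) > 0.3
        assert (np.abs(win.intensities[off_peak]).max()
                < np.abs(raw.intensities[off_peak]).max())
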