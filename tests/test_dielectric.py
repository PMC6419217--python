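"""Dipole trace, block ACF, permittivity transforms, optical constants."""

import numpy as np
import pytest

from nanothz.correlation import CorrelationSeries
from nanothz.dielectric import (
    DipoleTrace,
    absorption_coefficient,
    box_volume,
    cylinder_volume,
    dipole_acf,
    epsilon_imag,
    excluded_volume_model,
    kramers_kronig,
    optical_constants,
    total_dipole,
)
from nanothz.debye import DebyeParams, debye_model
from nanothz.synthetic import OUDipoleSpec, gen_ou_dipole
from nanothz.trajectory import Frame, Topology, Trajectory
from nanothz.units import EPS0, K_B, E_ANGSTROM_TO_CM, E_ANGSTROM_TO_DEBYE


def two_charge_system():
    topo = Topology(
        name=["P", "N"], element=["X", "X"], mass=np.array([1.0, 1.0]),
        charge=np.array([1.0, -1.0]), mol_id=np.array([0, 0]),
        hbond_role=["none", "none"],
    )
    frame = Frame(time=0.0, box=(20, 20, 20),
                  positions=[[0, 0, 0], [0, 0, 1.0]])
    return Trajectory([frame]), topo


class TestTotalDipole:
    def test_unit_dipole(self):
        traj, topo = two_charge_system()
        trace = total_dipole(traj, topo)
        assert np.allclose(trace.moments[0], [0, 0, -1.0])
        # 1 e·Å is about 4.8032 debye
        assert np.linalg.norm(trace.moments[0]) * E_ANGSTROM_TO_DEBYE == (
            pytest.approx(4.8032, abs=1e-4)
        )

    def test_neutral_translation_invariance(self, rng):
        q = rng.normal(0, 0.4, size=6)
        q -= q.mean()  # exactly neutral
        topo = Topology(
            name=[f"A{i}" for i in range(6)], element=["X"] * 6,
            mass=np.ones(6), charge=q, mol_id=np.zeros(6, int),
            hbond_role=["none"] * 6,
        )
        pos = rng.uniform(0, 10, size=(6, 3))
        t1 = Trajectory([Frame(time=0, box=(50,) * 3, positions=pos)])
        t2 = Trajectory([Frame(time=0, box=(50,) * 3, positions=pos + 7.3)])
        m1 = total_dipole(t1, topo).moments
        m2 = total_dipole(t2, topo).moments
        assert np.allclose(m1, m2, atol=1e-9)

    def test_zero_charges_zero_dipole(self, rng):
        topo = Topology(
            name=["A", "B"], element=["X", "X"], mass=np.ones(2),
            charge=np.zeros(2), mol_id=np.zeros(2, int),
            hbond_role=["none", "none"],
        )
        traj = Trajectory(
            [Frame(time=0, box=(10,) * 3,
                   positions=rng.uniform(0, 5, (2, 3)))]
        )
        assert np.allclose(total_dipole(traj, topo).moments, 0.0)

    def test_empty_selection_rejected(self):
        traj, topo = two_charge_system()
        with pytest.raises(ValueError):
            total_dipole(traj, topo, [])


class TestDipoleACF:
    def test_constant_dipole(self):
        m = np.tile([0.0, 0.0, 2.0], (40, 1))
        trace = DipoleTrace(times=np.arange(40) * 0.1, moments=m)
        acf = dipole_acf(trace, n_blocks=4, subtract_mean=False)
        assert np.allclose(acf.values, 4.0, rtol=1e-12)

    def test_matches_brute_force_single_block(self, rng):
        m = rng.normal(0, 1, size=(64, 3))
        trace = DipoleTrace(times=np.arange(64) * 0.1, moments=m)
        acf = dipole_acf(trace, n_blocks=1, subtract_mean=False)
        expect = np.zeros(64)
        for lag in range(64):
            acc = sum(float(m[t0] @ m[t0 + lag]) for t0 in range(64 - lag))
            expect[lag] = acc / (64 - lag)
        assert np.allclose(acf.values, expect, rtol=1e-10, atol=1e-12)

    def test_block_origins_do_not_cross(self):
        # two blocks with opposite constant dipoles: cross-block origins
        # would produce negative correlations at long lags
        m = np.concatenate([np.tile([1.0, 0, 0], (16, 1)),
                            np.tile([-1.0, 0, 0], (16, 1))])
        trace = DipoleTrace(times=np.arange(32) * 0.1, moments=m)
        acf = dipole_acf(trace, n_blocks=2, subtract_mean=False)
        assert len(acf.lags) == 16
        assert np.allclose(acf.values, 1.0, rtol=1e-12)

    def test_ou_single_process_closed_form(self):
        spec = OUDipoleSpec(amplitudes=(100.0, 0.0), taus=(5.0, 0.5),
                            dt=0.02, n_steps=500_000, seed=11)
        trace = gen_ou_dipole(spec)
        acf = dipole_acf(trace, n_blocks=20)
        tau = 5.0
        for lag_ps in (tau / 2, tau, 2 * tau):
            k = int(round(lag_ps / spec.dt))
            expect = 3 * 100.0 * np.exp(-lag_ps / tau)  # 3 components
            assert acf.values[k] == pytest.approx(expect, rel=0.05)

    def test_too_few_frames_rejected(self):
        trace = DipoleTrace(times=np.arange(10) * 0.1,
                            moments=np.zeros((10, 3)))
        with pytest.raises(ValueError):
            dipole_acf(trace, n_blocks=8)


class TestEpsilonImag:
    def test_zero_acf(self):
        acf = CorrelationSeries(lags=np.arange(50) * 0.1, values=np.zeros(50))
        e2 = epsilon_imag(acf, box_volume(30, 30, 30), 298.15,
                          np.linspace(0, 5, 20))
        assert np.allclose(e2, 0.0)

    def test_debye_lobe_closed_form(self):
        tau, c0, temp = 8.0, 100.0, 298.15
        dt = 0.01
        t = np.arange(0, 10 * tau, dt)
        acf = CorrelationSeries(lags=t, values=c0 * np.exp(-t / tau))
        vol = box_volume(30, 30, 30)
        x = np.linspace(0.1, 10.0, 40)          # 2πντ values
        nu = x / (2 * np.pi * tau)
        e2 = epsilon_imag(acf, vol, temp, nu)
        c0_si = c0 * E_ANGSTROM_TO_CM**2
        expect = (c0_si / (3 * EPS0 * vol.value * 1e-30 * K_B * temp)
                  * x / (1 + x**2))
        assert np.allclose(e2, expect, rtol=0.01)

    def test_volume_prefactor_linearity(self):
        t = np.arange(100) * 0.1
        acf = CorrelationSeries(lags=t, values=50 * np.exp(-t / 2.0))
        nu = np.linspace(0.05, 3, 10)
        a = epsilon_imag(acf, box_volume(20, 20, 20), 300.0, nu)
        b = epsilon_imag(acf, box_volume(20, 20, 40), 300.0, nu)
        assert np.allclose(a, 2 * b, rtol=1e-12)

    def test_zero_frequency_zero(self):
        t = np.arange(100) * 0.1
        acf = CorrelationSeries(lags=t, values=np.exp(-t))
        e2 = epsilon_imag(acf, box_volume(10, 10, 10), 300.0, np.array([0.0]))
        assert e2[0] == 0.0


class TestKramersKronig:
    def test_zero_loss_gives_unity(self):
        f = np.linspace(0, 5, 200)
        assert np.allclose(kramers_kronig(f, np.zeros_like(f)), 1.0)

    def test_debye_pair_recovery(self):
        delta, tau = 10.0, 8.0
        f_relax = 1 / (2 * np.pi * tau)
        fmax = 100 * f_relax
        f = np.linspace(0, fmax, 2001)
        x = 2 * np.pi * f * tau
        e2 = delta * x / (1 + x**2)
        e1 = kramers_kronig(f, e2)
        expect = 1 + delta / (1 + x**2)
        interior = (f > 0.2 * fmax) & (f < 0.8 * fmax)
        assert np.allclose(e1[interior], expect[interior], rtol=0.01)

    def test_static_limit_sum_rule(self):
        delta, tau = 10.0, 8.0
        fmax = 200 / (2 * np.pi * tau)
        f = np.linspace(0, fmax, 4001)
        x = 2 * np.pi * f * tau
        e2 = delta * x / (1 + x**2)
        e1 = kramers_kronig(f, e2)
        # eps'(0) − 1 = (2/π)∫ eps''/s ds (the ω→0 limit); for a Debye lobe
        # the integral is analytic and equals (π/2)·Δε
        from scipy.integrate import quad
        sum_rule = (2 / np.pi) * quad(
            lambda s: delta * 2 * np.pi * s * tau
            / (1 + (2 * np.pi * s * tau) ** 2) / s,
            0, np.inf,
        )[0]
        assert sum_rule == pytest.approx(delta, rel=1e-6)
        assert e1[0] - 1 == pytest.approx(sum_rule, rel=0.01)

    def test_nonuniform_grid_rejected(self):
        f = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(ValueError):
            kramers_kronig(f, np.zeros_like(f))


class TestOpticalConstantsAndAbsorption:
    def test_three_four_five(self):
        n, k = optical_constants(np.array([3.0]), np.array([4.0]))
        assert n[0] == pytest.approx(2.0, rel=1e-12)
        assert k[0] == pytest.approx(1.0, rel=1e-12)

    def test_lossless_medium(self):
        n, k = optical_constants(np.array([4.0]), np.array([0.0]))
        assert n[0] == pytest.approx(2.0)
        assert k[0] == 0.0

    def test_inverse_identity(self, rng):
        e1 = rng.uniform(-2, 80, 50)
        e2 = rng.uniform(0, 40, 50)
        n, k = optical_constants(e1, e2)
        eps = (n + 1j * k) ** 2
        assert np.allclose(eps.real, e1, atol=1e-12)
        assert np.allclose(-eps.imag, -e2, atol=1e-12)

    def test_zero_loss_zero_absorption(self):
        f = np.linspace(0, 3, 10)
        alpha = absorption_coefficient(f, np.full(10, 2.0), np.zeros(10))
        assert np.allclose(alpha, 0.0)

    def test_reference_value_at_1_thz(self):
        # eps' = 3, eps'' = 4 gives k = 1, so alpha = 4πν/c = 419.2 cm⁻¹
        alpha = absorption_coefficient(
            np.array([1.0]), np.array([3.0]), np.array([4.0])
        )
        assert alpha[0] == pytest.approx(419.2, abs=0.05)

    def test_equals_4pi_nu_k_over_c(self, rng):
        f = np.linspace(0.01, 5, 30)
        e1 = rng.uniform(1, 50, 30)
        e2 = rng.uniform(0, 30, 30)
        alpha = absorption_coefficient(f, e1, e2)
        _, k = optical_constants(e1, e2)
        from nanothz.units import C_LIGHT, THZ
        alt = 4 * np.pi * (f * THZ) * k / C_LIGHT / 100.0
        assert np.allclose(alpha, alt, rtol=1e-12)

    def test_single_debye_alpha_monotone(self):
        # absorption rises with frequency for a single-relaxation medium
        p = DebyeParams(78.0, 3.0001, 3.0, 8.0, 0.0001)
        f = np.linspace(0, 3, 500)
        e1, e2 = debye_model(p, f)
        alpha = absorption_coefficient(f, e1, e2)
        assert np.all(np.diff(alpha) > -1e-12)


class TestVolumeModels:
    def test_cylinder(self):
        v = cylinder_volume(7.1, 85.6)
        assert v.value == pytest.approx(np.pi * 7.1**2 * 85.6, rel=1e-12)
        assert v.value == pytest.approx(13556.3, abs=0.5)

    def test_unit_cylinder(self):
        assert cylinder_volume(1.0, 1.0 / np.pi).value == pytest.approx(1.0)

    def test_length_linearity(self):
        assert cylinder_volume(2.0, 10.0).value == pytest.approx(
            2 * cylinder_volume(2.0, 5.0).value
        )

    def test_excluded_volume(self):
        v = excluded_volume_model(2.0)
        assert v.value == pytest.approx(4 / 3 * np.pi * 8)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            cylinder_volume(-1.0, 5.0)
        with pytest.raises(ValueError):
            box_volume(0.0, 1.0, 1.0)
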