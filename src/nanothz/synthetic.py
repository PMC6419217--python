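"""Synthetic trajectories and dipole series with known ground truth.

Every analysis stage in the package has a generator here whose output obeys
a closed form, so the whole pipeline is verifiable without running
molecular dynamics:

* Ornstein–Uhlenbeck dipole series — exactly two-exponential ACF, the
  stand-in for a solution's total dipole with slow/fast relaxation;
* Brownian walkers with a known diffusion coefficient — the Einstein-
  relation oracle;
* harmonic velocity ensembles — VDOS peaks at prescribed frequencies;
* rigid water chains with exact donor–H–acceptor geometry — the
  hydrogen-bond criterion fixture;
* Poisson bond breaking — an analytic exp(−k·t) intermittent correlation;
* zigzag (n,0) carbon-nanotube coordinates on an exact cylinder.

All generators are deterministic under a fixed seed; randomness is split
internally per particle/process so results do not depend on evaluation
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .dielectric import DipoleTrace
from .hbond import HBond, HBondPresence
from .trajectory import Frame, Topology, Trajectory, wrap_positions
from .units import AMU_TO_KG, K_B

__all__ = [
    "OUDipoleSpec",
    "CNTSpec",
    "gen_ou_dipole",
    "gen_brownian",
    "gen_harmonic_velocities",
    "gen_water_cluster",
    "gen_breaking_bonds",
    "build_zigzag_cnt",
]

# TIP3P-like rigid water geometry and charges
OH_BOND = 0.9572      # Å
HOH_ANGLE = 104.52    # degrees
Q_O, Q_H = -0.834, 0.417  # e
M_O, M_H = 15.9994, 1.008  # amu


@dataclass(frozen=True)
class OUDipoleSpec:
    """Two-process Ornstein–Uhlenbeck dipole: amplitudes are the stationary
    variances per Cartesian component, (e·Å)²; taus the relaxation times (ps).

    Defaults are a water-like slow/fast pair (τ1 = 8 ps cooperative,
    τ2 = 0.5 ps fast) with amplitudes sized so that, in a (30 Å)³ volume at
    298.15 K, the implied dielectric strengths are solution-like
    (Δε1 ≈ 70, Δε2 ≈ 5).
    """

    amplitudes: tuple[float, float] = (270.0, 19.0)
    taus: tuple[float, float] = (8.0, 0.5)
    dt: float = 0.05
    n_steps: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        a1, a2 = self.amplitudes
        t1, t2 = self.taus
        if a1 < 0 or a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (t1 > t2 > 0):
            raise ValueError("need tau1 > tau2 > 0")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.dt >= t2 / 5.0:
            raise ValueError(
                f"dt={self.dt} too coarse to resolve tau2={t2}: need dt < tau2/5"
            )
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass(frozen=True)
class CNTSpec:
    """Zigzag (n,0) nanotube: chirality index, axial repeat units, C–C bond.

    The default bond length 1.44 Å is the value that makes the closed-form
    radius r = √3·n·cc/(2π) land on the conventional one-decimal radii for
    all six tubes from (18,0) to (35,0); 1.42 Å does not.
    """

    n: int
    repeat_units: int = 1
    cc_bond: float = 1.44

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("zigzag index n must be >= 4")
        if self.repeat_units < 1:
            raise ValueError("repeat_units must be >= 1")
        if not 1.3 <= self.cc_bond <= 1.6:
            raise ValueError("cc_bond must lie in [1.3, 1.6] Å")

    @property
    def radius(self) -> float:
        """Closed-form cylinder radius √3·n·cc/(2π), Å."""
        return float(np.sqrt(3.0) * self.n * self.cc_bond / (2.0 * np.pi))


def _ou_component(rng: np.random.Generator, amp: float, tau: float,
                  dt: float, n: int) -> np.ndarray:
    """Exact stationary OU discretisation: x' = ρx + √(A(1−ρ²))·ξ."""
    if amp == 0.0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    noise = rng.standard_normal(n)
    inp = np.sqrt(amp * (1.0 - rho * rho)) * noise
    inp[0] = np.sqrt(amp) * noise[0]  # start in the stationary distribution
    return lfilter([1.0], [1.0, -rho], inp)


def gen_ou_dipole(spec: OUDipoleSpec) -> DipoleTrace:
    """Dipole series whose ensemble ACF per component is exactly
    A1·e^(−t/τ1) + A2·e^(−t/τ2)."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    n = spec.n_steps
    moments = np.zeros((n, 3))
    k = 0
    for amp, tau in zip(spec.amplitudes, spec.taus):
        for axis in range(3):
            rng = np.random.default_rng(streams[k])
            moments[:, axis] += _ou_component(rng, amp, tau, spec.dt, n)
            k += 1
    return DipoleTrace(times=np.arange(n) * spec.dt, moments=moments)


def gen_brownian(
    d: float,
    n_particles: int,
    dt: float,
    n_steps: int,
    box: tuple[float, float, float] = (50.0, 50.0, 50.0),
    seed: int = 0,
    return_unwrapped: bool = False,
):
    """Independent Gaussian walkers with per-axis step variance 2·D·dt.

    D in Å²/ps.  Positions are wrapped into the box; with
    ``return_unwrapped`` the continuous ground-truth coordinates are
    returned alongside, for checking the unwrapping round trip.
    """
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if n_particles < 1 or n_steps < 1:
        raise ValueError("need at least one particle and one step")
    box_arr = np.asarray(box, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    start = rng.uniform(0.0, box_arr, size=(n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * d * dt), size=(n_steps - 1, n_particles, 3))
    true_pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    wrapped = wrap_positions(true_pos, box_arr)
    frames = [
        Frame(time=i * dt, box=box_arr, positions=wrapped[i])
        for i in range(n_steps)
    ]
    traj = Trajectory(frames, elements=["O"] * n_particles)
    if return_unwrapped:
        return traj, true_pos
    return traj


def gen_harmonic_velocities(
    frequencies,
    temperature: float,
    masses,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> Trajectory:
    """Superposed thermal cosine modes: VDOS peaks at the input frequencies.

    Each atom's velocity per axis is Σ_m V0·cos(2πν_m·t + φ), with random
    phases and thermal amplitudes chosen so the per-axis mean-square
    velocity is k_B·T/m.  Frequencies in THz must lie below the Nyquist
    frequency 1/(2·dt).  Positions are the integral of the velocities.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    nyquist = 1.0 / (2.0 * dt)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(freqs >= nyquist):
        raise ValueError(
            f"frequencies must be below the Nyquist frequency {nyquist} THz"
        )
    n_atoms = masses.size
    t = np.arange(n_steps) * dt
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vel = np.zeros((n_steps, n_atoms, 3))
    if freqs.size:
        # thermal amplitude per mode: <v²> per axis = kB·T/m split over modes
        v2 = K_B * temperature / (masses * AMU_TO_KG)  # (m/s)² per axis
        v0 = np.sqrt(2.0 * v2 / freqs.size) / 100.0    # Å/ps, cosine amplitude
        for a in range(n_atoms):
            for nu in freqs:
                phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
                vel[:, a, :] += v0[a] * np.cos(
                    2.0 * np.pi * nu * t[:, None] + phases[None, :]
                )
    pos = np.cumsum(vel, axis=0) * dt
    big = float(max(1e3, np.abs(pos).max() * 4 + 1))
    frames = [
        Frame(time=t[i], box=(big, big, big), positions=pos[i], velocities=vel[i])
        for i in range(n_steps)
    ]
    return Trajectory(frames, elements=["O"] * n_atoms)


def _donor_hydrogen_position(oo: float, angle_deg: float) -> np.ndarray:
    """Place a donor hydrogen in the xy-plane so that the donor–H–acceptor
    angle (vertex at H) is exactly ``angle_deg``.

    Donor O at the origin, acceptor O at (oo, 0, 0); H at distance OH_BOND
    from the donor, at polar angle φ from the O–O axis.  The D–H–A angle
    decreases monotonically from 180° (φ=0) to 0° (φ=π), so the target is
    bracketed or the geometry is impossible.
    """
    target = np.deg2rad(angle_deg)
    acc = np.array([oo, 0.0, 0.0])

    def angle_at_h(phi: float) -> float:
        h = OH_BOND * np.array([np.cos(phi), np.sin(phi), 0.0])
        to_d = -h
        to_a = acc - h
        c = np.dot(to_d, to_a) / (np.linalg.norm(to_d) * np.linalg.norm(to_a))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    f = lambda phi: angle_at_h(phi) - target
    if not 0 < angle_deg <= 180:
        raise ValueError("dha_angle must be in (0, 180] degrees")
    if abs(f(1e-9)) < 1e-12 or angle_deg == 180.0:
        phi_star = 0.0
    else:
        lo, hi = 1e-9, np.pi - 1e-9
        if f(lo) * f(hi) > 0:
            raise ValueError(
                f"no hydrogen placement gives a {angle_deg}° donor–H–acceptor "
                f"angle at O–O distance {oo} Å"
            )
        phi_star = brentq(f, lo, hi, xtol=1e-12)
    return OH_BOND * np.array([np.cos(phi_star), np.sin(phi_star), 0.0])


def gen_water_cluster(
    n_waters: int,
    oo_distance: float = 2.8,
    dha_angle: float = 175.0,
    seed: int = 0,
) -> tuple[Frame, Topology]:
    """A chain of rigid 3-site waters with exact consecutive O–O distance and
    donor–H–acceptor angle.

    Water *i* donates its first hydrogen toward water *i+1*; the second
    hydrogen is tilted out of the chain plane at the rigid H–O–H angle, and
    the last water's hydrogens point away from the chain, so the designed
    consecutive bonds are the only candidates.
    """
    if n_waters < 2:
        raise ValueError("need at least two waters")
    if oo_distance <= 0:
        raise ValueError("oo_distance must be positive")
    h1_local = _donor_hydrogen_position(oo_distance, dha_angle)
    # second hydrogen: rigid HOH angle away from h1, tilted into +z
    u = h1_local / np.linalg.norm(h1_local)
    w = np.array([0.0, 0.0, 1.0])
    w = w - np.dot(w, u) * u
    w /= np.linalg.norm(w)
    gamma = np.deg2rad(HOH_ANGLE)
    h2_local = OH_BOND * (np.cos(gamma) * u + np.sin(gamma) * w)
    # terminal water: hydrogens pointing along +x, away from the chain
    u_t = np.array([1.0, 0.0, 0.0])
    h1_term = OH_BOND * u_t
    h2_term = OH_BOND * (
        np.cos(gamma) * u_t + np.sin(gamma) * np.array([0.0, 0.0, 1.0])
    )

    positions, names, elements, roles = [], [], [], []
    masses, charges, mol_ids = [], [], []
    bonded: list[list[int]] = []
    for i in range(n_waters):
        o = np.array([i * oo_distance, 0.0, 0.0])
        terminal = i == n_waters - 1
        h1 = o + (h1_term if terminal else h1_local)
        h2 = o + (h2_term if terminal else h2_local)
        base = 3 * i
        positions += [o, h1, h2]
        names += [f"O{i}", f"H{i}a", f"H{i}b"]
        elements += ["O", "H", "H"]
        roles += ["both", "hydrogen", "hydrogen"]
        masses += [M_O, M_H, M_H]
        charges += [Q_O, Q_H, Q_H]
        mol_ids += [i, i, i]
        bonded += [[base + 1, base + 2], [], []]
    box = (n_waters * oo_distance + 50.0, 50.0, 50.0)
    frame = Frame(time=0.0, box=box, positions=np.array(positions))
    topo = Topology(
        name=names, element=elements, mass=np.array(masses),
        charge=np.array(charges), mol_id=np.array(mol_ids),
        hbond_role=roles, bonded_hydrogens=bonded,
    )
    return frame, topo


def gen_breaking_bonds(
    n_bonds: int,
    rate: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> HBondPresence:
    """Bonds intact until an exponential lifetime with the given rate (1/ps),
    then permanently broken — the survival curve is exactly exp(−rate·t)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if n_bonds < 1 or n_steps < 1:
        raise ValueError("need at least one bond and one step")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if rate == 0:
        presence = np.ones((n_bonds, n_steps), dtype=bool)
    else:
        lifetimes = rng.exponential(1.0 / rate, size=n_bonds)
        t = np.arange(n_steps) * dt
        presence = t[None, :] < lifetimes[:, None]
    bonds = [HBond(donor=3 * i, hydrogen=3 * i + 1, acceptor=3 * i + 2)
             for i in range(n_bonds)]
    return HBondPresence(bonds=bonds, presence=presence, dt=dt)


def build_zigzag_cnt(spec: CNTSpec) -> tuple[Frame, float]:
    """Carbon coordinates of an uncapped zigzag (n,0) tube, axis along z.

    The graphene sheet (4 atoms per rectangular cell, axial period 3·cc) is
    rolled onto a cylinder of radius √3·n·cc/(2π); every atom sits exactly
    on the cylinder.  Returns the frame and the closed-form radius (Å).
    """
    n, cc = spec.n, spec.cc_bond
    r = spec.radius
    circumference = np.sqrt(3.0) * n * cc
    # 2D unit cell (x around the circumference, y along the axis):
    cell = np.array(
        [
            [0.0, 0.0],
            [np.sqrt(3.0) * cc / 2.0, cc / 2.0],
            [np.sqrt(3.0) * cc / 2.0, 3.0 * cc / 2.0],
            [0.0, 2.0 * cc],
        ]
    )
    period = 3.0 * cc
    coords = []
    for rep in range(spec.repeat_units):
        for col in range(n):
            offset = np.array([col * np.sqrt(3.0) * cc, rep * period])
            for x, y in cell + offset:
                theta = 2.0 * np.pi * x / circumference
                coords.append([r * np.cos(theta), r * np.sin(theta), y])
    coords = np.array(coords)
    box = (2.0 * r + 30.0, 2.0 * r + 30.0, spec.repeat_units * period)
    frame = Frame(time=0.0, box=box, positions=coords)
    return frame, r
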