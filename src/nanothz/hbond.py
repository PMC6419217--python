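"""Geometric hydrogen-bond detection and the intermittent correlation C_HB.

A bond (donor D, hydrogen H, acceptor A) exists in a frame when the
minimum-image D–A distance is at most ``d_max`` (default 3.5 Å) and the
angle at the hydrogen between the rays H→D and H→A is at least
``angle_min`` (default 135°, i.e. near-linear).  The intermittent
correlation

    C_HB(τ) = ⟨h(0)·h(τ)⟩ / ⟨h(0)²⟩

asks whether a bond intact at one time is intact a lag τ later, with no
condition on what happened in between, so reformed bonds count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationSeries
from .trajectory import Frame, Topology, TopologyError, Trajectory

__all__ = [
    "HBondCriterion",
    "HBond",
    "HBondPresence",
    "detect_hbonds",
    "track_hbonds",
    "hbond_correlation",
    "hbond_lifetime",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Distance/angle cutoffs: D–A ≤ d_max (Å), D–H–A angle ≥ angle_min (°)."""

    d_max: float = 3.5
    angle_min: float = 135.0

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    """A (donor, hydrogen, acceptor) atom-index triple."""

    donor: int
    hydrogen: int
    acceptor: int


@dataclass
class HBondPresence:
    """Boolean bond × frame matrix over the union of all bonds ever seen."""

    bonds: list[HBond]
    presence: np.ndarray  # (n_bonds, n_frames) bool
    dt: float  # ps

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 2 or self.presence.shape[0] != len(self.bonds):
            raise ValueError("presence must be (n_bonds, n_frames)")
        if len(set(self.bonds)) != len(self.bonds):
            raise ValueError("bond labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.presence.shape[1]


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criterion: HBondCriterion = HBondCriterion(),
) -> list[HBond]:
    """All (D,H,A) triples in one frame satisfying the geometric criterion.

    D and A must belong to different molecules.  The D–A distance uses the
    minimum-image convention; the hydrogen is taken at its stored position
    (the O–H bond is intramolecular, so no image search is needed for H),
    with the H→D and H→A rays themselves minimum-imaged.
    """
    donors = topology.donors
    acceptors = topology.acceptors
    if donors.size == 0 or acceptors.size == 0:
        return []
    pos = frame.positions
    box = frame.box
    bonds: list[HBond] = []
    acc_pos = pos[acceptors]
    acc_mol = topology.mol_id[acceptors]
    cos_min = np.cos(np.deg2rad(criterion.angle_min))
    for d_idx in donors:
        hydrogens = topology.bonded_hydrogens[d_idx]
        if not hydrogens:
            raise TopologyError(f"donor atom {d_idx} has no bonded hydrogens")
        sep = _minimum_image(acc_pos - pos[d_idx], box)
        dist = np.linalg.norm(sep, axis=1)
        cand = np.nonzero((dist <= criterion.d_max)
                          & (acc_mol != topology.mol_id[d_idx]))[0]
        if cand.size == 0:
            continue
        for h_idx in hydrogens:
            hd = _minimum_image(pos[d_idx] - pos[h_idx], box)
            ha = _minimum_image(acc_pos[cand] - pos[h_idx], box)
            nhd = np.linalg.norm(hd)
            nha = np.linalg.norm(ha, axis=1)
            with np.errstate(invalid="ignore"):
                cosang = (ha @ hd) / (nha * nhd)
            # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
            ok = cand[np.nonzero(cosang <= cos_min)[0]]
            for a_local in ok:
                bonds.append(
                    HBond(int(d_idx), int(h_idx), int(acceptors[a_local]))
                )
    return bonds


def track_hbonds(
    trajectory: Trajectory,
    topology: Topology,
    criterion: HBondCriterion = HBondCriterion(),
) -> HBondPresence:
    """Per-frame detection over the union bond universe (intermittent h(t)).

    A bond enters the universe the first frame it is detected; its presence
    row is then simply the per-frame geometric test, so it may flicker off
    and on (no history condition).
    """
    per_frame = [detect_hbonds(fr, topology, criterion) for fr in trajectory]
    universe: dict[HBond, int] = {}
    for bonds in per_frame:
        for b in bonds:
            if b not in universe:
                universe[b] = len(universe)
    presence = np.zeros((len(universe), len(trajectory)), dtype=bool)
    for t, bonds in enumerate(per_frame):
        for b in bonds:
            presence[universe[b], t] = True
    return HBondPresence(
        bonds=list(universe.keys()), presence=presence, dt=trajectory.dt
    )


def hbond_correlation(presence: HBondPresence) -> CorrelationSeries:
    """Intermittent C_HB(τ) = Σ h(t0)h(t0+τ) / Σ h(t0)² over bonds and origins.

    Both sums run over the origins valid at each lag, so C_HB(0) = 1 exactly
    whenever any bond exists.
    """
    h = presence.presence.astype(np.float64)
    n_bonds, n_frames = h.shape
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if n_bonds == 0 or not np.any(h):
        raise ValueError("empty bond universe")
    max_lag = n_frames - 1
    num = np.empty(max_lag + 1)
    den = np.empty(max_lag + 1)
    num[0] = den[0] = h.sum()  # h² = h for booleans
    for tau in range(1, max_lag + 1):
        num[tau] = (h[:, :-tau] * h[:, tau:]).sum()
        den[tau] = h[:, :-tau].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return CorrelationSeries(
        lags=np.arange(max_lag + 1) * presence.dt,
        values=c,
        n_origins=(n_frames - np.arange(max_lag + 1)) * n_bonds,
        meta={"estimator": "hbond_correlation", "n_bonds": n_bonds},
    )


def hbond_lifetime(chb: CorrelationSeries) -> tuple[float, bool]:
    """τ_HB = ∫ C_HB(τ) dτ by the trapezoid rule over the available lags.

    Returns (lifetime_ps, truncated): ``truncated`` is set when C_HB has not
    decayed below 0.05 by the last lag, in which case the integral
    underestimates the true lifetime.
    """
    lifetime = float(np.trapezoid(chb.values, chb.lags))
    truncated = bool(chb.values[-1] > 0.05)
    return lifetime, truncated
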