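"""Static chain-geometry observables.

Per-axis radius of gyration (the observable that resolves how a confined
chain elongates axially while shrinking radially), end-to-end distance and
the excluded volume built on it.  Molecules are assumed whole: unwrap the
trajectory first, no periodic-image correction is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Topology, Trajectory

__all__ = [
    "GyrationResult",
    "ChainExtent",
    "radius_of_gyration",
    "chain_extent",
    "gyration_timeseries",
]


@dataclass(frozen=True)
class GyrationResult:
    """Mass-weighted RMS distance from the centre of mass, total and per axis.

    Satisfies rg_total² = rg_x² + rg_y² + rg_z².
    """

    rg_total: float
    rg_x: float
    rg_y: float
    rg_z: float
    n_atoms: int


@dataclass(frozen=True)
class ChainExtent:
    """End-to-end distance R_e (Å) and the excluded volume V_ex = 4/3·π·R_e³
    (Å³) used as a chain's occupied volume in the dielectric prefactor."""

    re: float
    v_ex: float


def radius_of_gyration(positions: np.ndarray, masses: np.ndarray) -> GyrationResult:
    """R_g = sqrt(Σ m_i |r_i − r_cm|² / Σ m_i), with per-axis components.

    Each axis component uses only that coordinate, so the squared components
    sum to the squared total.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float).reshape(-1)
    if positions.shape[0] < 1:
        raise ValueError("need at least one atom")
    if masses.shape[0] != positions.shape[0]:
        raise ValueError("masses and positions must have equal length")
    mtot = masses.sum()
    if mtot <= 0:
        raise ValueError("total mass must be positive")
    r_cm = (masses[:, None] * positions).sum(axis=0) / mtot
    d2 = (positions - r_cm) ** 2
    comp2 = (masses[:, None] * d2).sum(axis=0) / mtot  # per-axis Rg²
    total = float(np.sqrt(comp2.sum()))
    cx, cy, cz = np.sqrt(comp2)
    return GyrationResult(
        rg_total=total, rg_x=float(cx), rg_y=float(cy), rg_z=float(cz),
        n_atoms=positions.shape[0],
    )


def chain_extent(
    positions: np.ndarray, first_index: int, last_index: int
) -> ChainExtent:
    """End-to-end distance between two atoms and the sphere volume on it."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = positions.shape[0]
    if not (0 <= first_index < n and 0 <= last_index < n):
        raise ValueError("endpoint indices out of range")
    if first_index == last_index:
        raise ValueError("endpoints must be distinct atoms")
    re = float(np.linalg.norm(positions[last_index] - positions[first_index]))
    return ChainExtent(re=re, v_ex=4.0 / 3.0 * np.pi * re**3)


def gyration_timeseries(
    trajectory: Trajectory,
    topology: Topology,
    atom_selection: np.ndarray | list[int] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-frame radius of gyration for a selection, plus time mean/stddev.

    Returns a tidy table (frame, time_ps, rg_x, rg_y, rg_z, rg_total) and a
    summary dict with ``<col>_mean`` / ``<col>_std`` entries.
    """
    if atom_selection is None:
        sel = np.arange(topology.n_atoms)
    else:
        sel = np.asarray(atom_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("atom selection is empty")
    masses = topology.mass[sel]
    rows = []
    for i, fr in enumerate(trajectory):
        g = radius_of_gyration(fr.positions[sel], masses)
        rows.append(
            {
                "frame": i,
                "time_ps": fr.time,
                "rg_x": g.rg_x,
                "rg_y": g.rg_y,
                "rg_z": g.rg_z,
                "rg_total": g.rg_total,
            }
        )
    df = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    for col in ("rg_x", "rg_y", "rg_z", "rg_total"):
        summary[f"{col}_mean"] = float(df[col].mean())
        summary[f"{col}_std"] = float(df[col].std(ddof=0))
    return df, summary
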