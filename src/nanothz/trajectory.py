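"""Trajectory and topology containers plus extended-XYZ / topology-table I/O.

The on-disk trajectory dialect is extended XYZ with an orthorhombic box and
a timestamp on the comment line::

    <n_atoms>
    time=<ps> box="Lx Ly Lz"
    <element> x y z [vx vy vz]
    ...

Lengths are Å, times ps, velocities Å/ps.  The topology is a separate
tab-separated table (columns ``name element mass charge mol_id hbond_role
bonded_hydrogens``) because only masses, charges and hydrogen-bond roles are
needed by the analyses — force-field files are deliberately not parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "Topology",
    "TrajectoryFormatError",
    "TopologyError",
    "read_extended_xyz",
    "write_extended_xyz",
    "read_topology",
    "write_topology",
    "unwrap",
    "wrap_positions",
]

HBOND_ROLES = ("donor", "acceptor", "both", "hydrogen", "none")

#: Relative tolerance for "uniformly spaced" frame times.
DT_RTOL = 1e-6


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file or inconsistent frame structure."""


class TopologyError(ValueError):
    """Topology table violates its invariants."""


@dataclass
class Frame:
    """One snapshot: time (ps), orthorhombic box (Å), positions (n,3) Å,
    optional velocities (n,3) Å/ps."""

    time: float
    box: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError(f"box components must be positive, got {self.box}")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
            if self.velocities.shape != self.positions.shape:
                raise ValueError(
                    "velocities shape %s does not match positions %s"
                    % (self.velocities.shape, self.positions.shape)
                )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """Ordered, uniformly spaced frames sharing one atom count.

    Provides array views (``positions`` is (n_frames, n_atoms, 3)) so the
    estimators can stay vectorised.
    """

    def __init__(self, frames: Sequence[Frame], elements: Sequence[str] | None = None):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = frames[0].n_atoms
        for i, fr in enumerate(frames):
            if fr.n_atoms != n:
                raise TrajectoryFormatError(
                    f"frame {i} has {fr.n_atoms} atoms, expected {n}"
                )
        times = np.array([fr.time for fr in frames])
        if len(frames) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                i = int(np.argmax(dts <= 0))
                raise TrajectoryFormatError(
                    "frame times must be strictly increasing; "
                    f"times {times[i]:.6f} and {times[i + 1]:.6f} violate this"
                )
            dt = dts[0]
            bad = np.abs(dts - dt) > DT_RTOL * max(abs(dt), 1.0)
            if np.any(bad):
                i = int(np.argmax(bad))
                raise TrajectoryFormatError(
                    "non-uniform frame spacing: interval between times "
                    f"{times[i]:.6f} and {times[i + 1]:.6f} differs from dt={dt:.6f}"
                )
            self.dt = float(dt)
        else:
            self.dt = 0.0
        self.frames = frames
        self.elements = list(elements) if elements is not None else None

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def positions(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) position array, Å."""
        return np.stack([fr.positions for fr in self.frames])

    @property
    def velocities(self) -> np.ndarray | None:
        """(n_frames, n_atoms, 3) velocity array (Å/ps), or None."""
        if any(fr.velocities is None for fr in self.frames):
            return None
        return np.stack([fr.velocities for fr in self.frames])

    @property
    def boxes(self) -> np.ndarray:
        return np.stack([fr.box for fr in self.frames])


@dataclass
class Topology:
    """Static per-atom records aligned with the trajectory atom order.

    ``bonded_hydrogens`` lists, for each donor, the atom indices of its
    covalently bound hydrogens; every hydrogen-role atom must be claimed by
    exactly one donor.
    """

    name: list[str]
    element: list[str]
    mass: np.ndarray
    charge: np.ndarray
    mol_id: np.ndarray
    hbond_role: list[str]
    bonded_hydrogens: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.mol_id = np.asarray(self.mol_id, dtype=int)
        n = len(self.name)
        for attr in ("element", "mass", "charge", "mol_id", "hbond_role"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"column '{attr}' has wrong length")
        if not self.bonded_hydrogens:
            self.bonded_hydrogens = [[] for _ in range(n)]
        if len(self.bonded_hydrogens) != n:
            raise TopologyError("bonded_hydrogens has wrong length")
        if np.any(self.mass < 0) or not np.any(self.mass > 0):
            raise TopologyError("masses must be >= 0 with at least one > 0")
        if not np.all(np.isfinite(self.charge)):
            raise TopologyError("charges must be finite")
        for role in self.hbond_role:
            if role not in HBOND_ROLES:
                raise TopologyError(f"unknown hbond_role {role!r}")
        claimed: dict[int, int] = {}
        for donor, hs in enumerate(self.bonded_hydrogens):
            if hs and self.hbond_role[donor] not in ("donor", "both"):
                raise TopologyError(
                    f"atom {donor} lists bonded hydrogens but is not a donor"
                )
            for h in hs:
                if not 0 <= h < n:
                    raise TopologyError(f"hydrogen index {h} out of range")
                if self.hbond_role[h] != "hydrogen":
                    raise TopologyError(f"atom {h} is claimed as hydrogen but has role "
                                        f"{self.hbond_role[h]!r}")
                if h in claimed:
                    raise TopologyError(
                        f"hydrogen {h} claimed by donors {claimed[h]} and {donor}"
                    )
                claimed[h] = donor
        for i, role in enumerate(self.hbond_role):
            if role == "hydrogen" and i not in claimed:
                raise TopologyError(f"hydrogen atom {i} is not bound to any donor")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def donors(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.hbond_role) if r in ("donor", "both")],
            dtype=int,
        )

    @property
    def acceptors(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.hbond_role) if r in ("acceptor", "both")],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# extended XYZ

_COMMENT_RE = re.compile(
    r'time\s*=\s*([-\d.eE+]+)\s+box\s*=\s*"([-\d.eE+\s]+)"'
)


def _parse_comment(line: str, index: int) -> tuple[float | None, np.ndarray]:
    m = _COMMENT_RE.search(line)
    if m is None:
        raise TrajectoryFormatError(
            f'frame {index}: comment line must carry time=<ps> box="Lx Ly Lz", '
            f"got {line!r}"
        )
    box = np.array([float(x) for x in m.group(2).split()])
    if box.size != 3:
        raise TrajectoryFormatError(f"frame {index}: box needs 3 components")
    return float(m.group(1)), box


def read_extended_xyz(
    path: str | Path,
    topology: Topology | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read an extended-XYZ trajectory.

    Frame times come from the comment line; if a file lacks them entirely,
    supply ``dt`` (ps) and times are synthesised as ``i*dt``.  Velocities are
    populated iff velocity columns are present in every frame.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    elements: list[str] = []
    i = 0
    index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {index}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n > len(lines):
            raise TrajectoryFormatError(f"frame {index}: truncated file")
        try:
            time, box = _parse_comment(lines[i + 1], index)
        except TrajectoryFormatError:
            if dt is None:
                raise
            time, box = None, None  # resolved below
        if box is None:
            raise TrajectoryFormatError(
                f"frame {index}: box is required on the comment line"
            )
        if time is None:
            time = index * dt
        pos = np.empty((n, 3))
        vel: np.ndarray | None = None
        frame_elements: list[str] = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) not in (4, 7):
                raise TrajectoryFormatError(
                    f"frame {index}: atom line {j} has {len(parts)} fields "
                    "(expected 4 or 7)"
                )
            frame_elements.append(parts[0])
            pos[j] = [float(x) for x in parts[1:4]]
            if len(parts) == 7:
                if vel is None:
                    if j != 0:
                        raise TrajectoryFormatError(
                            f"frame {index}: mixed velocity columns"
                        )
                    vel = np.empty((n, 3))
                vel[j] = [float(x) for x in parts[4:7]]
            elif vel is not None:
                raise TrajectoryFormatError(f"frame {index}: mixed velocity columns")
        if topology is not None and n != topology.n_atoms:
            raise TrajectoryFormatError(
                f"frame {index}: {n} atoms but topology has {topology.n_atoms}"
            )
        if index == 0:
            elements = frame_elements
        frames.append(Frame(time=time, box=box, positions=pos, velocities=vel))
        i += 2 + n
        index += 1
    if not frames:
        raise TrajectoryFormatError("no frames found")
    # velocities present iff present in every frame
    if any(fr.velocities is None for fr in frames):
        for fr in frames:
            fr.velocities = None
    return Trajectory(frames, elements=elements)


def write_extended_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the extended-XYZ dialect (6-decimal fixed point)."""
    if len(trajectory) == 0:
        raise ValueError("cannot write an empty trajectory")
    elements = trajectory.elements or ["X"] * trajectory.n_atoms
    out: list[str] = []
    for fr in trajectory:
        out.append(str(fr.n_atoms))
        bx = " ".join(f"{b:.6f}" for b in fr.box)
        out.append(f'time={fr.time:.6f} box="{bx}"')
        for j in range(fr.n_atoms):
            cols = [elements[j]] + [f"{x:.6f}" for x in fr.positions[j]]
            if fr.velocities is not None:
                cols += [f"{v:.6f}" for v in fr.velocities[j]]
            out.append(" ".join(cols))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# topology table

_TOPO_COLUMNS = ["name", "element", "mass", "charge", "mol_id", "hbond_role",
                 "bonded_hydrogens"]


def read_topology(path: str | Path) -> Topology:
    """Read a tab-separated topology table (see module docstring)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"bonded_hydrogens": str})
    missing = [c for c in _TOPO_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"topology table missing columns: {missing}")
    bonded: list[list[int]] = []
    for raw in df["bonded_hydrogens"].fillna(""):
        raw = str(raw).strip()
        bonded.append([int(x) for x in raw.split(",")] if raw else [])
    return Topology(
        name=df["name"].astype(str).tolist(),
        element=df["element"].astype(str).tolist(),
        mass=df["mass"].to_numpy(float),
        charge=df["charge"].to_numpy(float),
        mol_id=df["mol_id"].to_numpy(int),
        hbond_role=df["hbond_role"].astype(str).tolist(),
        bonded_hydrogens=bonded,
    )


def write_topology(topology: Topology, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": topology.name,
            "element": topology.element,
            "mass": topology.mass,
            "charge": topology.charge,
            "mol_id": topology.mol_id,
            "hbond_role": topology.hbond_role,
            "bonded_hydrogens": [
                ",".join(str(h) for h in hs) for hs in topology.bonded_hydrogens
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# periodic-image handling

def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold positions into [0, L) per axis."""
    return np.mod(positions, box)


def unwrap(trajectory: Trajectory) -> Trajectory:
    """Remove periodic-image jumps so displacements are continuous.

    Assumes every true per-step displacement is below half the box per axis;
    larger physical jumps are silently misinterpreted as image crossings
    (documented hazard — there is no way to detect them from wrapped data).
    The first frame is returned unchanged.
    """
    pos = trajectory.positions
    boxes = trajectory.boxes
    disp = np.diff(pos, axis=0)
    # minimum-image per step, using the box of the later frame
    b = boxes[1:, None, :]
    disp -= b * np.round(disp / b)
    unwrapped = np.empty_like(pos)
    unwrapped[0] = pos[0]
    np.cumsum(disp, axis=0, out=disp)
    unwrapped[1:] = pos[0] + disp
    frames = [
        Frame(
            time=fr.time,
            box=fr.box,
            positions=unwrapped[i],
            velocities=fr.velocities,
        )
        for i, fr in enumerate(trajectory)
    ]
    return Trajectory(frames, elements=trajectory.elements)
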