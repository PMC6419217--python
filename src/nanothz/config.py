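"""Reproducible analysis runs from a validated configuration.

A :class:`RunConfig` names the inputs, the analysis, its parameters and a
seed; :func:`run` validates everything up front (no partial outputs on a
bad config), executes the analysis, writes delimited result tables and a
run log that echoes the full configuration plus every derived grid
parameter (dt, block length, frequency resolution, Nyquist), which is
enough to re-run bit-identically.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dielectric import (
    box_volume,
    compute_spectrum,
    cylinder_volume,
    dipole_acf,
    excluded_volume_model,
    total_dipole,
)
from .dynamics import diffusion_coefficient, msd, vacf, vdos
from .hbond import HBondCriterion, hbond_correlation, hbond_lifetime, track_hbonds
from .structure import gyration_timeseries
from .trajectory import read_extended_xyz, read_topology, unwrap

__all__ = ["RunConfig", "ConfigError", "run", "grid_parameters"]

ANALYSES = ("rg", "msd", "diffusion", "vacf", "vdos", "dielectric", "hbond")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


def grid_parameters(n_frames_per_block: int, dt: float) -> tuple[float, float]:
    """Fourier grid implied by a block: (resolution in GHz, max frequency in THz).

    resolution = 1/(n·dt), f_max = 1/(2·dt) (Nyquist); dt in ps.  A 5000-frame
    block at 0.1 ps gives 2 GHz resolution up to 5 THz.
    """
    if n_frames_per_block < 2:
        raise ValueError("need at least 2 frames per block")
    if dt <= 0:
        raise ValueError("dt must be positive")
    resolution_ghz = 1000.0 / (n_frames_per_block * dt)
    f_max_thz = 1.0 / (2.0 * dt)
    return resolution_ghz, f_max_thz


@dataclass
class RunConfig:
    """One analysis run.  Defaults follow the standard protocol: 20 blocks,
    298.15 K, H-bond cutoffs 3.5 Å / 135°."""

    analysis: str
    trajectory: str | None = None
    topology: str | None = None
    output_dir: str = "."
    seed: int = 0
    blocks: int = 20
    temperature: float = 298.15
    d_max: float = 3.5
    angle_min: float = 135.0
    volume_kind: str = "box"
    radius: float | None = None
    length: float | None = None
    re: float | None = None
    fmax_thz: float | None = None
    selection: list[int] | None = None
    fit_window: tuple[float, float] | None = None
    d0: float | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a key/value YAML config; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        extra = {k: data.pop(k) for k in list(data) if k not in known}
        cfg = cls(**data)
        cfg.extra.update(extra)
        return cfg

    def validate(self) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigError(
                f"unknown analysis {self.analysis!r}; choose from {ANALYSES}"
            )
        if self.trajectory is None:
            raise ConfigError("a trajectory path is required")
        if not Path(self.trajectory).exists():
            raise ConfigError(f"trajectory file not found: {self.trajectory}")
        if self.analysis in ("rg", "dielectric", "hbond"):
            if self.topology is None:
                raise ConfigError(f"analysis {self.analysis!r} needs a topology")
            if not Path(self.topology).exists():
                raise ConfigError(f"topology file not found: {self.topology}")
        if self.blocks < 1:
            raise ConfigError("blocks must be >= 1")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.volume_kind not in ("box", "cylinder", "excluded"):
            raise ConfigError(f"unknown volume kind {self.volume_kind!r}")
        if self.volume_kind == "cylinder" and not (self.radius and self.length):
            raise ConfigError("cylinder volume needs --radius and --length")
        if self.volume_kind == "excluded" and not self.re:
            raise ConfigError("excluded volume needs --re")


def _write_table(df: pd.DataFrame, path: Path, units_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run(config: RunConfig) -> dict:
    """Execute one configured analysis; returns {output name: path} plus a log.

    Deterministic for a fixed (inputs, config, seed).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"nanothz {__version__}",
        f"analysis: {config.analysis}",
        f"config: {config}",
    ]
    topo = read_topology(config.topology) if config.topology else None
    traj = read_extended_xyz(config.trajectory, topology=topo)
    log_lines.append(f"frames: {len(traj)}  atoms: {traj.n_atoms}  dt: {traj.dt} ps")
    sel = np.asarray(config.selection, int) if config.selection else None
    outputs: dict[str, Path] = {}

    if config.analysis == "rg":
        df, summary = gyration_timeseries(traj, topo, sel)
        out = outdir / "rg.tsv"
        _write_table(df, out, "time_ps in ps; rg columns in Angstrom")
        log_lines += [f"{k}: {v:.6f}" for k, v in summary.items()]
        outputs["rg"] = out

    elif config.analysis in ("msd", "diffusion"):
        series = msd(unwrap(traj), sel)
        df = pd.DataFrame({"lag_ps": series.lags, "msd_A2": series.values})
        out = outdir / "msd.tsv"
        _write_table(df, out, "lag_ps in ps; msd in Angstrom^2")
        outputs["msd"] = out
        if config.analysis == "diffusion":
            res = diffusion_coefficient(series, config.fit_window, d0=config.d0)
            ddf = pd.DataFrame([{
                "d_A2_per_ps": res.d,
                "d_relative": res.d_relative,
                "fit_t_min_ps": res.fit_window[0],
                "fit_t_max_ps": res.fit_window[1],
                "fit_r2": res.fit_r2,
            }])
            out2 = outdir / "diffusion.tsv"
            _write_table(ddf, out2, "d in Angstrom^2/ps")
            log_lines.append(f"D = {res.d:.6g} A^2/ps (R^2 = {res.fit_r2:.4f})")
            outputs["diffusion"] = out2

    elif config.analysis in ("vacf", "vdos"):
        series = vacf(traj, sel)
        df = pd.DataFrame({"lag_ps": series.lags, "vacf": series.values})
        out = outdir / "vacf.tsv"
        _write_table(df, out, "lag_ps in ps; vacf in (Angstrom/ps)^2")
        outputs["vacf"] = out
        if config.analysis == "vdos":
            spec = vdos(series, window=config.extra.get("window"))
            sdf = pd.DataFrame({
                "frequency_THz": spec.frequencies,
                "intensity": spec.intensities,
            })
            out2 = outdir / "vdos.tsv"
            _write_table(sdf, out2, "frequency in THz; intensity arbitrary units")
            outputs["vdos"] = out2

    elif config.analysis == "dielectric":
        trace = total_dipole(traj, topo, sel)
        acf = dipole_acf(trace, n_blocks=config.blocks)
        block_len = len(trace) // config.blocks
        res_ghz, nyq_thz = grid_parameters(block_len, trace.dt)
        log_lines.append(
            f"block length: {block_len} frames; frequency resolution: "
            f"{res_ghz:.6g} GHz; max frequency (Nyquist): {nyq_thz:.6g} THz"
        )
        if config.volume_kind == "box":
            bx = traj[0].box
            volume = box_volume(*bx)
        elif config.volume_kind == "cylinder":
            volume = cylinder_volume(config.radius, config.length)
        else:
            volume = excluded_volume_model(config.re)
        fmax = config.fmax_thz if config.fmax_thz else nyq_thz
        n_freq = max(int(round(fmax / (res_ghz / 1000.0))) + 1, 16)
        grid = np.linspace(0.0, fmax, n_freq)
        spectrum = compute_spectrum(acf, volume, config.temperature, grid)
        sdf = pd.DataFrame({
            "frequency_THz": spectrum.frequencies,
            "eps_real": spectrum.eps_real,
            "eps_imag": spectrum.eps_imag,
            "n": spectrum.n,
            "k": spectrum.k,
            "alpha_cm1": spectrum.alpha_cm1,
            "trusted": spectrum.trusted.astype(int),
        })
        out = outdir / "spectrum.tsv"
        _write_table(sdf, out, "frequency in THz; alpha in 1/cm")
        outputs["spectrum"] = out

    elif config.analysis == "hbond":
        crit = HBondCriterion(d_max=config.d_max, angle_min=config.angle_min)
        presence = track_hbonds(traj, topo, crit)
        counts = presence.presence.sum(axis=0)
        cdf = pd.DataFrame({
            "frame": np.arange(presence.n_frames),
            "time_ps": traj.times,
            "n_bonds": counts,
        })
        out = outdir / "hbond_counts.tsv"
        _write_table(cdf, out, "per-frame hydrogen-bond counts")
        outputs["counts"] = out
        chb = hbond_correlation(presence)
        life, truncated = hbond_lifetime(chb)
        hdf = pd.DataFrame({"lag_ps": chb.lags, "c_hb": chb.values})
        out2 = outdir / "chb.tsv"
        _write_table(hdf, out2, "intermittent hydrogen-bond correlation")
        log_lines.append(
            f"lifetime: {life:.6g} ps" + (" (truncated)" if truncated else "")
        )
        outputs["chb"] = out2

    log_path = outdir / f"{config.analysis}.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    print("\n".join(log_lines), file=sys.stderr)
    outputs["log"] = log_path
    return outputs
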