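"""Serialization of runs: observables CSV, configuration dumps, manifests."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import energy_profile, mean_rg, mobility_profile, rms_com_displacement
from .energetics import Trajectory

OBSERVABLES_SCHEMA = "pepmc-observables-v1"
PROFILES_SCHEMA = "pepmc-profiles-v1"


def write_observables(traj: Trajectory, path: Path) -> None:
    """Per-checkpoint scalars: t, total energy, mean Rg, RMS COM displacement."""
    dyn = rms_com_displacement(traj)
    df = pd.DataFrame({
        "t_mcs": traj.times,
        "energy": traj.energy,
        "mean_rg": dyn.r_g,
        "rms_com_displacement": dyn.r_c,
    })
    with open(path, "w") as fh:
        fh.write(f"# schema: {OBSERVABLES_SCHEMA}\n")
        df.to_csv(fh, index=False)


def write_profiles(traj: Trajectory, path: Path) -> None:
    """Per-position energy and mobility profiles over the second half."""
    ep = energy_profile(traj)
    mp = mobility_profile(traj)
    df = pd.DataFrame({
        "position": ep.positions,
        "residue": list(str(traj.sequence)),
        "energy_mean": ep.mean,
        "energy_se": ep.stderr,
        "mobility_mean": mp.mean,
        "mobility_se": mp.stderr,
    })
    with open(path, "w") as fh:
        fh.write(f"# schema: {PROFILES_SCHEMA}\n")
        df.to_csv(fh, index=False)


def write_xyz(traj: Trajectory, path: Path, checkpoint: int = -1) -> None:
    """XYZ-like text dump of one checkpoint: residue, chain id, wrapped xyz."""
    pos = np.mod(traj.positions[checkpoint], traj.config.L)
    n = traj.chain_length
    letters = list(str(traj.sequence))
    with open(path, "w") as fh:
        fh.write(f"{len(pos)}\n")
        fh.write(f"t_mcs={traj.times[checkpoint]} L={traj.config.L}\n")
        for i, p in enumerate(pos):
            fh.write(f"{letters[i % n]} {i // n} {p[0]} {p[1]} {p[2]}\n")


def read_xyz(path: Path) -> tuple[np.ndarray, int]:
    """Read a configuration dump; returns (positions, L)."""
    with open(path) as fh:
        n = int(fh.readline())
        header = dict(kv.split("=") for kv in fh.readline().split())
        pos = np.array([line.split()[2:5] for line in fh], dtype=np.int64)
    if len(pos) != n:
        raise ValueError(f"expected {n} records, found {len(pos)}")
    return pos, int(header["L"])


def write_manifest(traj: Trajectory, outdir: Path, files: list[str]) -> None:
    man = {
        "schema": "pepmc-manifest-v1",
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(traj.config),
        "sequence": str(traj.sequence),
        "sequence_name": traj.sequence.name,
        "seed": traj.config.seed,
        "matrix_provenance": traj.meta.get("matrix_provenance", "unknown"),
        "start_mcs": int(traj.times[0]),
        "end_mcs": int(traj.times[-1]),
        "acceptance_rate": traj.acceptance_rate,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(man, indent=2))


def save_run(traj: Trajectory, outdir: str | Path,
             dump_trajectory: bool = True) -> Path:
    """Write the standard output set of one run into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = ["observables.csv", "profiles.csv", "final_config.xyz"]
    write_observables(traj, outdir / "observables.csv")
    write_profiles(traj, outdir / "profiles.csv")
    write_xyz(traj, outdir / "final_config.xyz")
    if dump_trajectory:
        traj.save(outdir / "trajectory.npz")
        files.append("trajectory.npz")
    write_manifest(traj, outdir, files)
    return outdir
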