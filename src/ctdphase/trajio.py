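"""Trajectory formats, run configuration and provenance.

The XYZ dialect written here is standard XYZ with a structured comment
line carrying the box and per-atom trailing columns for chain and residue
indices, so a write -> read round trip preserves everything an analysis
needs.  PDB export (first frame) goes through biotite.  Run configuration
is TOML; every artifact can be stamped with the config hash, seed and
package version.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Trajectory

_COORD_FMT = "{:.4f}"   # 1e-4 nm precision


def write_xyz(traj: Trajectory, path) -> None:
    """Write a trajectory as one XYZ block per frame.

    Line format: ``C<chain> x y z chain residue`` with coordinates in nm;
    the comment line carries the frame index, box and sampling interval.
    """
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            box = ("none" if traj.box is None else
                   ",".join(_COORD_FMT.format(b) for b in traj.box))
            fh.write(f"frame={f} box={box} dt={traj.sampling_interval}\n")
            for b in range(traj.n_beads):
                x, y, z = traj.frames[f, b]
                fh.write("B {} {} {} {} {}\n".format(
                    _COORD_FMT.format(x), _COORD_FMT.format(y),
                    _COORD_FMT.format(z), traj.chain_id[b],
                    traj.residue_index[b]))


class XYZParseError(ValueError):
    pass


def read_xyz(path) -> Trajectory:
    """Read a trajectory written by write_xyz.

    Raises XYZParseError with a line number on malformed headers or
    inconsistent atom counts between frames.
    """
    frames, chain_id, residue_index = [], None, None
    box = None
    dt = 1.0
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"line {i + 1}: expected an atom count")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise XYZParseError(
                f"line {i + 1}: atom count {n} differs from first frame "
                f"({n_expected})")
        header = lines[i + 1] if i + 1 < len(lines) else ""
        for tok in header.split():
            if tok.startswith("box="):
                val = tok[4:]
                box = (None if val == "none" else
                       np.array([float(v) for v in val.split(",")]))
            elif tok.startswith("dt="):
                dt = float(tok[3:])
        coords = np.empty((n, 3))
        cids, rids = np.empty(n, dtype=int), np.empty(n, dtype=int)
        for b in range(n):
            ln = i + 2 + b
            if ln >= len(lines):
                raise XYZParseError(f"line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) != 6:
                raise XYZParseError(f"line {ln + 1}: expected 6 columns")
            coords[b] = [float(v) for v in parts[1:4]]
            cids[b], rids[b] = int(parts[4]), int(parts[5])
        frames.append(coords)
        chain_id, residue_index = cids, rids
        i += 2 + n
    if not frames:
        return Trajectory(np.zeros((0, 0, 3)), np.zeros(0, dtype=int),
                          np.zeros(0, dtype=int), box=None,
                          sampling_interval=dt)
    return Trajectory(np.array(frames), chain_id, residue_index, box=box,
                      sampling_interval=dt)


def write_pdb(traj: Trajectory, path, frame: int = 0,
              types: list[str] | None = None) -> None:
    """Export one frame as PDB (coordinates converted nm -> Angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_beads
    arr = struc.AtomArray(n)
    arr.coord = traj.frames[frame] * 10.0
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    names = types if types is not None else ["GLY"] * n
    arr.res_name = np.array([f"{t[:3].upper():<3}" for t in names])
    arr.res_id = traj.residue_index + 1
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    arr.chain_id = np.array([chains[c % len(chains)] for c in traj.chain_id])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


@dataclass
class RunConfig:
    """Serializable description of a processing run."""

    stages: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        return cls(stages=list(run.get("stages", [])),
                   parameters={k: v for k, v in raw.items() if k != "run"},
                   seed=int(run.get("seed", 0)),
                   output_dir=run.get("output_dir", "."),
                   log_level=run.get("log_level", "INFO"))

    def config_hash(self) -> str:
        blob = json.dumps(
            {"stages": self.stages, "parameters": self.parameters,
             "seed": self.seed},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_provenance(path, config: RunConfig, extra: dict | None = None) -> None:
    """Append a provenance record (seed, config hash, package version)."""
    from . import __version__

    record = {"config_hash": config.config_hash(), "seed": config.seed,
              "version": __version__}
    if extra:
        record.update(extra)
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")
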