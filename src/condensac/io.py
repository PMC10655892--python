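"""Trajectory and topology readers/writers (plain-text formats).

Supported formats:

* extended XYZ (``.xyz``): one block per frame — atom count, a comment
  line carrying ``Lattice``/``Time`` metadata, then ``species x y z``
  rows.  Species names are chromatin / anchor / bridge.
* LAMMPS dump text (``.lammpstrj``): ``id type x y z`` with types
  1 = chromatin, 2 = anchor, 3 = bridge.
* LAMMPS data file (write-only): full molecular topology (atoms, bonds
  typed 1 = chain, 2 = loop spring, 3 = centromere, angles type 1) so a
  run can be cross-validated in an external engine.

Coordinates are always written unwrapped; the periodic box appears only
as metadata, so observables never need image reconstruction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .forcefield import ForceField
from .topology import SPECIES_CODES, SPECIES_NAMES, ChromosomeTopology


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message carries the offending line."""


# ---------------------------------------------------------------------------
# extended XYZ

def write_xyz(traj: Trajectory, path: str | Path, precision: int = 6) -> None:
    names = np.array([SPECIES_NAMES[int(s)] for s in traj.species])
    fmt = f"%s %.{precision}f %.{precision}f %.{precision}f"
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{frame.shape[0]}\n")
            L = traj.box
            fh.write(
                f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
                f"Properties=species:S:1:pos:R:3 Time={t}\n"
            )
            for name, row in zip(names, frame):
                fh.write(fmt % (name, row[0], row[1], row[2]) + "\n")


def read_xyz(path: str | Path) -> Trajectory:
    frames, times, species = [], [], None
    box = 0.0
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError as err:
            raise TrajectoryParseError(
                f"line {ln + 1}: expected atom count, got {lines[ln]!r}"
            ) from err
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        t = 0.0
        for token in comment.split():
            if token.startswith("Time="):
                t = float(token[5:])
            if token.startswith('Lattice="'):
                box = float(token[9:].split()[0])
        if ln + 2 + natoms > len(lines):
            raise TrajectoryParseError(
                f"line {ln + 1}: frame declares {natoms} atoms but file ends early"
            )
        sp = np.empty(natoms, dtype=np.int8)
        xyz = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[ln + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"line {ln + 3 + k}: expected 'species x y z'"
                )
            if parts[0] not in SPECIES_CODES:
                raise TrajectoryParseError(
                    f"line {ln + 3 + k}: unknown species {parts[0]!r}"
                )
            sp[k] = SPECIES_CODES[parts[0]]
            xyz[k] = [float(v) for v in parts[1:4]]
        if species is None:
            species = sp
        elif not np.array_equal(species, sp) or natoms != frames[0].shape[0]:
            raise TrajectoryParseError(
                f"line {ln + 1}: frame size/species differ from first frame"
            )
        frames.append(xyz)
        times.append(t)
        ln += 2 + natoms
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    return Trajectory(
        frames=np.array(frames), times=np.array(times),
        species=species, box=box,
    )


# ---------------------------------------------------------------------------
# LAMMPS dump

def write_lammps_dump(traj: Trajectory, path: str | Path,
                      precision: int = 6) -> None:
    fmt = f"%d %d %.{precision}f %.{precision}f %.{precision}f"
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{t}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{frame.shape[0]}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            half = traj.box / 2.0 if traj.box > 0 else 0.0
            for _ in range(3):
                fh.write(f"{-half} {half}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i, row in enumerate(frame):
                fh.write(
                    fmt % (i + 1, int(traj.species[i]) + 1,
                           row[0], row[1], row[2]) + "\n"
                )


def read_lammps_dump(path: str | Path) -> Trajectory:
    frames, times, species = [], [], None
    box = 0.0
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    nlines = len(lines)
    while ln < nlines:
        if not lines[ln].strip():
            ln += 1
            continue
        if not lines[ln].startswith("ITEM: TIMESTEP"):
            raise TrajectoryParseError(
                f"line {ln + 1}: expected 'ITEM: TIMESTEP', got {lines[ln]!r}"
            )
        try:
            t = float(lines[ln + 1])
            if not lines[ln + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise TrajectoryParseError(
                    f"line {ln + 3}: expected 'ITEM: NUMBER OF ATOMS'"
                )
            natoms = int(lines[ln + 3])
        except (ValueError, IndexError) as err:
            raise TrajectoryParseError(
                f"line {ln + 2}: malformed frame header"
            ) from err
        if not lines[ln + 4].startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryParseError(f"line {ln + 5}: expected box bounds")
        lo, hi = (float(v) for v in lines[ln + 5].split()[:2])
        box = hi - lo
        if not lines[ln + 8].startswith("ITEM: ATOMS"):
            raise TrajectoryParseError(
                f"line {ln + 9}: expected 'ITEM: ATOMS id type x y z'"
            )
        if ln + 9 + natoms > nlines:
            raise TrajectoryParseError(
                f"line {ln + 4}: frame declares {natoms} atoms but file ends early"
            )
        sp = np.empty(natoms, dtype=np.int8)
        xyz = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[ln + 9 + k].split()
            if len(parts) < 5:
                raise TrajectoryParseError(
                    f"line {ln + 10 + k}: expected 'id type x y z'"
                )
            idx = int(parts[0]) - 1
            sp[idx] = int(parts[1]) - 1
            xyz[idx] = [float(v) for v in parts[2:5]]
        if species is None:
            species = sp
        elif natoms != frames[0].shape[0]:
            raise TrajectoryParseError(
                f"line {ln + 4}: inconsistent atom count {natoms}"
            )
        frames.append(xyz)
        times.append(t)
        ln += 9 + natoms
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    return Trajectory(
        frames=np.array(frames), times=np.array(times),
        species=species, box=box,
    )


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Dispatch on ``format`` or file suffix (.xyz / .lammpstrj)."""
    if format is None:
        suffix = Path(path).suffix
        format = {"xyz": "xyz_extended", ".xyz": "xyz_extended",
                  ".lammpstrj": "lammps_dump", ".dump": "lammps_dump"}.get(
            suffix, "xyz_extended")
    if format == "xyz_extended":
        write_xyz(traj, path)
    elif format == "lammps_dump":
        write_lammps_dump(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: str | Path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("ITEM:"):
        return read_lammps_dump(path)
    return read_xyz(path)


# ---------------------------------------------------------------------------
# LAMMPS data file (topology export for cross-validation)

def write_lammps_data(
    topo: ChromosomeTopology,
    positions: np.ndarray,
    box: float,
    path: str | Path,
    ff: ForceField | None = None,
) -> None:
    """Write a LAMMPS molecular data file for the polymer + bridges."""
    ff = ff or ForceField()
    n = positions.shape[0]
    n_bridges = n - topo.n_beads
    species = topo.species_with_bridges(n_bridges)
    bond_blocks = [
        (1, topo.chain_bonds),
        (2, topo.loop_springs),
        (3, topo.centromere_springs),
    ]
    n_bonds = sum(len(b) for _, b in bond_blocks)
    half = box / 2.0
    with open(path, "w") as fh:
        fh.write("condensac chromosome topology\n\n")
        fh.write(f"{n} atoms\n{n_bonds} bonds\n"
                 f"{len(topo.angle_triplets)} angles\n\n")
        fh.write("3 atom types\n3 bond types\n1 angle types\n\n")
        for axis in ("x", "y", "z"):
            fh.write(f"{-half} {half} {axis}lo {axis}hi\n")
        fh.write("\nMasses\n\n1 1.0\n2 1.0\n3 1.0\n\nAtoms\n\n")
        per = topo.beads_per_chromatid
        for i in range(n):
            if i < topo.n_beads:
                mol = i // per + 1
            else:
                mol = topo.n_chromatids + 1
            fh.write(
                f"{i + 1} {mol} {int(species[i]) + 1} "
                f"{positions[i, 0]:.6f} {positions[i, 1]:.6f} "
                f"{positions[i, 2]:.6f}\n"
            )
        if n_bonds:
            fh.write("\nBonds\n\n")
            bid = 1
            for btype, block in bond_blocks:
                for i, j in block:
                    fh.write(f"{bid} {btype} {i + 1} {j + 1}\n")
                    bid += 1
        if len(topo.angle_triplets):
            fh.write("\nAngles\n\n")
            for a, (i, j, k) in enumerate(topo.angle_triplets):
                fh.write(f"{a + 1} 1 {i + 1} {j + 1} {k + 1}\n")


# ---------------------------------------------------------------------------
# observable tables

def write_series_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Tidy CSV with time (or s) as the first column."""
    df.to_csv(path, index=False)


def read_series_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
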