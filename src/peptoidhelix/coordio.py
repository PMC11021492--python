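"""Reading and writing labelled ribbon coordinates (XYZ and PDB).

XYZ dialect: standard XYZ blocks (count line, comment line, atom lines), one
block per frame.  The comment line carries ``frame=<i> units=nm`` and the atom
name field encodes the lattice labels as ``<U|L><column>_<segment>_<residue>``
(e.g. ``U12_3_0`` is upper leaflet, column 12, segment 3, residue 0).
Positions are in nm.

PDB mapping (positions in Å, biotite does the parsing): chain ID = leaflet
(``U``/``L``), B-factor = column index, occupancy = segment index, atom name =
``R<residue>``; monomer ids are recomputed canonically from the labels on
read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import LabelingError, ParseError
from .geometry import LabeledCoordinates, RibbonLattice, canonical_monomer_ids

__all__ = ["read_coordinates", "write_coordinates", "read_xyz", "write_xyz", "read_pdb", "write_pdb"]

_NAME_RE = re.compile(r"^([UL])(\d+)_(\d+)_(\d+)$")


def _encode_names(coords: LabeledCoordinates) -> list[str]:
    letters = np.where(coords.leaflet > 0, "U", "L")
    return [
        f"{lt}{c}_{s}_{r}"
        for lt, c, s, r in zip(letters, coords.column, coords.segment, coords.residue)
    ]


def write_xyz(
    frames: LabeledCoordinates | Sequence[LabeledCoordinates], path: str | Path
) -> None:
    """Write one or more frames to a labelled multi-frame XYZ file (nm)."""
    if isinstance(frames, LabeledCoordinates):
        frames = [frames]
    path = Path(path)
    with path.open("w") as fh:
        for i, coords in enumerate(frames):
            names = _encode_names(coords)
            fh.write(f"{coords.n_points}\n")
            fh.write(f"frame={i} units=nm\n")
            for name, (x, y, z) in zip(names, coords.positions):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, lattice: RibbonLattice | None = None) -> list[LabeledCoordinates]:
    """Read a labelled (multi-frame) XYZ file; returns one entry per frame."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[LabeledCoordinates] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}", line=i + 1)
        body = lines[i + 2 : i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ParseError(
                f"truncated frame: expected {n_atoms} atom records", line=len(lines)
            )
        pos = np.empty((n_atoms, 3))
        leaflet = np.empty(n_atoms, dtype=int)
        column = np.empty(n_atoms, dtype=int)
        segment = np.empty(n_atoms, dtype=int)
        residue = np.empty(n_atoms, dtype=int)
        for j, line in enumerate(body):
            lineno = i + 3 + j
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"expected 'name x y z', got {line!r}", line=lineno)
            m = _NAME_RE.match(parts[0])
            if m is None:
                raise LabelingError(
                    f"line {lineno}: atom name {parts[0]!r} does not encode "
                    "'<U|L><column>_<segment>_<residue>' labels"
                )
            try:
                pos[j] = [float(p) for p in parts[1:]]
            except ValueError:
                raise ParseError(f"bad coordinate in {line!r}", line=lineno)
            leaflet[j] = 1 if m.group(1) == "U" else -1
            column[j] = int(m.group(2))
            segment[j] = int(m.group(3))
            residue[j] = int(m.group(4))
        frames.append(
            LabeledCoordinates(
                positions=pos,
                monomer_id=canonical_monomer_ids(leaflet, column, segment),
                leaflet=leaflet,
                column=column,
                segment=segment,
                residue=residue,
                lattice=lattice or RibbonLattice(),
            )
        )
        i += 2 + n_atoms
    if not frames:
        raise ParseError("no frames found", line=1)
    return frames


def write_pdb(coords: LabeledCoordinates, path: str | Path) -> None:
    """Write a single frame as PDB (Å; labels per the module docstring)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = coords.n_points
    atoms = struc.AtomArray(n)
    atoms.coord = coords.positions * 10.0  # nm -> Å
    atoms.chain_id = np.where(coords.leaflet > 0, "U", "L")
    atoms.res_id = coords.monomer_id + 1  # PDB res ids are 1-based
    atoms.res_name = np.full(n, "RIB")
    atoms.atom_name = np.array([f"R{r}" for r in coords.residue])
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, True)
    atoms.set_annotation("b_factor", coords.column.astype(float))
    atoms.set_annotation("occupancy", coords.segment.astype(float))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb(path: str | Path, lattice: RibbonLattice | None = None) -> LabeledCoordinates:
    """Read a single-frame PDB written by :func:`write_pdb`."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, extra_fields=["b_factor", "occupancy"])
    except Exception as exc:  # biotite raises various parse errors
        raise ParseError(f"could not parse PDB file: {exc}") from exc
    chain = np.asarray(atoms.chain_id)
    if not set(np.unique(chain)) <= {"U", "L"}:
        raise LabelingError("PDB chain ids must be 'U'/'L' to encode leaflets")
    names = np.asarray(atoms.atom_name)
    try:
        residue = np.array([int(n.lstrip("R")) for n in names])
    except ValueError:
        raise LabelingError("PDB atom names must be 'R<residue index>'")
    leaflet = np.where(chain == "U", 1, -1)
    column = np.asarray(atoms.b_factor).astype(int)
    segment = np.asarray(atoms.occupancy).astype(int)
    return LabeledCoordinates(
        positions=np.asarray(atoms.coord) / 10.0,  # Å -> nm
        monomer_id=canonical_monomer_ids(leaflet, column, segment),
        leaflet=leaflet,
        column=column,
        segment=segment,
        residue=residue,
        lattice=lattice or RibbonLattice(),
    )


def write_coordinates(
    frames: LabeledCoordinates | Sequence[LabeledCoordinates],
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write coordinates, dispatching on ``fmt`` or the file suffix."""
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "xyz":
        write_xyz(frames, path)
    elif fmt == "pdb":
        if not isinstance(frames, LabeledCoordinates):
            frames = list(frames)
            if len(frames) != 1:
                raise ValueError("PDB output supports a single frame")
            frames = frames[0]
        write_pdb(frames, path)
    else:
        raise ValueError(f"unknown coordinate format {fmt!r}")


def read_coordinates(
    path: str | Path, fmt: str | None = None, lattice: RibbonLattice | None = None
) -> list[LabeledCoordinates]:
    """Read coordinates (always a list of frames), dispatching on suffix."""
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz(path, lattice)
    if fmt == "pdb":
        return [read_pdb(path, lattice)]
    raise ValueError(f"unknown coordinate format {fmt!r}")
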