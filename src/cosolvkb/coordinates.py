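"""Coordinate file I/O: GRO, PDB and extended XYZ.

GRO and extended-XYZ support concatenated multi-frame files; PDB reading is
delegated to MDAnalysis (multi-MODEL files supported).  Positions are nm in
memory; the PDB boundary converts from Angstrom.  Extended XYZ is this
package's dialect: the comment line carries ``box=Lx Ly Lz`` in nm.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .structure import Frame, Trajectory, build_topology


class CoordinateParseError(ValueError):
    """Raised when a coordinate file does not conform to its format."""


_FORMATS = ("gro", "pdb", "xyz")


def _format_from_path(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported coordinate format {fmt!r}")
    return fmt


def read_coordinates(path, format: str | None = None,
                     species_map: dict | None = None) -> Trajectory:
    """Read a configuration/trajectory file into a :class:`Trajectory`.

    Parameters
    ----------
    path : file path
    format : "gro" | "pdb" | "xyz", inferred from the suffix when omitted
    species_map : optional residue-name -> species override table
    """
    fmt = _format_from_path(path, format)
    if fmt == "gro":
        return _read_gro(path, species_map)
    if fmt == "pdb":
        return _read_pdb(path, species_map)
    return _read_xyz(path, species_map)


def write_coordinates(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory to GRO or extended XYZ (all frames, concatenated)."""
    fmt = _format_from_path(path, format)
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    if fmt == "gro":
        _write_gro(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"writing format {fmt!r} is not supported")


# ---------------------------------------------------------------- GRO ------

def _parse_box_line(tokens, lineno):
    vals = [float(t) for t in tokens]
    if len(vals) == 3:
        box = vals
    elif len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise CoordinateParseError(
                f"line {lineno}: triclinic box is not supported")
        box = vals[:3]
    else:
        raise CoordinateParseError(
            f"line {lineno}: box line must carry 3 or 9 floats")
    if any(v <= 0 for v in box):
        raise CoordinateParseError(f"line {lineno}: box edges must be > 0")
    return np.array(box)


def _read_gro(path, species_map):
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = []
    topo = None
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        if i + 1 >= len(lines):
            raise CoordinateParseError(
                f"line {i + 1}: truncated GRO frame (missing atom count)")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise CoordinateParseError(
                f"line {i + 2}: expected atom count, got "
                f"{lines[i + 1]!r}") from None
        if i + 2 + natoms > len(lines) - 1:
            raise CoordinateParseError(
                f"line {len(lines)}: truncated GRO frame "
                f"(expected {natoms} atoms plus a box line)")
        names, resnames, resids = [], [], []
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            ln = lines[i + 2 + k]
            lineno = i + 3 + k
            if len(ln) < 44:
                raise CoordinateParseError(
                    f"line {lineno}: GRO atom line too short")
            try:
                resids.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                pos[k, 0] = float(ln[20:28])
                pos[k, 1] = float(ln[28:36])
                pos[k, 2] = float(ln[36:44])
            except ValueError:
                raise CoordinateParseError(
                    f"line {lineno}: malformed fixed-width GRO atom "
                    f"line") from None
        box_line = lines[i + 2 + natoms]
        box = _parse_box_line(box_line.split(), i + 3 + natoms)
        if topo is None:
            from .data import species_from_residue
            topo = build_topology(
                names, resnames, resids,
                species=[species_from_residue(r, species_map)
                         for r in resnames])
        frames.append(Frame(positions=pos, box=box))
        i += 3 + natoms
        while i < len(lines) and not lines[i].strip():
            i += 1
    if topo is None:
        raise CoordinateParseError("line 1: empty GRO file")
    return Trajectory(topology=topo, frames=frames)


def _write_gro(traj, path):
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write("written by cosolvkb\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for a, p in zip(traj.topology, fr.positions):
                fh.write(
                    f"{a.residue_index % 100000:5d}"
                    f"{a.residue_name:<5.5s}{a.name:>5.5s}"
                    f"{(a.index + 1) % 100000:5d}"
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n")
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}"
                     f"{fr.box[2]:10.5f}\n")


# ---------------------------------------------------------------- PDB ------

def _read_pdb(path, species_map):
    import MDAnalysis as mda
    from .data import species_from_residue

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - surface as parse error
            raise CoordinateParseError(f"PDB parse failure: {exc}") from exc
        dims = u.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            raise CoordinateParseError(
                "PDB file lacks a CRYST1 box; an explicit box is required")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise CoordinateParseError("non-orthorhombic PDB box")
        names = [str(n) for n in u.atoms.names]
        resnames = [str(r) for r in u.atoms.resnames]
        resids = [int(r) for r in u.atoms.resids]
        topo = build_topology(
            names, resnames, resids,
            species=[species_from_residue(r, species_map) for r in resnames])
        frames = []
        for ts in u.trajectory:
            frames.append(Frame(positions=ts.positions.astype(float) / 10.0,
                                box=np.asarray(ts.dimensions[:3],
                                               dtype=float) / 10.0))
    return Trajectory(topology=topo, frames=frames)


# ---------------------------------------------------------------- XYZ ------

def _read_xyz(path, species_map):
    from .data import species_from_residue

    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, topo = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise CoordinateParseError(
                f"line {i + 1}: expected atom count") from None
        if i + 1 >= len(lines):
            raise CoordinateParseError(f"line {i + 1}: missing comment line")
        comment = lines[i + 1]
        box = None
        for tok in comment.split():
            if tok.startswith("box="):
                parts = tok[4:].split(",") if "," in tok else None
                if parts is None:
                    # "box=Lx Ly Lz": take this token plus the next two
                    rest = comment.split("box=", 1)[1].split()
                    parts = rest[:3]
                box = _parse_box_line(parts, i + 2)
                break
        if box is None:
            raise CoordinateParseError(
                f"line {i + 2}: XYZ comment line must carry 'box=Lx Ly Lz'")
        if i + 2 + natoms > len(lines):
            raise CoordinateParseError(
                f"line {len(lines)}: truncated XYZ frame")
        names, resnames = [], []
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            toks = lines[i + 2 + k].split()
            if len(toks) < 4:
                raise CoordinateParseError(
                    f"line {i + 3 + k}: XYZ atom line needs 'name x y z'")
            names.append(toks[0])
            try:
                pos[k] = [float(t) for t in toks[1:4]]
            except ValueError:
                raise CoordinateParseError(
                    f"line {i + 3 + k}: non-numeric XYZ coordinate") from None
            resnames.append(toks[4] if len(toks) > 4 else "UNK")
        if topo is None:
            topo = build_topology(
                names, resnames, list(range(1, natoms + 1)),
                species=[species_from_residue(r, species_map)
                         for r in resnames])
        frames.append(Frame(positions=pos, box=box))
        i += 2 + natoms
    if topo is None:
        raise CoordinateParseError("line 1: empty XYZ file")
    return Trajectory(topology=topo, frames=frames)


def _write_xyz(traj, path):
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"box={fr.box[0]:.6f} {fr.box[1]:.6f} "
                     f"{fr.box[2]:.6f}\n")
            for a, p in zip(traj.topology, fr.positions):
                fh.write(f"{a.name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                         f"{a.residue_name}\n")
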