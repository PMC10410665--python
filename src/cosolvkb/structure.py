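"""Particle-configuration data model and periodic-boundary geometry.

Coordinates are stored in nm throughout (GRO convention).  Only orthorhombic
boxes are supported: every box is a triple of positive edge lengths, and all
minimum-image arithmetic assumes axis-aligned periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data import species_from_residue

VALID_SPECIES = ("protein", "water", "tba", "excipient", "ion")


@dataclass
class AtomRecord:
    """One atom of the topology.

    Masses are in amu, charges in elementary charges, radii in nm.  The
    ``species`` tag is the role the atom plays in the analysis (protein,
    water, tba, excipient, ion), normally inferred from the residue name.
    """

    index: int
    name: str
    species: str
    residue_index: int
    residue_name: str
    mass: float = 0.0
    charge: float = 0.0
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(f"unknown species tag {self.species!r}")
        if self.mass < 0:
            raise ValueError("mass must be >= 0")
        if self.vdw_radius < 0:
            raise ValueError("vdw_radius must be >= 0")


@dataclass
class Frame:
    """Positions (n_atoms, 3) in nm plus orthorhombic box edge lengths."""

    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(self.box > 0):
            raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: list[AtomRecord]
    frames: list[Frame]
    frame_interval: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = len(self.topology)
        idx = [a.index for a in self.topology]
        if len(set(idx)) != n:
            raise ValueError("atom indices must be unique within a topology")
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {fr.n_atoms} positions for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    # cached per-topology arrays -------------------------------------------
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    def species(self) -> np.ndarray:
        return np.array([a.species for a in self.topology])

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.topology])

    def select(self, species: str | None = None,
               residue_names: Iterable[str] | None = None,
               indices: Sequence[int] | None = None) -> np.ndarray:
        """Return atom indices matching the intersection of the criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            mask &= self.species() == species
        if residue_names is not None:
            names = {r.upper() for r in residue_names}
            mask &= np.array(
                [a.residue_name.upper() in names for a in self.topology])
        if indices is not None:
            sub = np.zeros(self.n_atoms, dtype=bool)
            sub[np.asarray(indices, dtype=int)] = True
            mask &= sub
        return np.nonzero(mask)[0]


def resolve_selection(traj: Trajectory, sel) -> np.ndarray:
    """Resolve a selection to an index array.

    ``sel`` may be a species tag string, an iterable of atom indices, or a
    boolean mask of length n_atoms.
    """
    if isinstance(sel, str):
        out = traj.select(species=sel)
    else:
        arr = np.asarray(sel)
        if arr.dtype == bool:
            if arr.shape != (traj.n_atoms,):
                raise ValueError("boolean selection mask has wrong length")
            out = np.nonzero(arr)[0]
        else:
            out = arr.astype(int)
            if out.size and (out.min() < 0 or out.max() >= traj.n_atoms):
                raise IndexError("selection index out of range")
    return out


def minimum_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(frame: Frame, a: int, b: int) -> float:
    """Minimum-image Euclidean distance (nm) between atoms ``a`` and ``b``."""
    n = frame.n_atoms
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"atom index out of range for frame of {n} atoms")
    d = frame.positions[b] - frame.positions[a]
    return float(np.linalg.norm(minimum_image_displacement(d, frame.box)))


def pairwise_min_image_distances(pos_a: np.ndarray, pos_b: np.ndarray,
                                 box: np.ndarray) -> np.ndarray:
    """(len_a, len_b) matrix of minimum-image distances."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d = minimum_image_displacement(d, box)
    return np.sqrt((d * d).sum(axis=-1))


def wrap_positions(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map positions into the primary cell [0, L) on each axis."""
    return np.mod(pos, np.asarray(box, dtype=float))


def analysis_window(traj: Trajectory, fraction: float = 0.8) -> Trajectory:
    """Keep the trailing ``fraction`` of frames for analysis.

    Mirrors the common practice of discarding the equilibration head of a
    trajectory; the default keeps the last 80% of frames.
    """
    if not 0 < fraction <= 1:
        raise ValueError("window fraction must be in (0, 1]")
    n = traj.n_frames
    skip = int(round((1 - fraction) * n))
    skip = min(skip, n - 1)
    return Trajectory(topology=traj.topology, frames=traj.frames[skip:],
                      frame_interval=traj.frame_interval, info=dict(traj.info))


def build_topology(names, residue_names, residue_indices,
                   species=None, masses=None, charges=None,
                   vdw_radii=None) -> list[AtomRecord]:
    """Assemble AtomRecords from parallel per-atom sequences.

    Species default to the packaged residue-name map; masses and radii
    default to element lookups keyed on the atom name.
    """
    from .data import element_mass, element_vdw_radius

    n = len(names)
    records = []
    for i in range(n):
        rn = residue_names[i]
        records.append(AtomRecord(
            index=i,
            name=names[i],
            species=(species[i] if species is not None
                     else species_from_residue(rn)),
            residue_index=int(residue_indices[i]),
            residue_name=rn,
            mass=(masses[i] if masses is not None
                  else element_mass(names[i], rn)),
            charge=(charges[i] if charges is not None else 0.0),
            vdw_radius=(vdw_radii[i] if vdw_radii is not None
                        else element_vdw_radius(names[i], rn)),
        ))
    return records
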