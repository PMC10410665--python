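"""Interfacial density profiles, radius of gyration, and accessible surface.

SASA uses a Shrake-Rupley-style construction with a deterministic
golden-spiral point set on each expanded sphere (atom radius + probe), so
repeated runs give bitwise-identical areas.  Periodic images are ignored in
the SASA computation: the protein is assumed compact and far from its own
images, which holds for all systems this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import guess_element
from .structure import Frame, Trajectory, resolve_selection, wrap_positions

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class DensityProfile:
    axis: str
    centers: np.ndarray        # nm
    dimensionless: np.ndarray  # rho(z)/<rho>, per bin
    counts: np.ndarray         # raw counts summed over frames (int)
    n_frames: int


def density_profile(traj: Trajectory, sel, axis: str = "z",
                    dz: float = 0.1) -> DensityProfile:
    """Frame-averaged dimensionless density along a box axis.

    Each slab count is divided by the whole-box mean count per slab, so a
    homogeneous system sits at 1 and vacuum slabs at 0; the plain average
    of the profile over all bins is 1 by construction.  ``dz`` must divide
    the box edge (within rounding).
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {tuple(_AXES)}")
    ax = _AXES[axis]
    idx = resolve_selection(traj, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    L = float(traj.frames[0].box[ax])
    n_bins = int(round(L / dz))
    if n_bins < 1 or abs(n_bins * dz - L) > 1e-6 * max(L, 1.0):
        raise ValueError(f"dz={dz} does not divide the box edge {L}")
    edges = np.linspace(0.0, L, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for fr in traj.frames:
        z = wrap_positions(fr.positions[idx], fr.box)[:, ax]
        h, _ = np.histogram(z, bins=edges)
        counts += h
    mean_per_bin = counts.sum() / n_bins
    dimensionless = counts / mean_per_bin
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(axis=axis, centers=centers,
                          dimensionless=dimensionless, counts=counts,
                          n_frames=traj.n_frames)


def _unwrap(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a selection whole by minimum-image displacement from atom 0.

    Fails silently for objects extending beyond half the box; callers
    analysing such selections should unwrap upstream.
    """
    d = pos - pos[0]
    d -= box * np.round(d / box)
    return pos[0] + d


def radius_of_gyration(frame: Frame, sel, masses=None,
                       mass_weighted: bool = True) -> float:
    """Radius of gyration (nm) of a selection, whole across the boundary."""
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    pos = _unwrap(frame.positions[idx], frame.box)
    if mass_weighted:
        if masses is None:
            raise ValueError("masses are required when mass_weighted")
        m = np.asarray(masses, dtype=float)[idx] if len(masses) != len(idx) \
            else np.asarray(masses, dtype=float)
        if m.sum() <= 0:
            raise ValueError("total mass must be positive")
    else:
        m = np.ones(idx.size)
    com = (m[:, None] * pos).sum(axis=0) / m.sum()
    sq = ((pos - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def golden_spiral_points(n: int) -> np.ndarray:
    """n points quasi-uniformly distributed on the unit sphere (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(frame: Frame, sel, radii=None, probe: float = 0.14,
         n_sphere_points: int = 960,
         topology: list | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (nm^2).

    Test points on each atom's expanded sphere (vdW radius + probe) count
    as accessible when they fall outside every other selected atom's
    expanded sphere; the per-atom area is the accessible fraction times the
    expanded-sphere area.  ``radii`` may be a full per-topology-atom array
    or one value per selected atom; when omitted they are taken from
    ``topology`` AtomRecords.
    """
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if radii is None:
        if topology is None:
            raise ValueError("either radii or topology must be given")
        radii = np.array([topology[i].vdw_radius for i in idx])
    else:
        radii = np.asarray(radii, dtype=float)
        if radii.shape[0] not in (idx.size,):
            radii = radii[idx]
    bad = np.nonzero(radii <= 0)[0]
    if bad.size:
        raise ValueError(
            f"missing vdW radius for selected atom(s) {idx[bad].tolist()}")
    pos = _unwrap(frame.positions[idx], frame.box)
    R = radii + probe
    sphere = golden_spiral_points(n_sphere_points)
    n = idx.size
    areas = np.empty(n)
    # neighbor lists from pairwise separations of expanded spheres
    dvec = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((dvec ** 2).sum(axis=-1))
    for i in range(n):
        pts = pos[i] + R[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        neighbors = np.nonzero((dist[i] < R[i] + R) & (np.arange(n) != i))[0]
        for j in neighbors:
            d2 = ((pts - pos[j]) ** 2).sum(axis=1)
            accessible &= d2 > R[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * R[i] ** 2
    return areas


def default_hydrophobic_mask(topology, sel) -> np.ndarray:
    """Atom-based hydrophobicity: carbon and sulfur count as hydrophobic."""
    idx = np.asarray(sel, dtype=int)
    return np.array([guess_element(topology[i].name,
                                   topology[i].residue_name) in ("C", "S")
                     for i in idx])


def hydrophobic_fraction(areas, hydrophobic_mask) -> float:
    """Fraction of total SASA contributed by hydrophobic atoms."""
    areas = np.asarray(areas, dtype=float)
    mask = np.asarray(hydrophobic_mask, dtype=bool)
    if areas.shape != mask.shape:
        raise ValueError("areas and classification must align")
    total = areas.sum()
    if total <= 0:
        raise ValueError("total SASA is zero; fraction undefined")
    return float(areas[mask].sum() / total)


def descriptor_series(traj: Trajectory, sel, probe: float = 0.14,
                      n_sphere_points: int = 960,
                      hydrophobic_mask=None) -> pd.DataFrame:
    """Per-frame Rg, total SASA and hydrophobic SASA fraction for a selection.

    Returns a DataFrame with one row per frame; means over the frames are
    the scalar descriptors reported by the pipeline.
    """
    idx = resolve_selection(traj, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    masses = traj.masses()
    radii = np.array([a.vdw_radius for a in traj.topology])
    if hydrophobic_mask is None:
        hydrophobic_mask = default_hydrophobic_mask(traj.topology, idx)
    rows = []
    for k, fr in enumerate(traj.frames):
        rg = radius_of_gyration(fr, idx, masses=masses)
        areas = sasa(fr, idx, radii=radii, probe=probe,
                     n_sphere_points=n_sphere_points)
        rows.append({"frame": k, "rg_nm": rg,
                     "sasa_nm2": float(areas.sum()),
                     "hydrophobic_fraction":
                         hydrophobic_fraction(areas, hydrophobic_mask)})
    return pd.DataFrame(rows)
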