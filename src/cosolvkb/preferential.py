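"""Preferential inclusion/exclusion profiles and residue contact occupancy.

The beta parameter compares how quickly cosolute ("solute") and water
("solvent") populations build up with distance r from the protein surface:

    beta(r) = [n_solute(r) / n_solute(inf)] / [n_solvent(r) / n_solvent(inf)]

where n(r) are frame-averaged cumulative molecule counts within surface
distance r and n(inf) the totals in the system.  beta > 1 means the
cosolute is preferentially included near the surface, beta < 1 excluded;
once r covers the whole box both ratios reach 1 and so does beta.

Surface distance of a molecule is the minimum over protein atoms of the
minimum-image distance from the molecule's center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RESIDUE_CLASS
from .structure import (Frame, Trajectory, pairwise_min_image_distances,
                        resolve_selection)


@dataclass
class BetaProfile:
    r: np.ndarray                 # bin upper edges, nm
    beta: np.ndarray              # NaN where undefined (no solvent yet)
    n_solute_r: np.ndarray        # frame-averaged cumulative counts
    n_solvent_r: np.ndarray
    n_solute_total: int
    n_solvent_total: int

    def at(self, radius: float) -> float:
        """Beta at the first bin edge >= radius."""
        k = int(np.searchsorted(self.r, radius - 1e-12))
        k = min(k, len(self.r) - 1)
        return float(self.beta[k])


def surface_distance(frame: Frame, protein_sel, point) -> float:
    """Distance (nm) from ``point`` to the nearest protein atom center."""
    idx = np.asarray(protein_sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty protein selection")
    d = pairwise_min_image_distances(np.asarray(point, float)[None, :],
                                     frame.positions[idx], frame.box)
    return float(d.min())


def group_molecules(traj: Trajectory, sel) -> list[np.ndarray]:
    """Split a selection into molecules by residue index (sorted, stable)."""
    idx = resolve_selection(traj, sel)
    if idx.size == 0:
        return []
    resid = traj.residue_indices()[idx]
    order = np.argsort(resid, kind="stable")
    idx, resid = idx[order], resid[order]
    cuts = np.nonzero(np.diff(resid))[0] + 1
    return np.split(idx, cuts)


def _molecule_com(frame: Frame, groups, masses) -> np.ndarray:
    """Centers of mass, made whole across the periodic boundary per molecule."""
    out = np.empty((len(groups), 3))
    for k, g in enumerate(groups):
        pos = frame.positions[g]
        ref = pos[0]
        d = pos - ref
        d -= frame.box * np.round(d / frame.box)
        m = masses[g]
        tot = m.sum()
        w = m / tot if tot > 0 else np.full(len(g), 1.0 / len(g))
        out[k] = ref + (w[:, None] * d).sum(axis=0)
    return out


def _surface_distances(frame: Frame, points, protein_idx) -> np.ndarray:
    d = pairwise_min_image_distances(points, frame.positions[protein_idx],
                                     frame.box)
    return d.min(axis=1)


def beta_profile(traj: Trajectory, protein_sel, solute_sel, solvent_sel,
                 dr: float = 0.02, r_max: float | None = None) -> BetaProfile:
    """Beta-parameter profile versus distance from the protein surface.

    ``r_max`` defaults to (sqrt(3)/2) of the largest box edge, which covers
    every point of the periodic cell so the last bin reaches the totals.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    p_idx = resolve_selection(traj, protein_sel)
    if p_idx.size == 0:
        raise ValueError("empty protein selection")
    solute = group_molecules(traj, solute_sel)
    solvent = group_molecules(traj, solvent_sel)
    if not solute or not solvent:
        raise ValueError("solute and solvent selections must be non-empty")
    all_idx = [p_idx, np.concatenate(solute), np.concatenate(solvent)]
    for a in range(3):
        for b in range(a + 1, 3):
            if np.intersect1d(all_idx[a], all_idx[b]).size:
                raise ValueError(
                    "protein/solute/solvent selections must be disjoint")
    if r_max is None:
        r_max = float(np.sqrt(3.0) / 2.0
                      * max(np.max(f.box) for f in traj.frames))
    n_bins = int(np.ceil(r_max / dr - 1e-9))
    edges = (np.arange(n_bins) + 1) * dr
    masses = traj.masses()
    cum_su = np.zeros(n_bins)
    cum_sv = np.zeros(n_bins)
    for fr in traj.frames:
        for groups, acc in ((solute, cum_su), (solvent, cum_sv)):
            com = _molecule_com(fr, groups, masses)
            dist = _surface_distances(fr, com, p_idx)
            # cumulative count within each upper edge
            acc += np.searchsorted(np.sort(dist), edges, side="right")
    cum_su /= traj.n_frames
    cum_sv /= traj.n_frames
    n_su, n_sv = len(solute), len(solvent)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (cum_su / n_su) / (cum_sv / n_sv)
    beta = np.where(cum_sv > 0, beta, np.nan)
    return BetaProfile(r=edges, beta=beta, n_solute_r=cum_su,
                       n_solvent_r=cum_sv, n_solute_total=n_su,
                       n_solvent_total=n_sv)


def contact_occupancy(traj: Trajectory, solute_sel, protein_sel,
                      cutoff: float = 0.3) -> pd.DataFrame:
    """Per-residue solute contact occupancy.

    A residue is "in contact" in a frame when at least one solute molecule's
    center of mass lies within ``cutoff`` (nm, default 0.3) of any atom of
    that residue; the occupancy is the fraction of frames in contact.
    Returns a DataFrame with residue_index, residue_name, occupancy.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    p_idx = resolve_selection(traj, protein_sel)
    if p_idx.size == 0:
        raise ValueError("empty protein residue set")
    solute = group_molecules(traj, solute_sel)
    if not solute:
        raise ValueError("empty solute selection")
    resid = traj.residue_indices()[p_idx]
    uniq = np.unique(resid)
    res_atoms = {ri: p_idx[resid == ri] for ri in uniq}
    names = {}
    for ri in uniq:
        names[ri] = traj.topology[res_atoms[ri][0]].residue_name
    masses = traj.masses()
    hits = {ri: 0 for ri in uniq}
    for fr in traj.frames:
        com = _molecule_com(fr, solute, masses)
        for ri in uniq:
            d = pairwise_min_image_distances(com,
                                             fr.positions[res_atoms[ri]],
                                             fr.box)
            if (d <= cutoff).any():
                hits[ri] += 1
    n = traj.n_frames
    return pd.DataFrame({
        "residue_index": uniq,
        "residue_name": [names[ri] for ri in uniq],
        "occupancy": [hits[ri] / n for ri in uniq],
    })


def occupancy_by_class(table: pd.DataFrame,
                       classification: dict | None = None) -> pd.DataFrame:
    """Mean occupancy per residue chemistry class, ranked descending.

    ``classification`` maps residue names to class labels; the packaged
    default uses positive {LYS, ARG, HIS}, negative {ASP, GLU} and standard
    polar/apolar assignments.  Unclassified residue names raise.
    """
    table = table.copy()
    cls_map = RESIDUE_CLASS if classification is None else classification
    missing = sorted({n for n in table["residue_name"]
                      if n.upper() not in {k.upper() for k in cls_map}})
    if missing:
        raise KeyError(f"unclassified residue names: {missing}")
    upper = {k.upper(): v for k, v in cls_map.items()}
    table["class"] = [upper[n.upper()] for n in table["residue_name"]]
    out = (table.groupby("class", as_index=False)["occupancy"].mean()
           .sort_values("occupancy", ascending=False)
           .reset_index(drop=True))
    return out
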