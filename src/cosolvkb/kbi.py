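"""Radial distribution functions, finite-size correction, Kirkwood-Buff integrals.

The Kirkwood-Buff integral G_ij(R) = int_0^R [g_ij(r) - 1] 4 pi r^2 dr
measures the net excess (G > 0, accumulation) or deficit (G < 0, exclusion)
of species j around species i.  Closed-system simulations bias g_ij at
order 1/N; the excess-particle correction implemented here removes that
bias so the running integral converges to the open-system value.

Normalisation conventions
-------------------------
``closed`` (default) divides shell counts by the closed-system density
(N_j - delta_ij)/V, which makes an ideal uniform mixture give g = 1
exactly.  ``open`` divides by N_j/V, the convention the finite-size
correction is formulated against: for an ideal gas of N particles it gives
g = (N-1)/N and an uncorrected KBI plateau of -(4/3) pi R^3 / N, which the
correction restores to ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import (Trajectory, pairwise_min_image_distances,
                        resolve_selection, wrap_positions)


@dataclass
class RdfCurve:
    r: np.ndarray            # bin centers, nm
    g: np.ndarray            # dimensionless
    counts: np.ndarray       # raw pair counts summed over frames (int)
    n_i: int
    n_j: int
    volume: float            # nm^3 (frame-averaged)
    same_species: bool
    dr: float
    n_frames: int
    normalization: str = "closed"

    @property
    def edges(self) -> np.ndarray:
        n = len(self.r)
        return np.arange(n + 1) * self.dr

    @property
    def shell_volumes(self) -> np.ndarray:
        e = self.edges
        return 4.0 * np.pi / 3.0 * (e[1:] ** 3 - e[:-1] ** 3)


@dataclass
class KbiCurve:
    R: np.ndarray            # integral upper limits, nm (R[0] = 0)
    G: np.ndarray            # nm^3, G[0] = 0
    plateau: float | None = None
    plateau_window: tuple[float, float] | None = None
    plateau_std: float | None = None


def _pair_distances_frame(pos_i, pos_j, box, same, r_max, method):
    """Distances of distinct pairs within r_max (same-species pairs once)."""
    if method == "tree":
        from scipy.spatial import cKDTree
        wi = wrap_positions(pos_i, box)
        wj = wrap_positions(pos_j, box)
        # cKDTree periodic boxes require coordinates strictly inside [0, L)
        wi = np.where(wi >= box, 0.0, wi)
        wj = np.where(wj >= box, 0.0, wj)
        if same:
            tree = cKDTree(wi, boxsize=box)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            if len(pairs) == 0:
                return np.empty(0)
            d = wi[pairs[:, 0]] - wi[pairs[:, 1]]
        else:
            ti = cKDTree(wi, boxsize=box)
            tj = cKDTree(wj, boxsize=box)
            mat = ti.sparse_distance_matrix(tj, r_max, output_type="ndarray")
            if len(mat) == 0:
                return np.empty(0)
            d = wi[mat["i"]] - wj[mat["j"]]
        d -= box * np.round(d / box)
        return np.sqrt((d * d).sum(axis=1))
    # brute force
    dmat = pairwise_min_image_distances(pos_i, pos_j, box)
    if same:
        iu = np.triu_indices(len(pos_i), k=1)
        dist = dmat[iu]
    else:
        dist = dmat.ravel()
    return dist[dist <= r_max]


def compute_rdf(traj: Trajectory, sel_i, sel_j, r_max: float | None = None,
                dr: float = 0.002, normalization: str = "closed",
                method: str = "auto") -> RdfCurve:
    """Radial distribution function between two selections.

    ``r_max`` defaults to half the smallest box edge and may not exceed it.
    Distances use the minimum-image convention; when the two selections are
    identical each unordered pair is counted once and self-pairs are
    excluded.  ``method`` picks the pair search: "brute" (O(N^2) reference),
    "tree" (KD-tree), or "auto".
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    if normalization not in ("closed", "open"):
        raise ValueError(f"unknown normalization {normalization!r}")
    idx_i = resolve_selection(traj, sel_i)
    idx_j = resolve_selection(traj, sel_j)
    if idx_i.size == 0 or idx_j.size == 0:
        raise ValueError("empty selection")
    same = np.array_equal(np.sort(idx_i), np.sort(idx_j))
    if not same and np.intersect1d(idx_i, idx_j).size:
        raise ValueError("selections must be identical or disjoint")
    half_min = min(float(np.min(f.box)) for f in traj.frames) / 2.0
    if r_max is None:
        r_max = half_min
    if r_max > half_min * (1 + 1e-9):
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge {half_min}")
    n_bins = int(np.ceil(r_max / dr - 1e-9))
    edges = np.arange(n_bins + 1) * dr
    if method == "auto":
        method = "tree" if idx_i.size * idx_j.size > 250_000 else "brute"
    counts = np.zeros(n_bins, dtype=np.int64)
    vol = 0.0
    for fr in traj.frames:
        dist = _pair_distances_frame(fr.positions[idx_i],
                                     fr.positions[idx_j], fr.box, same,
                                     edges[-1], method)
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        vol += fr.volume
    vol /= traj.n_frames
    n_i, n_j = idx_i.size, idx_j.size
    delta = 1 if same else 0
    dens_count = n_j - delta if normalization == "closed" else n_j
    rho = dens_count / vol
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    pair_factor = 2.0 if same else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = pair_factor * counts / (traj.n_frames * n_i * rho * shell)
    g = np.where(shell > 0, g, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfCurve(r=centers, g=g, counts=counts, n_i=n_i, n_j=n_j,
                    volume=vol, same_species=same, dr=dr,
                    n_frames=traj.n_frames, normalization=normalization)


def finite_size_corrected_rdf(rdf: RdfCurve) -> RdfCurve:
    """Excess-particle finite-size correction of a closed-system rdf.

    g_corr(r) = g(r) * N_j (1 - v(r)/V) / (N_j (1 - v(r)/V) - dN_j(r) - d_ij)

    with v(r) the sphere volume at the bin's upper edge, dN_j(r) the running
    excess of j particles within r implied by the uncorrected curve, and
    d_ij = 1 for same-species pairs.  For an ideal gas normalised with the
    open convention (g = (N-1)/N) the corrected curve is exactly 1.
    """
    edges = rdf.edges
    v = 4.0 * np.pi / 3.0 * edges[1:] ** 3
    rho_j = rdf.n_j / rdf.volume
    excess = np.cumsum(rho_j * (rdf.g - 1.0) * rdf.shell_volumes)
    delta = 1.0 if rdf.same_species else 0.0
    numer = rdf.n_j * (1.0 - v / rdf.volume)
    denom = numer - excess - delta
    if np.any(denom <= 0):
        raise ValueError(
            "finite-size correction denominator <= 0: system under-sampled "
            "or selection too small for the requested r_max")
    g_corr = rdf.g * numer / denom
    return RdfCurve(r=rdf.r, g=g_corr, counts=rdf.counts, n_i=rdf.n_i,
                    n_j=rdf.n_j, volume=rdf.volume,
                    same_species=rdf.same_species, dr=rdf.dr,
                    n_frames=rdf.n_frames,
                    normalization=rdf.normalization + "+finite_size")


def kbi_running(rdf: RdfCurve) -> KbiCurve:
    """Running Kirkwood-Buff integral by trapezoidal accumulation.

    The integrand (g - 1) 4 pi r^2 is taken at r = 0 (where it vanishes)
    and at each bin center; G is reported at those same grid points.
    """
    r = rdf.r
    if len(r) > 1:
        widths = np.diff(r)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("kbi_running requires uniform bins")
    grid = np.concatenate(([0.0], r))
    integrand = np.concatenate(([0.0],
                                (rdf.g - 1.0) * 4.0 * np.pi * r ** 2))
    G = np.concatenate(([0.0],
                        np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                  * np.diff(grid))))
    return KbiCurve(R=grid, G=G)


def kbi_plateau(kbi: KbiCurve, window: tuple[float, float]) -> KbiCurve:
    """Mean of G over an R window, with its standard deviation.

    The standard deviation over the window is a convergence diagnostic: a
    drifting (unconverged) running integral shows a large value.
    Returns a copy of the curve with the plateau fields filled in.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("plateau window must satisfy R_lo < R_hi")
    mask = (kbi.R >= lo) & (kbi.R <= hi)
    if not mask.any():
        raise ValueError("plateau window contains no curve points")
    vals = kbi.G[mask]
    return KbiCurve(R=kbi.R, G=kbi.G, plateau=float(vals.mean()),
                    plateau_window=(lo, hi),
                    plateau_std=float(vals.std(ddof=0)))


def write_rdf_tsv(path, rdf: RdfCurve, corrected: RdfCurve | None = None,
                  kbi: KbiCurve | None = None, header_extra: str = "") -> None:
    """Export r, g [, g_corrected] [, G] as TSV with a '#' metadata header."""
    cols = [rdf.r, rdf.g]
    names = ["r_nm", "g"]
    if corrected is not None:
        cols.append(corrected.g)
        names.append("g_corrected")
    if kbi is not None:
        # kbi grid = [0] + centers; drop the leading zero to align
        cols.append(kbi.G[1:])
        names.append("G_nm3")
    header = (f"# rdf: dr={rdf.dr} n_i={rdf.n_i} n_j={rdf.n_j} "
              f"frames={rdf.n_frames} normalization={rdf.normalization}")
    if header_extra:
        header += f" {header_extra}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("\t".join(names) + "\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
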