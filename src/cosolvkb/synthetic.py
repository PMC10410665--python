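"""Synthetic configuration generators with known statistical ground truth.

Every analysis stage in this package is validated against configurations
built here: ideal mixtures (g = 1, beta = 1 null models), a Metropolis
Lennard-Jones fluid (nontrivial pair structure), a rigid toy protein with
cosolute placed on prescribed radial shells (beta profiles and contact
occupancies known by construction), and liquid slabs with a vacuum region
(interfacial density profiles).  Generators are deterministic under a fixed
seed and share no global random state.
"""

from __future__ import annotations

import numpy as np

from .observables import golden_spiral_points
from .structure import AtomRecord, Frame, Trajectory

_SHELL_RESNAMES = ("LYS", "ARG", "ASP", "ALA", "SER")


def _single_atom_topology(start_index, start_resid, n, name, resname,
                          species, mass, radius=0.15):
    return [AtomRecord(index=start_index + k, name=name, species=species,
                       residue_index=start_resid + k, residue_name=resname,
                       mass=mass, vdw_radius=radius)
            for k in range(n)]


def gen_ideal_mixture(n_a: int, n_b: int, box, frames: int = 1,
                      seed: int = 0) -> Trajectory:
    """Uncorrelated uniform positions: the exact null model (g = 1, beta = 1).

    Species ``a`` atoms are labeled TBA/tba and ``b`` atoms SOL/water so the
    output drops straight into the solute/solvent selections.
    """
    if n_a < 0 or n_b < 0 or n_a + n_b == 0:
        raise ValueError("need at least one particle")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive edge lengths")
    if frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    topo = (_single_atom_topology(0, 1, n_a, "TB", "TBA", "tba", 74.12)
            + _single_atom_topology(n_a, n_a + 1, n_b, "OW", "SOL",
                                    "water", 18.015))
    frames_out = [Frame(positions=rng.uniform(0, 1, (n_a + n_b, 3)) * box,
                        box=box.copy()) for _ in range(frames)]
    return Trajectory(topology=topo, frames=frames_out,
                      info={"kind": "ideal_mixture", "seed": seed})


def _lj_energy_of(i, pos, L, rc2):
    d = pos - pos[i]
    d -= L * np.round(d / L)
    r2 = (d * d).sum(axis=1)
    r2[i] = np.inf
    m = r2 < rc2
    inv6 = 1.0 / r2[m] ** 3
    return float(np.sum(4.0 * (inv6 * inv6 - inv6)))


def gen_lj_fluid(n: int, reduced_density: float, reduced_temperature: float,
                 sweeps: int, seed: int = 0, burn_in: int | None = None,
                 record_every: int = 1, max_displacement: float = 0.15,
                 sigma_nm: float = 0.34) -> Trajectory:
    """Metropolis sampling of a truncated (2.5 sigma) Lennard-Jones fluid.

    Starts from a simple-cubic lattice; one sweep = n single-particle trial
    moves.  Frames recorded every ``record_every`` sweeps after ``burn_in``
    (default: half the sweeps) are exported in nm via sigma = 0.34 nm.
    The per-sweep total energy series (reduced units, from the lattice
    start) and the overall acceptance rate land in ``Trajectory.info``.
    """
    if not 0 < reduced_density < 1.2:
        raise ValueError("reduced density must lie in (0, 1.2)")
    if reduced_temperature <= 0:
        raise ValueError("reduced temperature must be positive")
    if sweeps < 1 or n < 2:
        raise ValueError("need at least one sweep and two particles")
    if burn_in is None:
        burn_in = sweeps // 2
    if burn_in >= sweeps:
        raise ValueError("burn_in must be smaller than sweeps")
    rng = np.random.default_rng(seed)
    L = (n / reduced_density) ** (1.0 / 3.0)
    rc2 = 2.5 ** 2
    if L < 2 * 2.5:
        # half-box below the cutoff: still fine for sampling, distances are
        # minimum-image, but warn via info flag rather than refusing
        pass
    m = int(np.ceil(n ** (1.0 / 3.0)))
    grid = (np.stack(np.meshgrid(*[np.arange(m)] * 3,
                                 indexing="ij"), axis=-1)
            .reshape(-1, 3)[:n] + 0.5) * (L / m)
    pos = grid.astype(float)
    energy = 0.5 * sum(_lj_energy_of(i, pos, L, rc2) for i in range(n))
    energies = np.empty(sweeps)
    beta = 1.0 / reduced_temperature
    accepted = attempted = 0
    frames_out = []
    for sweep in range(sweeps):
        for _ in range(n):
            i = int(rng.integers(n))
            old = pos[i].copy()
            e_old = _lj_energy_of(i, pos, L, rc2)
            pos[i] = np.mod(old + rng.uniform(-max_displacement,
                                              max_displacement, 3), L)
            e_new = _lj_energy_of(i, pos, L, rc2)
            dE = e_new - e_old
            attempted += 1
            if dE <= 0 or rng.random() < np.exp(-beta * dE):
                accepted += 1
                energy += dE
            else:
                pos[i] = old
        energies[sweep] = energy
        if sweep >= burn_in and (sweep - burn_in) % record_every == 0:
            frames_out.append(Frame(positions=pos * sigma_nm,
                                    box=np.full(3, L * sigma_nm)))
    topo = _single_atom_topology(0, 1, n, "AR", "LJ", "excipient", 39.948,
                                 radius=0.17)
    return Trajectory(topology=topo, frames=frames_out, info={
        "kind": "lj_fluid", "seed": seed,
        "acceptance_rate": accepted / attempted,
        "energy_series": energies, "sigma_nm": sigma_nm,
        "reduced_density": reduced_density,
        "reduced_temperature": reduced_temperature,
        "box_sigma": L,
    })


def gen_shell_protein(n_residues: int, shell_spec, bulk, box,
                      frames: int = 1, seed: int = 0,
                      core_radius: float = 0.4,
                      shell_bias: dict | None = None) -> Trajectory:
    """Rigid toy protein with cosolute on prescribed surface-distance shells.

    The protein is ``n_residues`` one-bead residues (names cycling
    LYS/ARG/ASP/ALA/SER) on a sphere of ``core_radius`` at the box center,
    identical in every frame.  For each ``(radius, count)`` entry of
    ``shell_spec``, ``count`` solute molecules per frame are placed radially
    outward from randomly chosen beads at exactly that distance, so their
    protein-surface distance is the shell radius by construction.
    ``bulk = (n_solute, n_solvent)`` adds uniform molecules outside the
    protein core.  ``shell_bias`` maps residue names to relative weights
    for the bead choice (e.g. ``{"LYS": 2.0}`` doubles placement near
    lysine).  Construction metadata for the expected-profile oracle is
    stored in ``Trajectory.info``.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    box = np.asarray(box, dtype=float)
    shell_spec = [(float(s), int(c)) for s, c in shell_spec]
    bulk_solute, bulk_solvent = int(bulk[0]), int(bulk[1])
    for s, c in shell_spec:
        if c < 0:
            raise ValueError("shell counts must be >= 0")
        if s <= 0:
            raise ValueError(
                f"shell radius {s} overlaps the protein core")
    if shell_spec and core_radius + max(s for s, _ in shell_spec) \
            >= float(np.min(box)) / 2:
        raise ValueError("shells must fit inside the box")
    rng = np.random.default_rng(seed)
    center = box / 2.0
    beads = center + core_radius * golden_spiral_points(n_residues)
    resnames = [_SHELL_RESNAMES[k % len(_SHELL_RESNAMES)]
                for k in range(n_residues)]
    topo = [AtomRecord(index=k, name="CA", species="protein",
                       residue_index=k + 1, residue_name=resnames[k],
                       mass=110.0, vdw_radius=0.20)
            for k in range(n_residues)]
    n_shell = sum(c for _, c in shell_spec)
    n_solute = n_shell + bulk_solute
    nxt = n_residues
    topo += _single_atom_topology(nxt, n_residues + 1, n_solute, "TB",
                                  "TBA", "tba", 74.12)
    nxt += n_solute
    topo += _single_atom_topology(nxt, n_residues + n_solute + 1,
                                  bulk_solvent, "OW", "SOL", "water",
                                  18.015)
    weights = np.ones(n_residues)
    if shell_bias:
        upper = {k.upper(): v for k, v in shell_bias.items()}
        weights = np.array([upper.get(rn, 1.0) for rn in resnames])
    weights = weights / weights.sum()

    def _uniform_outside_core(count):
        out = np.empty((count, 3))
        filled = 0
        while filled < count:
            cand = rng.uniform(0, 1, (max(count - filled, 16), 3)) * box
            keep = np.linalg.norm(cand - center, axis=1) > core_radius
            cand = cand[keep][:count - filled]
            out[filled:filled + len(cand)] = cand
            filled += len(cand)
        return out

    frames_out = []
    for _ in range(frames):
        pos = np.empty((len(topo), 3))
        pos[:n_residues] = beads
        cursor = n_residues
        for s, c in shell_spec:
            picks = rng.choice(n_residues, size=c, p=weights)
            u = (beads[picks] - center) / core_radius
            pos[cursor:cursor + c] = beads[picks] + s * u
            cursor += c
        pos[cursor:cursor + bulk_solute] = _uniform_outside_core(bulk_solute)
        cursor += bulk_solute
        pos[cursor:] = _uniform_outside_core(bulk_solvent)
        frames_out.append(Frame(positions=pos, box=box.copy()))
    return Trajectory(topology=topo, frames=frames_out, info={
        "kind": "shell_protein", "seed": seed, "center": center,
        "core_radius": core_radius, "bead_positions": beads,
        "shells": shell_spec, "bulk_solute": bulk_solute,
        "bulk_solvent": bulk_solvent,
    })


def expected_shell_profile(traj: Trajectory, r_edges, n_mc: int = 200_000,
                           seed: int = 12345):
    """Construction-oracle expectation for the shell-protein beta profile.

    Returns ``(n_solute(r), n_solvent(r), beta(r))`` expected at the given
    surface-distance bin edges.  Shell contributions are exact step
    functions; the bulk (uniform outside the core) surface-distance CDF is
    estimated by Monte Carlo with an independent stream, accurate to
    ~1/sqrt(n_mc).
    """
    info = traj.info
    if info.get("kind") != "shell_protein":
        raise ValueError("trajectory was not built by gen_shell_protein")
    r_edges = np.asarray(r_edges, dtype=float)
    rng = np.random.default_rng(seed)
    box = traj.frames[0].box
    center, core = info["center"], info["core_radius"]
    beads = info["bead_positions"]
    pts = rng.uniform(0, 1, (int(n_mc * 1.3), 3)) * box
    pts = pts[np.linalg.norm(pts - center, axis=1) > core][:n_mc]
    d = pts[:, None, :] - beads[None, :, :]
    d -= box * np.round(d / box)
    sdist = np.sqrt((d * d).sum(axis=-1)).min(axis=1)
    cdf = np.searchsorted(np.sort(sdist), r_edges, side="right") / len(sdist)
    shell_cum = np.array([sum(c for s, c in info["shells"] if s <= e)
                          for e in r_edges], dtype=float)
    exp_solute = shell_cum + info["bulk_solute"] * cdf
    exp_solvent = info["bulk_solvent"] * cdf
    n_su = sum(c for _, c in info["shells"]) + info["bulk_solute"]
    n_sv = info["bulk_solvent"]
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (exp_solute / n_su) / (exp_solvent / n_sv)
    return exp_solute, exp_solvent, beta


def gen_slab(n: int, box, occupied_fraction: float, frames: int = 1,
             seed: int = 0) -> Trajectory:
    """Uniform liquid slab occupying [0, f*Lz] with vacuum above.

    Mimics interfacial boxes where a cube of liquid sits under an extra
    vacuum region along z (e.g. f = 2/3 on a 12 nm edge reproduces an
    8 nm liquid layer with 4 nm of vacuum).
    """
    if not 0 < occupied_fraction <= 1:
        raise ValueError("occupied fraction must lie in (0, 1]")
    if n < 1:
        raise ValueError("need at least one particle")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    scale = box * np.array([1.0, 1.0, occupied_fraction])
    topo = _single_atom_topology(0, 1, n, "OW", "SOL", "water", 18.015)
    frames_out = [Frame(positions=rng.uniform(0, 1, (n, 3)) * scale,
                        box=box.copy()) for _ in range(frames)]
    return Trajectory(topology=topo, frames=frames_out, info={
        "kind": "slab", "seed": seed,
        "occupied_fraction": occupied_fraction,
    })
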