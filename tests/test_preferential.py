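import numpy as np
import pandas as pd
import pytest

from cosolvkb import (AtomRecord, Frame, Trajectory, beta_profile,
                      contact_occupancy, occupancy_by_class,
                      surface_distance)
from cosolvkb.synthetic import expected_shell_profile, gen_shell_protein

from conftest import make_single_atoms


def pinned_system(solute_offsets, n_frames=1, box=6.0):
    """One-residue protein bead at the center plus pinned solute beads.

    ``solute_offsets`` is a list per frame of x-offsets from the bead.
    """
    topo = [AtomRecord(index=0, name="CA", species="protein",
                       residue_index=1, residue_name="LYS", mass=110.0,
                       vdw_radius=0.2)]
    n_solute = len(solute_offsets[0])
    for k in range(n_solute):
        topo.append(AtomRecord(index=1 + k, name="TB", species="tba",
                               residue_index=2 + k, residue_name="TBA",
                               mass=74.12, vdw_radius=0.15))
    for k in range(20):
        topo.append(AtomRecord(index=1 + n_solute + k, name="OW",
                               species="water",
                               residue_index=2 + n_solute + k,
                               residue_name="SOL", mass=18.015,
                               vdw_radius=0.152))
    rng = np.random.default_rng(5)
    center = np.full(3, box / 2)
    frames = []
    for offs in ([solute_offsets[0]] * n_frames if len(solute_offsets) == 1
                 else solute_offsets):
        pos = [center]
        for off in offs:
            pos.append(center + [off, 0.0, 0.0])
        water = rng.uniform(0, box, (20, 3))
        frames.append(Frame(positions=np.vstack([pos, water]),
                            box=np.full(3, box)))
    return Trajectory(topology=topo, frames=frames)


class TestSurfaceDistance:
    def test_single_atom_reduces_to_pair_distance(self):
        traj = make_single_atoms([[1.0, 1.0, 1.0]], box=[4, 4, 4],
                                 species="protein", resname="ALA")
        d = surface_distance(traj.frames[0], [0], [1.0, 1.0, 2.5])
        assert d == pytest.approx(1.5)

    def test_min_over_protein_atoms(self):
        traj = make_single_atoms([[1.0, 1.0, 1.0], [3.0, 1.0, 1.0]],
                                 box=[8, 8, 8], species="protein",
                                 resname="ALA")
        d = surface_distance(traj.frames[0], [0, 1], [3.5, 1.0, 1.0])
        assert d == pytest.approx(0.5)

    def test_coincident_point(self):
        traj = make_single_atoms([[1.0, 1.0, 1.0]], box=[4, 4, 4],
                                 species="protein", resname="ALA")
        assert surface_distance(traj.frames[0], [0], [1.0, 1.0, 1.0]) == 0.0

    def test_empty_selection_rejected(self):
        traj = make_single_atoms([[1, 1, 1]], box=[4, 4, 4])
        with pytest.raises(ValueError):
            surface_distance(traj.frames[0], [], [0, 0, 0])


class TestBetaProfile:
    def test_construction_oracle_within_three_se(self, shell_fixture):
        prof = beta_profile(shell_fixture, "protein", "tba", "water",
                            dr=0.1)
        exp_su, exp_sv, exp_beta = expected_shell_profile(shell_fixture,
                                                          prof.r)
        # binomial-ish SE on frame-averaged cumulative counts
        nf = shell_fixture.n_frames
        se_su = np.sqrt(np.maximum(exp_su, 1.0) / nf)
        se_sv = np.sqrt(np.maximum(exp_sv, 1.0) / nf)
        assert np.all(np.abs(prof.n_solute_r - exp_su) <= 3 * se_su + 1e-9)
        assert np.all(np.abs(prof.n_solvent_r - exp_sv) <= 3 * se_sv + 1e-9)

    def test_whole_box_beta_is_exactly_one(self, shell_fixture):
        prof = beta_profile(shell_fixture, "protein", "tba", "water",
                            dr=0.1)
        assert prof.beta[-1] == 1.0
        assert prof.n_solute_r[-1] == prof.n_solute_total
        assert prof.n_solvent_r[-1] == prof.n_solvent_total

    def test_swap_maps_beta_to_reciprocal(self, shell_fixture):
        a = beta_profile(shell_fixture, "protein", "tba", "water", dr=0.1)
        b = beta_profile(shell_fixture, "protein", "water", "tba", dr=0.1)
        mask = (np.isfinite(a.beta) & np.isfinite(b.beta)
                & (a.beta > 0) & (b.beta > 0))
        assert mask.any()
        np.testing.assert_allclose(b.beta[mask], 1.0 / a.beta[mask],
                                   rtol=1e-9)

    def test_empty_numerator_gives_zero(self):
        # all solute pinned at 2.0 nm: beta below that distance is 0 or NaN
        traj = pinned_system([[2.0, 2.0]], n_frames=2)
        prof = beta_profile(traj, "protein", "tba", "water", dr=0.1)
        early = prof.beta[(prof.r > 0.5) & (prof.r < 1.9)]
        early = early[np.isfinite(early)]
        assert np.all(early == 0.0)

    def test_cumulative_counts_match_brute_force(self, shell_fixture):
        prof = beta_profile(shell_fixture, "protein", "tba", "water",
                            dr=0.25)
        p_idx = shell_fixture.select(species="protein")
        for species, avg in (("tba", prof.n_solute_r),
                             ("water", prof.n_solvent_r)):
            idx = shell_fixture.select(species=species)
            total = np.zeros(len(prof.r), dtype=np.int64)
            for fr in shell_fixture.frames:
                for i in idx:  # single-atom molecules: COM = position
                    d = fr.positions[p_idx] - fr.positions[i]
                    d -= fr.box * np.round(d / fr.box)
                    r = np.sqrt((d * d).sum(axis=1)).min()
                    total += (r <= prof.r).astype(np.int64)
            np.testing.assert_allclose(avg * shell_fixture.n_frames, total,
                                       atol=1e-8)

    def test_overlapping_selections_rejected(self, shell_fixture):
        with pytest.raises(ValueError, match="disjoint"):
            beta_profile(shell_fixture, "protein", "tba", "tba")


class TestContactOccupancy:
    def test_pinned_inside_cutoff(self):
        traj = pinned_system([[0.25]], n_frames=4)
        table = contact_occupancy(traj, "tba", "protein", cutoff=0.3)
        assert table["occupancy"].iloc[0] == 1.0

    def test_pinned_outside_cutoff(self):
        traj = pinned_system([[0.35]], n_frames=4)
        table = contact_occupancy(traj, "tba", "protein", cutoff=0.3)
        assert table["occupancy"].iloc[0] == 0.0

    def test_alternating_frames_give_half(self):
        frames = [[0.25] if k % 2 == 0 else [0.35] for k in range(6)]
        traj = pinned_system(frames)
        table = contact_occupancy(traj, "tba", "protein", cutoff=0.3)
        assert table["occupancy"].iloc[0] == 0.5

    def test_monotone_in_cutoff(self, shell_fixture):
        occ = [contact_occupancy(shell_fixture, "tba", "protein",
                                 cutoff=c)["occupancy"].to_numpy()
               for c in (0.2, 0.3, 0.45)]
        assert np.all(occ[0] <= occ[1] + 1e-12)
        assert np.all(occ[1] <= occ[2] + 1e-12)

    def test_empty_solute_rejected(self, shell_fixture):
        with pytest.raises(ValueError):
            contact_occupancy(shell_fixture, "excipient", "protein")


class TestOccupancyByClass:
    def test_lysine_bias_ranks_positive_class_first(self):
        traj = gen_shell_protein(n_residues=20, shell_spec=[(0.25, 15)],
                                 bulk=(0, 50), box=(6, 6, 6), frames=40,
                                 seed=77, shell_bias={"LYS": 4.0})
        table = contact_occupancy(traj, "tba", "protein", cutoff=0.3)
        classes = occupancy_by_class(table)
        assert classes.iloc[0]["class"] == "positive"
        ranking = table.sort_values("occupancy", ascending=False)
        assert ranking.iloc[0]["residue_name"] == "LYS"

    def test_uniform_occupancy_gives_equal_means(self):
        table = pd.DataFrame({"residue_index": [1, 2, 3],
                              "residue_name": ["LYS", "ASP", "ALA"],
                              "occupancy": [0.4, 0.4, 0.4]})
        classes = occupancy_by_class(table)
        assert np.allclose(classes["occupancy"], 0.4)

    def test_single_class_mean_equals_global_mean(self):
        table = pd.DataFrame({"residue_index": [1, 2],
                              "residue_name": ["ALA", "VAL"],
                              "occupancy": [0.2, 0.6]})
        classes = occupancy_by_class(table)
        assert len(classes) == 1
        assert classes["occupancy"].iloc[0] == pytest.approx(0.4)

    def test_unclassified_residue_named_in_error(self):
        table = pd.DataFrame({"residue_index": [1],
                              "residue_name": ["XYZ"],
                              "occupancy": [0.5]})
        with pytest.raises(KeyError, match="XYZ"):
            occupancy_by_class(table)
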