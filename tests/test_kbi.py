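import numpy as np
import pytest
from scipy.integrate import quad

from cosolvkb import (compute_rdf, finite_size_corrected_rdf, kbi_plateau,
                      kbi_running)
from cosolvkb.kbi import KbiCurve, RdfCurve
from cosolvkb.synthetic import gen_ideal_mixture, gen_lj_fluid

from conftest import make_single_atoms


def analytic_rdf(g_values, dr, n_i=1000, n_j=1000, volume=1000.0,
                 same=False, normalization="closed"):
    """Wrap an analytic g(r) sampled at bin centers into an RdfCurve."""
    n = len(g_values)
    centers = (np.arange(n) + 0.5) * dr
    return RdfCurve(r=centers, g=np.asarray(g_values, float),
                    counts=np.zeros(n, dtype=np.int64), n_i=n_i, n_j=n_j,
                    volume=volume, same_species=same, dr=dr, n_frames=1,
                    normalization=normalization)


def brute_counts(traj, idx_i, idx_j, edges, same):
    """O(N^2) reference pair histogram (independent of the library path)."""
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for fr in traj.frames:
        for a, i in enumerate(idx_i):
            for j in (idx_j[a + 1:] if same else idx_j):
                d = fr.positions[j] - fr.positions[i]
                d = d - fr.box * np.round(d / fr.box)
                r = np.sqrt((d * d).sum())
                if r <= edges[-1]:
                    k = min(int(r / (edges[1] - edges[0])), len(counts) - 1)
                    counts[k] += 1
    return counts


class TestComputeRdf:
    def test_ideal_mixture_is_uniform(self):
        traj = gen_ideal_mixture(250, 250, (4, 4, 4), frames=100, seed=11)
        rdf = compute_rdf(traj, "tba", "water", dr=0.05)
        expected = (rdf.n_i * rdf.n_j / rdf.volume * rdf.shell_volumes
                    * rdf.n_frames)
        se = 1.0 / np.sqrt(expected)
        dev = np.abs(rdf.g - 1.0)[1:]
        assert np.all(dev <= 3.0 * se[1:])

    def test_pinned_pair_lands_in_one_bin(self):
        traj = make_single_atoms([[1.0, 1.0, 1.0], [1.0, 1.0, 1.5]],
                                 box=[4, 4, 4])
        rdf = compute_rdf(traj, [0], [1], dr=0.1, r_max=2.0)
        assert rdf.counts.sum() == 1
        assert rdf.counts[int(0.5 / 0.1)] == 1

    def test_counts_match_brute_force_reference(self):
        traj = gen_lj_fluid(64, 0.5, 1.2, sweeps=40, seed=5, burn_in=30,
                            record_every=5)
        idx = np.arange(64)
        rdf = compute_rdf(traj, idx, idx, dr=0.02, method="brute")
        ref = brute_counts(traj, idx, idx, rdf.edges, same=True)
        np.testing.assert_array_equal(rdf.counts, ref)

    def test_tree_and_brute_methods_agree_exactly(self):
        traj = gen_ideal_mixture(300, 200, (4, 4, 4), frames=3, seed=9)
        a = compute_rdf(traj, "tba", "water", dr=0.02, method="brute")
        b = compute_rdf(traj, "tba", "water", dr=0.02, method="tree")
        np.testing.assert_array_equal(a.counts, b.counts)
        s1 = compute_rdf(traj, "tba", "tba", dr=0.02, method="brute")
        s2 = compute_rdf(traj, "tba", "tba", dr=0.02, method="tree")
        np.testing.assert_array_equal(s1.counts, s2.counts)

    def test_total_counts_identity(self):
        traj = gen_ideal_mixture(40, 30, (3, 3, 3), frames=5, seed=2)
        half_diag_cover = 1.5  # half the smallest edge
        cross = compute_rdf(traj, "tba", "water", r_max=half_diag_cover,
                            dr=0.05)
        ref = brute_counts(traj, traj.select(species="tba"),
                           traj.select(species="water"), cross.edges,
                           same=False)
        assert cross.counts.sum() == ref.sum()

    def test_r_max_beyond_half_box_rejected(self):
        traj = gen_ideal_mixture(10, 10, (4, 4, 4), frames=1, seed=0)
        with pytest.raises(ValueError, match="half"):
            compute_rdf(traj, "tba", "water", r_max=2.5)

    def test_empty_selection_rejected(self):
        traj = gen_ideal_mixture(10, 10, (4, 4, 4), frames=1, seed=0)
        with pytest.raises(ValueError):
            compute_rdf(traj, "protein", "water")


class TestFiniteSizeCorrection:
    def test_infinite_system_limit_unchanged(self):
        rdf = analytic_rdf(np.ones(200), dr=0.01, n_i=10**9, n_j=10**9,
                           volume=1e12, same=False)
        corr = finite_size_corrected_rdf(rdf)
        np.testing.assert_allclose(corr.g, rdf.g, rtol=1e-6)

    def test_ideal_gas_open_normalization_corrects_to_one(self):
        # closed N,V ideal gas under N/V normalization: g = (N-1)/N exactly
        n = 500
        rdf = analytic_rdf(np.full(150, (n - 1) / n), dr=0.01, n_i=n,
                           n_j=n, volume=27.0, same=True,
                           normalization="open")
        corr = finite_size_corrected_rdf(rdf)
        np.testing.assert_allclose(corr.g, 1.0, rtol=1e-12)

    def test_correction_is_small_for_large_n(self):
        n = 10**4
        rdf = analytic_rdf(np.full(100, (n - 1) / n), dr=0.01, n_i=n,
                           n_j=n, volume=1000.0, same=True,
                           normalization="open")
        corr = finite_size_corrected_rdf(rdf)
        assert abs(corr.g[0] - rdf.g[0]) / rdf.g[0] < 0.01

    def test_undersampled_system_flagged(self):
        rdf = analytic_rdf(np.full(100, 5.0), dr=0.05, n_i=10, n_j=10,
                           volume=8.0, same=True)
        with pytest.raises(ValueError, match="under-sampled"):
            finite_size_corrected_rdf(rdf)


class TestKbiRunning:
    def test_uniform_g_gives_zero_integral(self):
        kbi = kbi_running(analytic_rdf(np.ones(500), dr=0.002))
        assert np.all(kbi.G == 0.0)

    def test_hard_core_step_closed_form(self):
        a, dr = 0.3, 1e-4
        centers = (np.arange(int(0.6 / dr)) + 0.5) * dr
        g = (centers >= a).astype(float)
        kbi = kbi_running(analytic_rdf(g, dr=dr))
        assert kbi.G[-1] == pytest.approx(-(4 / 3) * np.pi * a**3, abs=1e-6)

    def test_gaussian_bump_matches_quadrature(self):
        A, r0, s, dr = 0.5, 0.3, 0.05, 5e-4
        centers = (np.arange(int(1.5 / dr)) + 0.5) * dr
        g = 1 + A * np.exp(-((centers - r0) ** 2) / (2 * s * s))
        kbi = kbi_running(analytic_rdf(g, dr=dr))
        ref, _ = quad(lambda r: A * np.exp(-((r - r0) ** 2) / (2 * s * s))
                      * 4 * np.pi * r * r, 0.0, centers[-1])
        assert kbi.G[-1] == pytest.approx(ref, rel=1e-4)

    def test_linear_in_bump_amplitude(self):
        dr = 1e-3
        centers = (np.arange(1000) + 0.5) * dr
        bump = np.exp(-((centers - 0.4) ** 2) / (2 * 0.05**2))
        g1 = kbi_running(analytic_rdf(1 + 0.3 * bump, dr=dr)).G[-1]
        g2 = kbi_running(analytic_rdf(1 + 0.6 * bump, dr=dr)).G[-1]
        assert g2 == pytest.approx(2 * g1, rel=1e-9)

    def test_non_uniform_bins_rejected(self):
        rdf = analytic_rdf(np.ones(10), dr=0.01)
        rdf.r = rdf.r ** 1.1  # deliberately distort the grid
        with pytest.raises(ValueError, match="uniform"):
            kbi_running(rdf)


class TestKbiPlateau:
    def test_constant_curve(self):
        kbi = KbiCurve(R=np.linspace(0, 2, 101), G=np.full(101, -0.4))
        out = kbi_plateau(kbi, (1.0, 2.0))
        assert out.plateau == pytest.approx(-0.4)
        assert out.plateau_std == pytest.approx(0.0, abs=1e-12)

    def test_linear_drift_gives_midpoint(self):
        R = np.linspace(0, 2, 201)
        kbi = KbiCurve(R=R, G=0.5 * R)
        out = kbi_plateau(kbi, (1.0, 2.0))
        assert out.plateau == pytest.approx(0.5 * 1.5, rel=1e-9)

    def test_empty_window_rejected(self):
        kbi = KbiCurve(R=np.linspace(0, 1, 11), G=np.zeros(11))
        with pytest.raises(ValueError):
            kbi_plateau(kbi, (5.0, 6.0))
        with pytest.raises(ValueError):
            kbi_plateau(kbi, (0.8, 0.2))

    def test_clustered_fluid_has_positive_self_kbi(self):
        # seeds plus close companions: attractive clustering -> G_TT > 0
        rng = np.random.default_rng(31)
        frames = []
        for _ in range(20):
            seeds = rng.uniform(0, 4, (120, 3))
            partners = seeds + rng.normal(0, 0.05, (120, 3))
            frames.append(np.vstack([seeds, partners]))
        traj = make_single_atoms(frames[0], box=[4, 4, 4], species="tba",
                                 resname="TBA", frames=frames)
        rdf = compute_rdf(traj, "tba", "tba", dr=0.02)
        out = kbi_plateau(kbi_running(rdf), (1.2, 2.0))
        assert out.plateau > 0
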