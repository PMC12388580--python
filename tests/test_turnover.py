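"""Ordination, ANOSIM, time-decay regression and slope comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

import persistome as pm


def exhaustive_anosim(d: np.ndarray, labels):
    """Oracle: observed R and exact permutation p by full enumeration."""
    labels = np.asarray(labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu])

    def r_of(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) \
            / (n * (n - 1) / 4.0)

    observed = r_of(labels)
    perms = [r_of(np.array(p)) for p in
             set(itertools.permutations(labels))]
    p = sum(r >= observed - 1e-12 for r in perms) / len(perms)
    return observed, p


class TestPcoa:
    def test_two_points(self):
        dm = DistanceMatrix(np.array([[0, 0.8], [0.8, 0]]), ids=["a", "b"])
        res = pm.pcoa(dm)
        coords = np.sort(res.samples.iloc[:, 0].to_numpy())
        assert coords == pytest.approx([-0.4, 0.4], abs=1e-12)

    def test_identical_samples(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        res = pm.pcoa(dm)
        assert np.allclose(res.eigvals, 0.0, atol=1e-12)
        assert res.samples.shape[1] == 0

    def test_square_has_two_equal_eigenvalues(self):
        # 4 points on a unit square: two equal positive eigenvalues (= 1/2)
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pm.pcoa(DistanceMatrix(d, ids=list("abcd")))
        pos = np.sort(res.eigvals[res.eigvals > 1e-9].to_numpy())
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_euclidean_distances_reconstructed(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pm.pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(7)]))
        coords = res.samples.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d, d2, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pm.pcoa(np.array([[0, 1.0], [0.5, 0]]))


class TestAnosim:
    def _separated(self):
        # all between-group distances exceed all within-group distances
        d = np.array([
            [0.0, 0.1, 0.2, 0.9, 0.8, 0.9],
            [0.1, 0.0, 0.1, 0.8, 0.9, 0.9],
            [0.2, 0.1, 0.0, 0.9, 0.9, 0.8],
            [0.9, 0.8, 0.9, 0.0, 0.2, 0.1],
            [0.8, 0.9, 0.9, 0.2, 0.0, 0.1],
            [0.9, 0.9, 0.8, 0.1, 0.1, 0.0]])
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(6)]), \
            ["g1"] * 3 + ["g2"] * 3

    def test_perfect_separation_r_is_one(self):
        dm, groups = self._separated()
        res = pm.anosim(dm, groups, n_perm=199, seed=1)
        assert res.r_statistic == pytest.approx(1.0)
        # only 20 distinct labelings of 3+3 exist; the exact p floor is 0.1
        assert res.p_value <= 0.15

    def test_r_matches_exhaustive_oracle(self, rng):
        x = rng.uniform(0.1, 1.0, size=(6, 6))
        d = np.triu(x, 1)
        d = d + d.T
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        groups = ["a", "a", "a", "b", "b", "b"]
        oracle_r, _ = exhaustive_anosim(d, groups)
        assert pm.anosim_r(dm, groups) == pytest.approx(oracle_r, abs=1e-12)
        res = pm.anosim(dm, groups, n_perm=999, seed=0)
        assert res.r_statistic == pytest.approx(oracle_r, abs=1e-12)

    def test_null_r_small_on_iid_data(self):
        # |R| stays near 0 for random labels on structureless data
        rs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            pts = r.normal(size=(8, 4))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
            rs.append(pm.anosim_r(dm, ["a"] * 4 + ["b"] * 4))
        # mean near zero within 3 sigma of the replicate spread
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.05

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]),
                            ids=list("abc"))
        with pytest.raises(ValueError):
            pm.anosim(dm, ["a", "b", "b"], n_perm=99, seed=0)


def power_law_dm(times, slope, ids=None):
    """Similarity s = dt^slope -> exact log-log line with the given slope."""
    n = len(times)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dt = abs(times[i] - times[j])
            d[i, j] = d[j, i] = 1.0 - dt ** slope
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestTimeDecay:
    def test_exact_power_law_recovered(self):
        times = np.array([1.0, 2, 4, 8, 16, 32])
        dm = power_law_dm(times, -0.5)
        fit = pm.time_decay_fit(dm, times)
        assert fit.slope_w == pytest.approx(-0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_similarity_zero_slope(self):
        times = np.array([1.0, 2, 4, 8])
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        fit = pm.time_decay_fit(DistanceMatrix(d, ids=list("abcd")), times)
        assert fit.slope_w == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_succession_decays(self):
        # study-shaped design: 21 days x 6 tanks, decaying stage overlap
        table, manifest, _, _ = pm.simulate_dataset(
            n_taxa=600, n_persistent=40, seed=2)
        abs_tab, _ = pm.quantify(table, manifest)
        dm = pm.beta_matrix(abs_tab)
        fit = pm.time_decay_fit(dm, table.metadata["dph"].astype(float))
        assert fit.slope_w < 0
        assert fit.p_value < 0.01

    def test_slope_invariant_to_time_rescaling(self):
        times = np.array([1.0, 2, 4, 8, 16])
        dm = power_law_dm(times, -0.3)
        a = pm.time_decay_fit(dm, times)
        b = pm.time_decay_fit(dm, times * 37.0)
        assert a.slope_w == pytest.approx(b.slope_w, abs=1e-12)
        assert a.intercept != pytest.approx(b.intercept, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        d = np.array([[0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError):
            pm.time_decay_fit(DistanceMatrix(d, ids=["a", "b"]), [1.0, 2.0])


class TestCompareSlopes:
    def test_identical_fits_no_difference(self):
        times = np.array([1.0, 2, 4, 8, 16])
        fit = pm.time_decay_fit(power_law_dm(times, -0.5), times)
        res = pm.compare_slopes(fit, fit, n_perm=99, seed=0)
        assert res.slope_difference == pytest.approx(0.0, abs=1e-12)
        assert res.f_statistic == pytest.approx(0.0)

    def test_noiseless_slopes_recovered_exactly(self):
        times = np.array([1.0, 2, 4, 8, 16, 32])
        fa = pm.time_decay_fit(power_law_dm(times, -0.5), times)
        fb = pm.time_decay_fit(power_law_dm(times, -1.0), times)
        res = pm.compare_slopes(fa, fb, n_perm=199, seed=1)
        assert res.slope_difference == pytest.approx(-0.5, abs=1e-10)
        assert res.p_value < 1e-6
        assert res.permutation_p < 0.05

    def test_degenerate_x_rejected(self):
        fit = pm.TimeDecayFit(0.0, 0.0, 1.0, 0.5, 3,
                              pairs=[(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])
        with pytest.raises(ValueError):
            pm.compare_slopes(fit, fit, n_perm=99, seed=0)
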