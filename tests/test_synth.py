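"""Synthetic-data generator: determinism, conservation laws, planted truth."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

import persistome as pm
from persistome.synth import STAGE_BY_DPH


class TestSourceProfile:
    def test_normalized_and_sized(self):
        sp = pm.make_source_profile(10, 1.0, 42)
        assert len(sp.asv_ids) == 10
        assert sp.rel_abundance.sum() == pytest.approx(1.0, abs=1e-12)
        assert (sp.rel_abundance >= 0).all()

    def test_zero_sigma_is_uniform(self):
        sp = pm.make_source_profile(2, 0.0, 1)
        assert np.allclose(sp.rel_abundance, [0.5, 0.5])

    def test_seed_determinism(self):
        a = pm.make_source_profile(300, 2.0, 7)
        b = pm.make_source_profile(300, 2.0, 7)
        assert np.array_equal(a.rel_abundance, b.rel_abundance)

    def test_heavy_tail_is_sorted(self):
        sp = pm.make_source_profile(50, 2.0, 3)
        assert (np.diff(sp.rel_abundance) <= 0).all()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            pm.make_source_profile(1, 1.0, 0)


class TestNeutralTable:
    def test_row_sums_conserved(self):
        src = pm.make_source_profile(40, 1.5, 0)
        tab = pm.sample_neutral_table(src, 0.4, 3000, 30, seed=5)
        assert (tab.counts.sum(axis=1) == 3000).all()

    def test_determinism(self):
        src = pm.make_source_profile(20, 1.0, 2)
        a = pm.sample_neutral_table(src, 0.5, 1000, 10, seed=9)
        b = pm.sample_neutral_table(src, 0.5, 1000, 10, seed=9)
        assert a.counts.equals(b.counts)

    def test_high_m_mean_frequency_matches_source(self):
        # m -> 1 pins local communities at the source: sample mean within 3 SE
        src = pm.make_source_profile(50, 1.0, 4)
        tab = pm.sample_neutral_table(src, 1.0, 10**6, 100, seed=6)
        freqs = tab.counts.to_numpy() / 10**6
        mean = freqs.mean(axis=0)
        se = freqs.std(axis=0, ddof=1) / np.sqrt(100) + 1e-12
        assert (np.abs(mean - src.rel_abundance) < 3 * se + 1e-6).all()

    def test_dominant_taxon_always_detected(self):
        # p_max * Nt * m >> 1 -> detection probability ~ 1
        src = pm.make_source_profile(300, 2.0, 7)
        tab = pm.sample_neutral_table(src, 0.6, 5000, 126, seed=11)
        top = src.asv_ids[int(np.argmax(src.rel_abundance))]
        assert (tab.counts[top] > 0).all()

    def test_invalid_m_rejected(self):
        src = pm.make_source_profile(5, 1.0, 0)
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                pm.sample_neutral_table(src, bad, 100, 5, seed=0)

    def test_occupancy_matches_model_prediction(self):
        # generator/fitter consistency: over 500 replicate samples the
        # empirical occupancy of every taxon sits inside a family-wise
        # (Bonferroni) Wilson band around the model-predicted occupancy
        src = pm.make_source_profile(40, 1.5, 8)
        m, Nt, n = 0.3, 2000, 500
        tab = pm.sample_neutral_table(src, m, Nt, n, seed=21)
        obs_counts = (tab.counts.to_numpy() > 0).sum(axis=0)
        pred = pm.sloan_occupancy_counts(src.rel_abundance, m, Nt)
        lo, hi = proportion_confint(obs_counts, n, alpha=0.05 / len(pred),
                                    method="wilson")
        assert ((pred >= lo) & (pred <= hi)).all()


@pytest.fixture(scope="module")
def planted():
    pers = pm.make_source_profile(10, 0.5, 1)
    pool = pm.SourceProfile([f"T{i}" for i in range(40)],
                            pm.make_source_profile(40, 1.5, 2).rel_abundance)
    stages = [(f"Z{i}", d) for i, d in enumerate([1, 3, 7, 12, 21], 1)]
    tab = pm.plant_succession_table(stages, 4, pers, pool, 0.95, 5000, 3)
    return pers, pool, tab


class TestSuccessionTable:
    def test_shape_and_metadata(self, planted):
        _, _, tab = planted
        assert tab.counts.shape[0] == 20
        assert set(tab.metadata.columns) >= {"dph", "stage", "tank", "mass_g"}
        assert (tab.counts.sum(axis=1) == 5000).all()

    def test_persistent_occupancy_is_one(self, planted):
        pers, _, tab = planted
        assert (tab.counts[pers.asv_ids] > 0).all().all()

    def test_persistent_share_near_fraction(self, planted):
        pers, _, tab = planted
        share = tab.counts[pers.asv_ids].sum(axis=1) / tab.counts.sum(axis=1)
        assert share.between(0.90, 0.99).all()

    def test_stage_structure_in_similarity(self):
        # stages sharing no transients are less similar than replicates
        pers = pm.make_source_profile(5, 0.5, 1)
        pool = pm.SourceProfile([f"T{i}" for i in range(100)],
                                pm.make_source_profile(100, 1.0, 2).rel_abundance)
        stages = [("first", 1), ("last", 21)]
        tab = pm.plant_succession_table(stages, 6, pers, pool, 0.6, 5000, 7,
                                        transient_width=40)
        dm = pm.beta_matrix(tab)
        d = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        first = [s for s in dm.ids if s.startswith("D01")]
        last = [s for s in dm.ids if s.startswith("D21")]
        within = np.concatenate([
            d.loc[first, first].to_numpy()[np.triu_indices(6, 1)],
            d.loc[last, last].to_numpy()[np.triu_indices(6, 1)]])
        between = d.loc[first, last].to_numpy().ravel()
        assert between.mean() > within.mean()

    def test_empty_stage_list_rejected(self):
        pers = pm.make_source_profile(3, 0.5, 1)
        pool = pm.SourceProfile(["T1", "T2"], np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            pm.plant_succession_table([], 3, pers, pool, 0.9, 100, 0)

    def test_overlapping_ids_rejected(self):
        pers = pm.make_source_profile(3, 0.5, 1)
        pool = pm.SourceProfile(["ASV1", "T2"], np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            pm.plant_succession_table([("a", 1)], 2, pers, pool, 0.9, 100, 0)


class TestSpikeIns:
    def _table(self):
        counts = pd.DataFrame([[100, 50], [80, 60]], index=["s1", "s2"],
                              columns=["a", "b"])
        return pm.CountTable(counts)

    def _manifest(self):
        copies = pd.DataFrame({"SP1": [1e4, 1e4], "SP2": [1e5, 1e5],
                               "SP3": [1e6, 1e6]}, index=["s1", "s2"])
        return pm.SpikeInManifest(copies)

    def test_noiseless_linear_map(self):
        out = pm.add_spikein_reads(self._table(), self._manifest(), 0.01)
        assert list(out.spike_counts.loc["s1"]) == [100, 1000, 10000]
        assert out.spike_ids == ("SP1", "SP2", "SP3")

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            pm.add_spikein_reads(self._table(), self._manifest(), 0.0)

    def test_poisson_noise_within_4_sigma(self):
        copies = pd.DataFrame({"SP1": [1e6], "SP2": [2e6], "SP3": [4e6]},
                              index=["s1"])
        tab = pm.CountTable(pd.DataFrame([[10, 10]], index=["s1"],
                                         columns=["a", "b"]))
        out = pm.add_spikein_reads(tab, pm.SpikeInManifest(copies), 0.01,
                                   seed=4, poisson_noise=True)
        reads = out.spike_counts.loc["s1", "SP1"]
        assert abs(reads - 1e4) < 4 * np.sqrt(1e4)

    def test_id_collision_rejected(self):
        copies = pd.DataFrame({"a": [1e4], "SP2": [1e5], "SP3": [1e6]},
                              index=["s1"])
        tab = pm.CountTable(pd.DataFrame([[10, 10]], index=["s1"],
                                         columns=["a", "b"]))
        with pytest.raises(ValueError):
            pm.add_spikein_reads(tab, pm.SpikeInManifest(copies), 0.01)


class TestRandomTree:
    def test_two_tips_cherry(self):
        tree = pm.random_rooted_tree(["A", "B"], 0)
        tips = list(tree.tips())
        assert sorted(t.name for t in tips) == ["A", "B"]
        assert all(t.length > 0 for t in tips)

    def test_binary_internal_node_count(self):
        tree = pm.random_rooted_tree([f"t{i}" for i in range(17)], 1)
        internal = [n for n in tree.traverse() if not n.is_tip()]
        assert len(internal) == 16
        assert len(list(tree.tips())) == 17

    def test_all_branch_lengths_positive(self):
        tree = pm.random_rooted_tree([f"t{i}" for i in range(10)], 2)
        for node in tree.traverse(include_self=False):
            assert node.length is not None and node.length > 0

    def test_newick_determinism(self):
        a = str(pm.random_rooted_tree(["A", "B", "C", "D"], 42))
        b = str(pm.random_rooted_tree(["A", "B", "C", "D"], 42))
        assert a == b

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            pm.random_rooted_tree(["A", "A", "B"], 0)


def test_study_design_shape():
    design = pm.study_design()
    assert len(design) == 21                       # sampling days
    assert len({s for s, _ in design}) == 12       # developmental stages
    assert [d for _, d in design] == sorted(STAGE_BY_DPH)


def test_simulate_dataset_truth_consistency(small_study):
    table, manifest, tree, truth = small_study
    assert len(table.sample_ids) == 24
    assert set(truth.persistent_ids) <= set(table.asv_ids)
    assert len(truth.persistent_ids) == 20
    assert sorted(t.name for t in tree.tips()) == sorted(table.asv_ids)
    assert set(truth.read_per_copy_k) == set(table.sample_ids)
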