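import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import bogwater as bw
from bogwater.diversity import DistanceMatrix


def random_instance(seed, n_samples=5, n_otus=10):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=(n_samples, n_otus))
    counts[counts.sum(axis=1) == 0, 0] = 1  # no empty samples
    ids = [f"o{j}" for j in range(n_otus)]
    table = bw.OtuTable(counts, [f"s{i}" for i in range(n_samples)], ids)
    tree = bw.generate_tree(ids, seed=seed + 1)
    return table, tree


class TestRichness:
    def test_counts_nonzero_otus(self):
        t = bw.OtuTable([[5, 0, 1], [0, 0, 0]], ["a", "b"],
                        ["x", "y", "z"])
        assert list(bw.richness(t)) == [2, 0]

    def test_bounded_by_rarefaction_depth(self, rarefied):
        table, _ = rarefied
        assert np.all(bw.richness(table) <= 2500)


class TestRarefactionCurves:
    def test_full_depth_returns_observed_richness(self):
        t = bw.OtuTable([[10, 5, 0]], ["s"], ["a", "b", "c"])
        curve = bw.rarefaction_curves(t, [15], reps=3, seed=0)
        assert curve.loc["s", 15] == 2

    def test_depth_one_gives_richness_one(self):
        t = bw.OtuTable([[10, 5, 3]], ["s"], ["a", "b", "c"])
        curve = bw.rarefaction_curves(t, [1], reps=20, seed=0)
        assert curve.loc["s", 1] == 1.0

    def test_depth_beyond_total_is_undefined(self):
        t = bw.OtuTable([[3, 3]], ["s"], ["a", "b"])
        curve = bw.rarefaction_curves(t, [7], reps=2, seed=0)
        assert np.isnan(curve.loc["s", 7])

    def test_hypergeometric_expectation(self):
        # sample (100, 100) at depth 50: E[richness]
        #   = 2 - 2 * C(100,50)/C(200,50)
        t = bw.OtuTable([[100, 100]], ["s"], ["a", "b"])
        reps = 4000
        curve = bw.rarefaction_curves(t, [50], reps=reps, seed=1)
        p_miss = math.comb(100, 50) / math.comb(200, 50)
        expected = 2 - 2 * p_miss
        se = math.sqrt(2 * p_miss * (1 - p_miss) / reps)  # upper bound
        assert abs(curve.loc["s", 50] - expected) < 3 * max(se, 1e-4)


class TestBetaDiversity:
    def test_unifrac_hand_example(self, cherry_tree):
        t = bw.OtuTable([[1, 0, 0], [0, 1, 0]], ["s1", "s2"],
                        ["A", "B", "C"])
        got = {m: bw.beta_diversity(t, m, tree=cherry_tree).data[0, 1]
               for m in ("unweighted_unifrac", "weighted_unifrac_raw",
                         "weighted_unifrac_norm")}
        assert got["unweighted_unifrac"] == pytest.approx(2 / 3)
        assert got["weighted_unifrac_raw"] == pytest.approx(2.0)
        assert got["weighted_unifrac_norm"] == pytest.approx(0.5)

    def test_identical_samples_distance_zero(self, cherry_tree):
        t = bw.OtuTable([[2, 3, 1], [2, 3, 1]], ["s1", "s2"],
                        ["A", "B", "C"])
        for metric in bw.BETA_METRICS:
            dm = bw.beta_diversity(t, metric, tree=cherry_tree)
            assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_communities_bray_curtis_one(self):
        t = bw.OtuTable([[5, 0], [0, 7]], ["s1", "s2"], ["a", "b"])
        assert bw.beta_diversity(t, "bray_curtis").data[0, 1] == 1.0

    def test_missing_tree_otu_is_an_error(self, cherry_tree):
        t = bw.OtuTable([[1, 1, 1, 1]], ["s"], ["A", "B", "C", "D"])
        with pytest.raises(ValueError, match="D"):
            bw.beta_diversity(t, "weighted_unifrac_norm", tree=cherry_tree)

    @pytest.mark.parametrize("metric", bw.BETA_METRICS)
    def test_symmetry_identity_and_bounds(self, metric):
        # 200 random table/tree instances across the five metrics
        for seed in range(40):
            table, tree = random_instance(seed * 7 + 1)
            dm = bw.beta_diversity(table, metric, tree=tree)
            d = dm.data
            assert np.allclose(d, d.T)
            assert np.all(np.diag(d) == 0)
            assert d.min() >= 0
            if metric != "weighted_unifrac_raw":
                assert d.max() <= 1 + 1e-12

    def test_unifrac_matches_scikit_bio(self):
        from skbio.diversity import beta_diversity as skbd
        for seed in (3, 17, 91):
            table, tree = random_instance(seed, n_samples=4, n_otus=8)
            mine = bw.beta_diversity(table, "weighted_unifrac_norm",
                                     tree=tree)
            ref = skbd("weighted_unifrac", table.counts,
                       ids=table.sample_ids, taxa=table.otu_ids,
                       tree=tree, normalized=True)
            assert np.allclose(mine.data, ref.data, atol=1e-12)
            mine_u = bw.beta_diversity(table, "unweighted_unifrac",
                                       tree=tree)
            ref_u = skbd("unweighted_unifrac", table.counts,
                         ids=table.sample_ids, taxa=table.otu_ids,
                         tree=tree)
            assert np.allclose(mine_u.data, ref_u.data, atol=1e-12)

    def test_self_distance_zero_over_random_trees(self):
        for seed in range(20):
            table, tree = random_instance(seed, n_samples=2, n_otus=12)
            dup = bw.OtuTable(np.vstack([table.counts[0]] * 2),
                              ["a", "b"], table.otu_ids)
            for metric in ("unweighted_unifrac", "weighted_unifrac_raw",
                           "weighted_unifrac_norm"):
                dm = bw.beta_diversity(dup, metric, tree=tree)
                assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(pts))
        res = bw.pcoa(DistanceMatrix(("a", "b", "c"), d))
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_input_recovered_exactly(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        res = bw.pcoa(DistanceMatrix(tuple("abcdefg"), d))
        d_back = squareform(pdist(res.coordinates))
        assert np.allclose(d_back, d, atol=1e-10)

    def test_two_samples(self):
        res = bw.pcoa(DistanceMatrix(("a", "b"),
                                     np.array([[0.0, 3.0], [3.0, 0.0]])))
        assert np.allclose(np.abs(res.coordinates[:, 0]), 1.5)

    def test_proportions_non_increasing_and_sum_le_one(self, rarefied, sim):
        table, _ = rarefied
        dm = bw.beta_diversity(table.select_samples(table.sample_ids[:40]),
                               "bray_curtis")
        res = bw.pcoa(dm)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            bw.pcoa(DistanceMatrix(("a",), np.zeros((1, 1))))


@pytest.fixture()
def worked_dm():
    d = np.array([[0, 1, 2, 2],
                  [1, 0, 2, 2],
                  [2, 2, 0, 1],
                  [2, 2, 1, 0]], dtype=float)
    return DistanceMatrix(("a", "b", "c", "d"), d)


class TestPermanova:
    def test_worked_example_exhaustive(self, worked_dm):
        res = bw.permanova(worked_dm, ["g1", "g1", "g2", "g2"],
                           n_perm="exact")
        assert res.F == pytest.approx(7.0)
        assert res.r2 == pytest.approx(3.5 / 4.5)
        assert res.p == pytest.approx(8 / 24)

    def test_worked_example_seeded(self, worked_dm):
        res = bw.permanova(worked_dm, ["g1", "g1", "g2", "g2"],
                           n_perm=999, seed=0)
        assert abs(res.p - 1 / 3) <= 0.05

    def test_seeded_determinism(self, worked_dm):
        a = bw.permanova(worked_dm, ["g1", "g1", "g2", "g2"],
                         n_perm=99, seed=7)
        b = bw.permanova(worked_dm, ["g1", "g1", "g2", "g2"],
                         n_perm=99, seed=7)
        assert a == b

    def test_matches_scikit_bio_statistic(self):
        import skbio
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        X[6:] += 1.0
        d = squareform(pdist(X))
        labels = tuple(f"s{i}" for i in range(12))
        groups = ["a"] * 6 + ["b"] * 6
        mine = bw.permanova(DistanceMatrix(labels, d), groups,
                            n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, labels), groups, permutations=99)
        assert mine.F == pytest.approx(ref["test statistic"])

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            X = rng.normal(size=(16, 4))
            d = squareform(pdist(X))
            dm = DistanceMatrix(tuple(map(str, range(16))), d)
            res = bw.permanova(dm, ["a"] * 8 + ["b"] * 8,
                               n_perm=199, seed=rep)
            rejections += res.p <= 0.05
        # binomial 99.9% band around 0.05 for 120 replicates
        assert 0 <= rejections / n_rep <= 0.12

    def test_zero_within_group_variance_warns_infinite_f(self):
        d = np.array([[0, 0, 1, 1],
                      [0, 0, 1, 1],
                      [1, 1, 0, 0],
                      [1, 1, 0, 0]], dtype=float)
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        with pytest.warns(UserWarning):
            res = bw.permanova(dm, ["g1", "g1", "g2", "g2"],
                               n_perm=99, seed=0)
        assert math.isinf(res.F)


class TestPairwiseGroupTest:
    def test_exact_rank_sum_small_example(self):
        df = bw.pairwise_group_test([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert df.loc[0, "p"] == pytest.approx(1 / 3)
        assert df.loc[0, "adjusted_p"] == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        df = bw.pairwise_group_test([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert df.loc[0, "adjusted_p"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_pair_count(self):
        values = [1, 2, 3, 4, 5, 6]
        groups = ["a", "a", "b", "b", "c", "c"]
        df = bw.pairwise_group_test(values, groups)
        assert len(df) == 3
        raw = bw.pairwise_group_test(values[:4], groups[:4]).loc[0, "p"]
        ab = df[(df.group1 == "a") & (df.group2 == "b")].iloc[0]
        assert ab.adjusted_p == pytest.approx(min(1.0, raw * 3))

    def test_paired_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            bw.pairwise_group_test([1, 2, 3, 4, 5],
                                   ["a", "a", "a", "b", "b"], paired=True)

    def test_paired_signed_rank_detects_shift(self):
        x = np.arange(10.0)
        df = bw.pairwise_group_test(
            np.concatenate([x, x + 3]),
            ["pre"] * 10 + ["post"] * 10, paired=True)
        assert df.loc[0, "p"] < 0.01


class TestDispersionAndTimeDecay:
    def test_group_of_three_yields_three_distances(self, worked_dm):
        disp = bw.within_group_dispersion(worked_dm,
                                          ["g", "g", "g", "h"])
        assert len(disp["g"]) == 3
        assert len(disp["h"]) == 0

    def test_identical_samples_zero_dispersion(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        disp = bw.within_group_dispersion(dm, ["g"] * 3)
        assert np.all(disp["g"] == 0)

    def test_planted_dispersion_difference_detected(self):
        rng = np.random.default_rng(3)
        tight = rng.normal(scale=0.1, size=(10, 3))
        loose = rng.normal(scale=2.0, size=(10, 3))
        d = squareform(pdist(np.vstack([tight, loose])))
        dm = DistanceMatrix(tuple(map(str, range(20))), d)
        disp = bw.within_group_dispersion(dm, ["t"] * 10 + ["l"] * 10)
        df = bw.pairwise_group_test(
            np.concatenate([disp["t"], disp["l"]]),
            ["t"] * len(disp["t"]) + ["l"] * len(disp["l"]))
        assert df.loc[0, "p"] < 0.001

    def test_time_decay_pairs(self):
        ids = ["TBE01JUN07", "TBE08JUN07", "TBE15JUN07", "MAE01JUN07"]
        meta = [bw.SampleMetadata.from_sample_id(s) for s in ids]
        d = np.zeros((4, 4))
        dm = DistanceMatrix(tuple(ids), d)
        df = bw.time_decay(dm, meta)
        tb = df[df.site.str.contains("TB")]
        assert sorted(tb.dt_days) == [7, 7, 14]
        assert len(df) == 3  # the single MA sample contributes no pairs

    def test_missing_metadata_is_an_error(self):
        dm = DistanceMatrix(("TBE01JUN07", "TBE08JUN07"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="TBE08JUN07"):
            bw.time_decay(dm, [bw.SampleMetadata.from_sample_id(
                "TBE01JUN07")])


class TestZscoreByYear:
    def test_single_year(self):
        out = bw.zscore_by_year([1.0, 2.0, 3.0], [2007, 2007, 2007])
        assert np.allclose(out, [-1, 0, 1])

    def test_constant_year_maps_to_zero(self):
        out = bw.zscore_by_year([5.0, 5.0, 5.0], [2007] * 3)
        assert np.allclose(out, 0.0)

    def test_years_normalized_independently(self):
        vals = [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]
        years = [2007] * 3 + [2008] * 3
        out = bw.zscore_by_year(vals, years)
        for y in (2007, 2008):
            sub = out[np.array(years) == y]
            assert sub.mean() == pytest.approx(0.0, abs=1e-12)
            assert sub.std(ddof=1) == pytest.approx(1.0)

    def test_singleton_year_is_an_error(self):
        with pytest.raises(ValueError, match="2008"):
            bw.zscore_by_year([1.0, 2.0, 3.0], [2007, 2007, 2008])
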