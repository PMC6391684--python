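"""CNV genotype calling, abundances, independence, and summary arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vgenepop.cnv import (CnvCallSet, CnvPolymorphism, cluster_copy_numbers,
                          haplotype_count_estimate, mean_off_diagonal_r2,
                          min_max_haploid, pairwise_r_squared,
                          regional_distribution_test,
                          segment_set_difference_probability,
                          variant_relative_abundance)

INDEL = CnvPolymorphism("indel", ["G1"], [("del", (0,)), ("ins", (1,))])
PAIR = CnvPolymorphism("pair", ["G1", "G2"], [("ins", (1, 1)), ("del", (0, 0))])


class TestMinMaxHaploid:
    @pytest.mark.parametrize("diploid,expected", [(13, 7), (7, 4), (2, 1), (0, 0)])
    def test_balanced_decomposition(self, diploid, expected):
        assert min_max_haploid(diploid) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            min_max_haploid(-1)

    @given(st.integers(0, 10_000))
    def test_parts_sum_back(self, d):
        assert min_max_haploid(d) + d // 2 == d


class TestHaplotypeCount:
    @pytest.mark.parametrize("counts,expected", [
        ([2, 2, 2, 7, 4], 224), ([2, 2], 4), ([1], 1)])
    def test_product(self, counts, expected):
        assert haplotype_count_estimate(counts) == expected

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            haplotype_count_estimate([])
        with pytest.raises(ValueError):
            haplotype_count_estimate([2, 0])


class TestClustering:
    def test_noiseless_integer_estimates_recovered_exactly(self):
        est = pd.DataFrame({"G1": [0.0, 1.0, 2.0, 1.0, 0.0, 2.0]},
                           index=[f"i{k}" for k in range(6)])
        cs = cluster_copy_numbers(est, INDEL)
        assert list(cs.calls["cn_G1"]) == [0, 1, 2, 1, 0, 2]

    def test_noisy_two_group_recovery(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, 120)  # diploid copies of the inserted pair
        X = np.column_stack([truth, truth]).astype(float)
        X *= 1 + rng.normal(0, 0.08, X.shape)
        est = pd.DataFrame(X, columns=["G1", "G2"],
                           index=[f"i{k}" for k in range(120)])
        cs = cluster_copy_numbers(est, PAIR)
        assert (cs.calls.set_index("individual_id")["cn_G1"]
                == pd.Series(truth, index=est.index)).mean() >= 0.95

    def test_subset_clustering_consistent_with_held_out_group(self):
        """Clustering on one group of a two-group polymorphism still separates
        the held-out group's estimates cleanly."""
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, 150)
        X = np.column_stack([truth, truth]).astype(float)
        X *= 1 + rng.normal(0, 0.06, X.shape)
        est = pd.DataFrame(X, columns=["G1", "G2"],
                           index=[f"i{k}" for k in range(150)])
        sub = CnvPolymorphism("sub", ["G1"],
                              [("ins2", (2,)), ("ins1", (1,)), ("del", (0,))])
        cs = cluster_copy_numbers(est, sub)
        called = cs.calls.set_index("individual_id")["cn_G1"]
        for cls in called.unique():
            held_out = est.loc[called.index[called == cls], "G2"]
            assert (np.round(held_out) == cls).mean() > 0.95

    def test_identical_estimates_collapse_with_warning(self):
        est = pd.DataFrame({"G1": [1.0] * 5}, index=list("abcde"))
        with pytest.warns(UserWarning, match="identical"):
            cs = cluster_copy_numbers(est, INDEL)
        assert cs.calls["cluster"].nunique() == 1

    def test_rounding_mode_calls_totals(self):
        poly = CnvPolymorphism("hi", ["G1"],
                               [(str(c), (c,)) for c in range(1, 8)],
                               call_method="round")
        est = pd.DataFrame({"G1": [13.2, 6.8, 2.1]}, index=list("abc"))
        cs = cluster_copy_numbers(est, poly)
        assert list(cs.calls["cn_G1"]) == [13, 7, 2]
        assert list(cs.calls["hap2"].astype(int)) == [7, 4, 1]

    def test_missing_group_rejected(self):
        est = pd.DataFrame({"G9": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="lacks groups"):
            cluster_copy_numbers(est, INDEL)


def _callset(class_rows):
    """CnvCallSet from (individual, hap1, hap2) triples for the PAIR poly."""
    rows = []
    for ind, h1, h2 in class_rows:
        pair = tuple(sorted((h1, h2)))
        vec = tuple(a + b for a, b in zip(PAIR.variant_vector(pair[0]),
                                          PAIR.variant_vector(pair[1])))
        rows.append({"individual_id": ind, "cluster": 0,
                     "class_label": "/".join(pair), "hap1": pair[0],
                     "hap2": pair[1], "cn_G1": vec[0], "cn_G2": vec[1]})
    return CnvCallSet(polymorphism=PAIR, calls=pd.DataFrame(rows))


class TestRelativeAbundance:
    def test_all_homozygous(self):
        cs = _callset([(f"i{k}", "ins", "ins") for k in range(10)])
        assert dict(variant_relative_abundance(cs)) == {"ins": 1.0}

    def test_direct_haploid_counting(self):
        rows = [(f"a{k}", "ins", "ins") for k in range(50)]
        rows += [(f"b{k}", "ins", "del") for k in range(50)]
        ra = variant_relative_abundance(_callset(rows))
        assert ra["ins"] == pytest.approx(0.75)
        assert ra["del"] == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            variant_relative_abundance(_callset([]))

    def test_planted_frequency_recovered_through_clustering(self):
        rng = np.random.default_rng(2)
        p, n = 0.72, 1000
        hap = rng.random((n, 2)) < p  # each haplotype carries the insertion w.p. p
        truth = hap.sum(axis=1)
        est = pd.DataFrame(
            {"G1": truth * (1 + rng.normal(0, 0.05, n)),
             "G2": truth * (1 + rng.normal(0, 0.05, n))},
            index=[f"i{k}" for k in range(n)])
        ra = variant_relative_abundance(cluster_copy_numbers(est, PAIR))
        sd = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(ra["ins"] - p) < 3 * sd


class TestRSquared:
    def test_duplicated_and_anticorrelated_columns(self):
        x = np.arange(10.0)
        est = pd.DataFrame({"a": x, "b": x.copy(), "c": 10 - x})
        r2 = pairwise_r_squared(est)
        assert r2.loc["a", "b"] == pytest.approx(1.0)
        assert r2.loc["a", "c"] == pytest.approx(1.0)  # sign-invariant

    def test_constant_column_undefined(self):
        est = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        r2 = pairwise_r_squared(est)
        assert np.isnan(r2.loc["a", "b"]) and np.isnan(r2.loc["b", "b"])
        assert r2.loc["a", "a"] == 1.0

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            pairwise_r_squared(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        est = pd.DataFrame(rng.integers(0, 3, (1000, 4)).astype(float),
                           columns=list("abcd"))
        assert mean_off_diagonal_r2(pairwise_r_squared(est)) < 0.02


class TestRegionalTest:
    def test_proportional_region_not_flagged(self):
        rows = [(f"i{k}", "ins", "ins") for k in range(40)]
        rows += [(f"i{k+40}", "del", "del") for k in range(40)]
        cs = _callset(rows)
        regions = pd.Series(["north", "south"] * 40,
                            index=[f"i{k}" for k in range(80)])
        res = regional_distribution_test(cs, regions).set_index("region")
        assert res.loc["north", "statistic"] == pytest.approx(0.0)
        assert not res["flagged"].any()

    def test_hand_computed_statistic(self):
        # region counts (90, 10) against global proportions (0.5, 0.5):
        # sum (O-E)^2/E = 2 * 40^2 / 50 = 64
        rows = [(f"a{k}", "ins", "ins") for k in range(90)]
        rows += [(f"a{k}", "del", "del") for k in range(90, 100)]
        rows += [(f"b{k}", "ins", "ins") for k in range(10)]
        rows += [(f"b{k}", "del", "del") for k in range(10, 100)]
        cs = _callset(rows)
        regions = pd.Series(
            {**{f"a{k}": "A" for k in range(100)},
             **{f"b{k}": "B" for k in range(100)}})
        res = regional_distribution_test(cs, regions).set_index("region")
        assert res.loc["A", "statistic"] == pytest.approx(64.0)
        assert res.loc["A", "flagged"]

    def test_zero_alpha_flags_nothing(self):
        rows = [(f"a{k}", "ins", "ins") for k in range(90)]
        rows += [(f"b{k}", "del", "del") for k in range(90)]
        cs = _callset(rows)
        regions = pd.Series({**{f"a{k}": "A" for k in range(90)},
                             **{f"b{k}": "B" for k in range(90)}})
        res = regional_distribution_test(cs, regions, alpha=0.0)
        assert not res["flagged"].any()


class TestSetDifference:
    def test_shared_set_and_all_different(self):
        assert segment_set_difference_probability(
            {"a": {"g1"}, "b": {"g1"}, "c": {"g1"}}) == 0.0
        assert segment_set_difference_probability(
            {"a": {"g1"}, "b": {"g2"}}) == 1.0

    def test_enumerated_example(self):
        # sets {S, S, T, U}: 5 of the 6 unordered pairs differ
        pres = {"a": {"s"}, "b": {"s"}, "c": {"t"}, "d": {"u"}}
        assert segment_set_difference_probability(pres) == pytest.approx(5 / 6)

    def test_stratified(self):
        pres = {"a": {"s"}, "b": {"s"}, "c": {"t"}, "d": {"t"}}
        strata = pd.Series({"a": "R1", "b": "R1", "c": "R2", "d": "R2"})
        overall, per = segment_set_difference_probability(pres, strata)
        assert overall == pytest.approx(4 / 6)
        assert (per.set_index("stratum")["p_different"] == 0.0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["S", "T", "U", "V"]), min_size=2,
                    max_size=12))
    def test_matches_pair_enumeration(self, labels):
        pres = {f"i{k}": {lab} for k, lab in enumerate(labels)}
        expected = np.mean([labels[i] != labels[j]
                            for i, j in itertools.combinations(range(len(labels)), 2)])
        assert segment_set_difference_probability(pres) == pytest.approx(expected)
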