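"""Normalization, log ratios and island correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symisle import expression as ex
from symisle.errors import NormalizationError, SymisleError
from symisle.microsynteny import MicrosyntenyCall
from tests.conftest import toy_matrix


def brute_force_size_factors(counts):
    """Independent median-of-ratios implementation (plain loops)."""
    genes = [g for g in counts.index if (counts.loc[g] > 0).all()]
    log_gm = {g: np.mean([np.log(v) for v in counts.loc[g]]) for g in genes}
    factors = {}
    for s in counts.columns:
        ratios = [counts.loc[g, s] / np.exp(log_gm[g]) for g in genes]
        factors[s] = np.median(ratios)
    return pd.Series(factors)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = toy_matrix([[5, 5], [10, 10], [3, 3]])
        assert np.allclose(ex.size_factors_median_ratio(counts), 1.0)

    def test_scaling_equivariance(self):
        counts = toy_matrix([[5, 10], [8, 16], [100, 200]])
        factors = ex.size_factors_median_ratio(counts)
        assert np.isclose(factors.iloc[1] / factors.iloc[0], 2.0)

    def test_matches_brute_force_on_integer_matrix(self):
        counts = toy_matrix([[3, 7, 11], [1, 2, 4], [10, 10, 9], [6, 2, 8], [5, 5, 5]])
        expected = brute_force_size_factors(counts)
        assert np.allclose(ex.size_factors_median_ratio(counts), expected)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(220):
            counts = toy_matrix(rng.integers(0, 50, size=(rng.integers(2, 8), rng.integers(2, 5))))
            if not (counts > 0).all(axis=1).any():
                continue
            got = ex.size_factors_median_ratio(counts)
            assert np.allclose(got, brute_force_size_factors(counts))

    def test_matches_pydeseq2(self):
        """Cross-check against the reference DESeq2 implementation."""
        anndata = pytest.importorskip("anndata")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(40, 6)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        meta = pd.DataFrame({"condition": ["a", "b"] * 3}, index=counts.columns)
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        ref = pd.Series(dds.obs["size_factors"].to_numpy(), index=counts.columns)
        ours = ex.size_factors_median_ratio(counts)
        # even gene counts interpolate the median in log space there,
        # ratio space here; agreement is to ~1e-4 relative
        assert np.allclose(ours, ref, rtol=1e-3)

    def test_no_all_positive_gene_raises(self):
        counts = toy_matrix([[0, 5], [5, 0]])
        with pytest.raises(NormalizationError):
            ex.size_factors_median_ratio(counts)


class TestNormalize:
    def test_median_ratio_identity_on_identical_columns(self):
        counts = toy_matrix([[4, 4], [9, 9]])
        pd.testing.assert_frame_equal(ex.normalize(counts, "median_ratio"), counts)

    def test_library_depth_equalizes_column_sums(self, rng):
        counts = toy_matrix(rng.integers(1, 100, size=(10, 4)))
        norm = ex.normalize(counts, "library_depth")
        sums = norm.sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])

    def test_library_depth_matches_hand_computation(self):
        counts = toy_matrix([[10, 30], [20, 10], [30, 40], [40, 120]])
        norm = ex.normalize(counts, "library_depth")
        # totals 100 and 200, mean 150 -> scale columns by 1.5 and 0.75
        expected = toy_matrix([[15, 22.5], [30, 7.5], [45, 30], [60, 90]])
        pd.testing.assert_frame_equal(norm, expected)

    def test_zero_total_column_raises(self):
        counts = toy_matrix([[0, 5], [0, 3]])
        with pytest.raises(NormalizationError, match="s1"):
            ex.normalize(counts, "library_depth")

    def test_unknown_method_raises(self):
        with pytest.raises(SymisleError):
            ex.normalize(toy_matrix([[1]]), "quantile")


class TestLogRatio:
    def test_equal_means_give_zero(self):
        counts = toy_matrix([[7, 7, 7, 7]])
        r = ex.log_ratio(counts, ["s1", "s2"], ["s3", "s4"])
        assert np.allclose(r, 0.0)

    def test_fourfold_gives_two_with_small_pseudocount(self):
        counts = toy_matrix([[4000, 4000, 1000, 1000]])
        r = ex.log_ratio(counts, ["s1", "s2"], ["s3", "s4"], pseudocount=1e-9)
        assert np.allclose(r, 2.0)

    def test_matches_direct_recomputation(self, rng):
        counts = toy_matrix(rng.integers(0, 1000, size=(10, 6)))
        nod, root = ["s1", "s2", "s3"], ["s4", "s5", "s6"]
        r = ex.log_ratio(counts, nod, root, pseudocount=1.0)
        expected = np.log2(
            (counts[nod].mean(axis=1) + 1) / (counts[root].mean(axis=1) + 1)
        )
        assert np.allclose(r, expected)

    def test_unknown_sample_raises(self):
        with pytest.raises(SymisleError, match="sX"):
            ex.log_ratio(toy_matrix([[1, 2]]), ["sX"], ["s2"])


class TestCrossSpeciesCorrelation:
    def test_identical_ratios_give_one(self):
        r = pd.Series({"a1": 1.0, "a2": -0.5, "a3": 2.0})
        rb = pd.Series({"b1": 1.0, "b2": -0.5, "b3": 2.0})
        pairs = [("a1", "b1"), ("a2", "b2"), ("a3", "b3")]
        val, n = ex.cross_species_ratio_correlation(r, rb, pairs)
        assert n == 3 and np.isclose(val, 1.0)

    def test_negated_ratios_give_minus_one(self):
        r = pd.Series({"a1": 1.0, "a2": -0.5, "a3": 2.0})
        rb = -r.rename({"a1": "b1", "a2": "b2", "a3": "b3"})
        val, _ = ex.cross_species_ratio_correlation(
            r, rb, [("a1", "b1"), ("a2", "b2"), ("a3", "b3")]
        )
        assert np.isclose(val, -1.0)

    def test_matches_textbook_pearson(self):
        xs = [0.2, 1.5, -0.7, 2.2, 0.0, -1.1]
        ys = [0.5, 1.1, -0.9, 1.8, 0.3, -0.6]
        ra = pd.Series(xs, index=[f"a{i}" for i in range(6)])
        rb = pd.Series(ys, index=[f"b{i}" for i in range(6)])
        pairs = [(f"a{i}", f"b{i}") for i in range(6)]
        val, n = ex.cross_species_ratio_correlation(ra, rb, pairs)
        assert n == 6
        assert np.isclose(val, stats.pearsonr(xs, ys).statistic)

    def test_fewer_than_three_pairs_is_undefined(self):
        ra = pd.Series({"a1": 1.0, "a2": 2.0})
        rb = pd.Series({"b1": 1.0, "b2": 2.0})
        val, n = ex.cross_species_ratio_correlation(ra, rb, [("a1", "b1"), ("a2", "b2")])
        assert n == 2 and np.isnan(val)

    def test_repeated_target_contributes_repeated_pairs(self):
        ra = pd.Series({"a1": 1.0, "a2": 1.1, "a3": -2.0})
        rb = pd.Series({"b1": 0.9, "b2": -1.5})
        pairs = [("a1", "b1"), ("a2", "b1"), ("a3", "b2")]
        val, n = ex.cross_species_ratio_correlation(ra, rb, pairs)
        assert n == 3
        expected = stats.pearsonr([1.0, 1.1, -2.0], [0.9, 0.9, -1.5]).statistic
        assert np.isclose(val, expected)


class TestIslandMeanPairwise:
    def test_identical_profiles_give_one(self):
        m = toy_matrix([[1, 5, 9, 2], [1, 5, 9, 2]])
        c = ex.island_mean_pairwise_correlation(["g1", "g2"], m, list(m.columns))
        assert c.defined and np.isclose(c.mean_pairwise_r, 1.0)
        assert c.n_pairs == 1

    def test_orthogonal_profiles_average_to_one_third(self):
        """Three genes engineered so pairwise r are exactly (1, 0, 0)."""
        base = np.array([0.0, 1.0, 2.0, 3.0])
        orth = np.array([1.0, 0.0, 3.0, 2.0])  # r(base, orth) = 0.8 in raw space
        # construct profiles in log space: log2(x+1) must give the vectors
        m = toy_matrix(np.power(2.0, np.vstack([base, base, 2 * base - base.mean()])) - 1)
        # direct averaging oracle on the log profiles
        logs = np.log2(m.to_numpy() + 1)
        rs = [
            np.corrcoef(logs[i], logs[j])[0, 1]
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        c = ex.island_mean_pairwise_correlation(list(m.index), m, list(m.columns))
        assert np.isclose(c.mean_pairwise_r, np.mean(rs))

    def test_single_gene_island_undefined(self):
        m = toy_matrix([[1, 2, 3]])
        c = ex.island_mean_pairwise_correlation(["g1"], m, list(m.columns))
        assert not c.defined and c.n_pairs == 0

    def test_zero_variance_profiles_excluded_and_counted(self):
        m = toy_matrix([[5, 5, 5], [1, 2, 3], [2, 4, 6]])
        c = ex.island_mean_pairwise_correlation(["g1", "g2", "g3"], m, list(m.columns))
        assert c.n_zero_variance == 1
        assert c.n_genes_used == 2
        assert c.n_pairs == 1

    def test_gene_order_invariance(self, rng):
        m = toy_matrix(rng.integers(0, 100, size=(5, 6)))
        genes = list(m.index)
        c1 = ex.island_mean_pairwise_correlation(genes, m, list(m.columns))
        c2 = ex.island_mean_pairwise_correlation(genes[::-1], m, list(m.columns))
        assert np.isclose(c1.mean_pairwise_r, c2.mean_pairwise_r)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(220):
            n_genes = int(rng.integers(2, 6))
            m = toy_matrix(rng.integers(0, 60, size=(n_genes, 5)))
            c = ex.island_mean_pairwise_correlation(list(m.index), m, list(m.columns))
            logs = np.log2(m.to_numpy(dtype=float) + 1)
            keep = [i for i in range(n_genes) if logs[i].var() > 0]
            if len(keep) < 2:
                assert not c.defined
                continue
            rs = [
                stats.pearsonr(logs[i], logs[j]).statistic
                for k, i in enumerate(keep)
                for j in keep[k + 1 :]
            ]
            assert np.isclose(c.mean_pairwise_r, np.mean(rs))
            assert -1.0 <= c.mean_pairwise_r <= 1.0 + 1e-12


def call_with_flags(island_id, flags):
    return MicrosyntenyCall(island_id, "chr1" if any(flags.values()) else None, flags, sum(flags.values()))


class TestDeduplication:
    def test_three_genes_one_target_excluded(self):
        best = {f"a{i}": ("b1", 100.0 - i, 1e-30) for i in range(3)}
        call = call_with_flags("isl", {f"a{i}": True for i in range(3)})
        d = ex.deduplicate_island(list(best), best, call)
        assert d.pairs == [("a0", "b1")]  # highest bitscore retained
        assert d.excluded

    def test_four_genes_three_targets_retained(self):
        best = {
            "a1": ("b1", 100.0, 1e-30),
            "a2": ("b1", 90.0, 1e-30),
            "a3": ("b2", 80.0, 1e-30),
            "a4": ("b3", 70.0, 1e-30),
        }
        call = call_with_flags("isl", {a: True for a in best})
        d = ex.deduplicate_island(list(best), best, call)
        assert d.pairs == [("a1", "b1"), ("a3", "b2"), ("a4", "b3")]
        assert not d.excluded

    def test_no_syntenic_hits_excluded_with_no_pairs(self):
        best = {"a1": ("b1", 100.0, 1e-30)}
        call = call_with_flags("isl", {"a1": False})
        d = ex.deduplicate_island(["a1"], best, call)
        assert d.pairs == [] and d.excluded

    def test_bitscore_tie_breaks_to_smaller_gene_id(self):
        best = {"a9": ("b1", 100.0, 1e-30), "a2": ("b1", 100.0, 1e-30)}
        call = call_with_flags("isl", {"a9": True, "a2": True})
        d = ex.deduplicate_island(["a9", "a2"], best, call)
        assert d.pairs == [("a2", "b1")]

    def test_unique_genes_are_subset_of_redundant(self, small_members, small_best_hits, small_calls):
        for island_id, members in small_members.items():
            redundant = ex.pairs_redundant(members, small_best_hits)
            d = ex.deduplicate_island(members, small_best_hits, small_calls[island_id])
            assert set(d.pairs) <= set(redundant)
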