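"""Diversity indices, Bray-Curtis, PERMANOVA, and dispersion homogeneity."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from foulscan import synthetic as syn
from foulscan.stats import (
    AbundanceMatrix,
    DistanceMatrix,
    aggregate_rank,
    alpha_diversity,
    bray_curtis,
    dispersion_test,
    expected_rarefied_richness,
    marker_exclusive_taxa,
    permanova,
    rarefaction,
    sqrt_relative_transform,
)


def matrix(counts, groups=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    groups = groups or ["g1"] * (n // 2) + ["g2"] * (n - n // 2)
    return AbundanceMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        group_labels=groups,
        otu_ids=[f"o{j}" for j in range(counts.shape[1])],
        counts=counts,
    )


class TestAlphaDiversity:
    def test_single_otu(self):
        a = alpha_diversity([10])
        assert (a.observed, a.chao1, a.shannon, a.inv_simpson) == (1, 1.0, 0.0, 1.0)

    def test_uniform_two_otus(self):
        a = alpha_diversity([5, 5])
        assert a.shannon == pytest.approx(np.log(2))
        assert a.inv_simpson == pytest.approx(2.0)

    def test_chao1_formula(self):
        # S_obs=5, F1=2 singletons, F2=1 doubleton -> 5 + 2*1/(2*2) = 5.5
        a = alpha_diversity([1, 1, 2, 3, 4])
        assert a.chao1 == pytest.approx(5.5)

    def test_chao1_defined_without_doubletons(self):
        a = alpha_diversity([1, 1, 5])
        assert a.chao1 == pytest.approx(3 + 2 * 1 / 2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0, 0])

    def test_inequality_chain_on_random_vectors(self, rng):
        """chao1 >= S_obs and 1 <= inv_simpson <= exp(shannon) <= S_obs."""
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            x = rng.integers(0, 50, size=n)
            if x.sum() == 0:
                x[rng.integers(0, n)] = 1
            a = alpha_diversity(x)
            assert a.chao1 >= a.observed
            assert 1.0 <= a.inv_simpson <= np.exp(a.shannon) + 1e-9
            assert np.exp(a.shannon) <= a.observed + 1e-9


class TestRarefaction:
    def test_full_depth_is_observed_richness(self):
        counts = [5, 3, 0, 2]
        out = rarefaction(counts, [10], n_iter=5, seed=1)
        assert out[10] == 3.0

    def test_depth_one(self):
        out = rarefaction([4, 4], [1], n_iter=50, seed=2)
        assert out[1] == 1.0

    def test_matches_hypergeometric_expectation(self, rng):
        counts = rng.integers(0, 30, size=25)
        counts[counts.argmin()] = 1
        total = int(counts.sum())
        depth = total // 2
        mc = rarefaction(counts, [depth], n_iter=400, seed=3)[depth]
        exact = expected_rarefied_richness(counts, depth)
        # MC standard error of a 25-category richness mean at 400 draws
        assert abs(mc - exact) < 0.35

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction([2, 2], [5], n_iter=2, seed=1)


class TestBrayCurtis:
    def test_identical_samples(self):
        d = bray_curtis(matrix([[3, 4], [3, 4]]))
        assert d.d[0, 1] == 0.0

    def test_disjoint_supports_without_dummy(self):
        d = bray_curtis(matrix([[1, 0], [0, 1]]), dummy=0)
        assert d.d[0, 1] == 1.0

    def test_dummy_shrinks_disjoint_distance(self):
        d = bray_curtis(matrix([[1, 0], [0, 1]]))
        expected = 2 / (2 + 2e-4)  # |1-0|+|0-1| over totals plus two dummies
        assert d.d[0, 1] == pytest.approx(expected)

    def test_all_zero_pair_defined_as_zero(self):
        d = bray_curtis(matrix([[0, 0], [0, 0], [1, 2]]))
        assert d.d[0, 1] == 0.0

    def test_properties_on_random_matrices(self, rng):
        for _ in range(10):
            X = rng.integers(0, 40, size=(6, 12))
            d = bray_curtis(matrix(X)).d
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= 0).all() and (d <= 1).all()

    def test_matches_scipy_without_dummy(self, rng):
        X = rng.integers(1, 40, size=(5, 8)).astype(float)
        mine = bray_curtis(matrix(X), dummy=0).d
        ref = squareform(pdist(X, metric="braycurtis"))
        assert np.allclose(mine, ref)


# counts and frozen oracle values computed with vegan (adonis2 / betadisper,
# Bray-Curtis on counts plus a 1e-4 dummy column, centroid type)
VEGAN_COUNTS = np.array(
    [
        [28, 6, 43, 33, 4, 7],
        [33, 13, 43, 29, 3, 2],
        [42, 8, 36, 44, 4, 3],
        [17, 6, 70, 66, 5, 4],
        [362, 12, 67, 29, 4, 14],
        [63, 7, 59, 87, 5, 8],
        [32, 13, 95, 65, 7, 7],
        [122, 17, 103, 83, 3, 1],
    ]
)
VEGAN_GROUPS = ["painted"] * 4 + ["bare"] * 4
VEGAN_ADONIS_F = 3.854354
VEGAN_ADONIS_R2 = 0.3911321
VEGAN_BETADISPER_F = 2.591096
VEGAN_MEAN_DISTS = {"bare": 0.2241022, "painted": 0.1268197}


class TestPermanova:
    def test_ss_decomposition_on_random_input(self, rng):
        for _ in range(10):
            X = rng.integers(0, 50, size=(8, 10))
            m = matrix(X)
            res = permanova(bray_curtis(m), m.group_labels, n_perm=9, seed=0)
            assert res.SS_between + res.SS_within == pytest.approx(
                res.SS_total, abs=1e-9
            )
            assert 0 <= res.R2 <= 1

    def test_no_structure_gives_p_one(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0)
        res = permanova(DistanceMatrix(list("abcdef"), d), ["a"] * 3 + ["b"] * 3)
        assert res.p_value == 1.0

    def test_exhaustive_enumeration_minimum(self):
        """6 samples in 2 groups of 3 have 20 relabellings; a clean
        within/between split is matched only by itself and its complement."""
        d = np.full((6, 6), 0.9)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        res = permanova(
            DistanceMatrix(list("abcdef"), d), ["a"] * 3 + ["b"] * 3, n_perm=9999
        )
        assert res.exhaustive
        assert res.p_value == pytest.approx(2 / 20)

    def test_matches_vegan_adonis(self):
        m = matrix(VEGAN_COUNTS, groups=VEGAN_GROUPS)
        res = permanova(bray_curtis(m), m.group_labels, n_perm=999, seed=0)
        assert res.pseudo_F == pytest.approx(VEGAN_ADONIS_F, abs=1e-6)
        assert res.R2 == pytest.approx(VEGAN_ADONIS_R2, abs=1e-6)

    def test_group_name_and_order_invariance(self, rng):
        X = rng.integers(0, 50, size=(10, 12))
        m = matrix(X, groups=["p"] * 5 + ["b"] * 5)
        d = bray_curtis(m)
        res1 = permanova(d, m.group_labels, n_perm=199, seed=7)
        res2 = permanova(d, ["grp_" + g for g in m.group_labels], n_perm=199, seed=7)
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)
        assert res1.p_value == res2.p_value

    def test_small_groups_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(DistanceMatrix(list("abc"), d), ["a", "a", "b"])


class TestDispersion:
    def test_euclidean_worked_example(self):
        """Two side-by-side point pairs: every point sits 1.0 from its
        group centroid (centroids at the segment midpoints)."""
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0], [2.0, 1.0]])
        d = squareform(pdist(pts))
        res = dispersion_test(
            DistanceMatrix(list("abcd"), d), ["A", "A", "B", "B"], n_perm=99, seed=1
        )
        assert res.group_mean_distances["A"] == pytest.approx(1.0)
        assert res.group_mean_distances["B"] == pytest.approx(1.0)

    def test_matches_vegan_betadisper(self):
        m = matrix(VEGAN_COUNTS, groups=VEGAN_GROUPS)
        res = dispersion_test(bray_curtis(m), m.group_labels, n_perm=99, seed=0)
        assert res.F_stat == pytest.approx(VEGAN_BETADISPER_F, abs=1e-6)
        for g, v in VEGAN_MEAN_DISTS.items():
            assert res.group_mean_distances[g] == pytest.approx(v, abs=1e-6)

    def test_detects_dispersion_difference(self):
        m = syn.gen_abundance(syn.GroupEffectSpec(10, 20, 0.0, 4.0, seed=17))
        res = dispersion_test(bray_curtis(m), m.group_labels, n_perm=199, seed=3)
        assert res.p_value <= 0.05


class TestAggregateRank:
    def make(self):
        m = matrix(np.array([[30, 70], [10, 0]]))
        lineages = {
            "o0": ("Animalia", "Mollusca", "Bivalvia", "Mytilida", "Mytilidae",
                   "Mytilus", "Mytilus edulis"),
            "o1": ("Animalia", "Chordata", "Ascidiacea", "Phlebobranchia",
                   "Cionidae", "Ciona", "Ciona intestinalis"),
        }
        return m, lineages

    def test_two_phyla_split(self):
        m, lineages = self.make()
        rel = aggregate_rank(m, lineages, "phylum")
        assert rel.loc["s0", "Mollusca"] == pytest.approx(0.3)
        assert rel.loc["s0", "Chordata"] == pytest.approx(0.7)
        assert rel.loc["s1", "Mollusca"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        X = rng.integers(1, 30, size=(4, 2))
        m, lineages = self.make()
        m = matrix(X)
        rel = aggregate_rank(m, lineages, "phylum")
        assert np.allclose(rel.sum(axis=1), 1.0)

    def test_missing_assignment_pooled_unassigned(self):
        m, lineages = self.make()
        del lineages["o1"]
        rel = aggregate_rank(m, lineages, "phylum")
        assert rel.loc["s0", "Unassigned"] == pytest.approx(0.7)

    def test_all_zero_sample_flagged(self):
        m = matrix(np.array([[0, 0], [5, 5]]))
        _, lineages = self.make()
        rel = aggregate_rank(m, lineages, "phylum")
        assert rel.attrs["all_zero_samples"] == ["s0"]
        assert rel.loc["s0"].sum() == 0

    def test_unknown_rank(self):
        m, lineages = self.make()
        with pytest.raises(ValueError):
            aggregate_rank(m, lineages, "tribe")


class TestMarkerExclusives:
    def test_identical_sets_no_exclusives(self):
        s = {"16S": {"A", "B"}, "18S": {"A", "B"}}
        excl, _ = marker_exclusive_taxa(s)
        assert excl == {"16S": set(), "18S": set()}

    def test_single_marker_all_exclusive(self):
        excl, shared = marker_exclusive_taxa({"COI": {"A", "B"}})
        assert excl == {"COI": {"A", "B"}} and shared == {}

    def test_matches_brute_force_set_algebra(self, rng):
        taxa = [f"P{i}" for i in range(12)]
        sets = {
            m: {t for t in taxa if rng.random() < 0.4}
            for m in ("16S", "18S", "23S", "COI")
        }
        excl, shared = marker_exclusive_taxa(sets)
        for m in sets:
            brute = sets[m] - set().union(*(sets[o] for o in sets if o != m))
            assert excl[m] == brute
        # exclusive sets pairwise disjoint
        all_excl = [x for s in excl.values() for x in s]
        assert len(all_excl) == len(set(all_excl))


def test_sqrt_relative_transform_rows():
    m = matrix(np.array([[1, 3], [2, 2]]))
    out = sqrt_relative_transform(m)
    assert np.allclose(out.counts**2, [[0.25, 0.75], [0.5, 0.5]])
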