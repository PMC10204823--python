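"""Beta-diversity oracles: UniFrac branch classification, PCoA geometry,
PERMANOVA permutation enumeration, centroid distances and DPCoA algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import skbio
from azairway import (
    DistanceMatrix,
    FeatureTable,
    SampleMetadata,
    distance_matrix,
    distance_to_sputum_centroid,
    dpcoa,
    pcoa,
    permanova,
    simulate_tree,
    unweighted_unifrac,
    weighted_unifrac,
)


# ---------------------------------------------------------------------------
# Brute-force branch-classification oracles
# ---------------------------------------------------------------------------

def _branch_leafsets(tree):
    for node in tree.tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        yield node.length, leaves


def unweighted_oracle(set_a, set_b, tree):
    unique = total = 0.0
    for length, leaves in _branch_leafsets(tree):
        in_a, in_b = bool(leaves & set_a), bool(leaves & set_b)
        if in_a or in_b:
            total += length
        if in_a != in_b:
            unique += length
    return unique / total


def weighted_oracle(counts_a, counts_b, names, tree, normalized):
    pa = np.asarray(counts_a, float) / np.sum(counts_a)
    pb = np.asarray(counts_b, float) / np.sum(counts_b)
    prop_a = dict(zip(names, pa))
    prop_b = dict(zip(names, pb))
    num = denom = 0.0
    for length, leaves in _branch_leafsets(tree):
        fa = sum(prop_a.get(n, 0.0) for n in leaves)
        fb = sum(prop_b.get(n, 0.0) for n in leaves)
        num += length * abs(fa - fb)
        denom += length * (fa + fb)
    return num / denom if normalized else num


class TestUniFrac:
    def test_identical_presence_is_zero(self, cherry_tree):
        assert unweighted_unifrac([1, 1, 0], [2, 9, 0], ["A", "B", "C"], cherry_tree) == 0.0

    def test_star_tree_disjoint_sets(self, star_tree):
        d = unweighted_unifrac(
            [1, 1, 0, 0], [0, 0, 1, 0], ["t1", "t2", "t3", "t4"], star_tree
        )
        assert d == pytest.approx(1.0)

    def test_cherry_hand_partition(self, cherry_tree):
        d = unweighted_unifrac([1, 1, 0], [1, 0, 1], ["A", "B", "C"], cherry_tree)
        assert d == pytest.approx(0.6)

    def test_weighted_identity_and_scale_invariance(self, cherry_tree):
        names = ["A", "B", "C"]
        assert weighted_unifrac([2, 4, 0], [1, 2, 0], names, cherry_tree) == pytest.approx(0.0)
        d1 = weighted_unifrac([2, 4, 1], [5, 0, 3], names, cherry_tree)
        d2 = weighted_unifrac([4, 8, 2], [5, 0, 3], names, cherry_tree)
        assert d1 == pytest.approx(d2)

    def test_weighted_star_raw_and_normalized(self, star_tree):
        names = ["t1", "t2", "t3", "t4"]
        raw = weighted_unifrac([9, 0, 0, 0], [0, 4, 0, 0], names, star_tree, normalized=False)
        norm = weighted_unifrac([9, 0, 0, 0], [0, 4, 0, 0], names, star_tree, normalized=True)
        assert raw == pytest.approx(2.0)
        assert norm == pytest.approx(1.0)

    def test_both_empty_rejected(self, cherry_tree):
        with pytest.raises(ValueError, match="empty"):
            unweighted_unifrac([0, 0, 0], [0, 0, 0], ["A", "B", "C"], cherry_tree)

    def test_matches_branch_oracle_on_random_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            tree = simulate_tree(n, seed=int(rng.integers(2**31)))
            names = tree.leaf_names
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            if a.sum() == 0:
                a[0] = 1
            if b.sum() == 0:
                b[-1] = 1
            set_a = {nm for nm, c in zip(names, a) if c}
            set_b = {nm for nm, c in zip(names, b) if c}
            got = unweighted_unifrac(a, b, names, tree)
            assert got == pytest.approx(unweighted_oracle(set_a, set_b, tree), abs=1e-10)
            for normalized in (True, False):
                got_w = weighted_unifrac(a, b, names, tree, normalized=normalized)
                assert got_w == pytest.approx(
                    weighted_oracle(a, b, names, tree, normalized), abs=1e-10
                )

    def test_unweighted_triangle_inequality_small_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            tree = simulate_tree(n, seed=int(rng.integers(2**31)))
            names = tree.leaf_names
            samples = rng.integers(0, 2, size=(4, n))
            samples[samples.sum(axis=1) == 0, 0] = 1
            d = np.zeros((4, 4))
            for i, j in itertools.combinations(range(4), 2):
                d[i, j] = d[j, i] = unweighted_unifrac(samples[i], samples[j], names, tree)
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestDistanceMatrix:
    def test_single_sample_zero_matrix(self, cherry_tree):
        table = FeatureTable(pd.DataFrame([[1, 1, 0]], index=["S"], columns=["A", "B", "C"]))
        dm = distance_matrix(table, cherry_tree)
        assert dm.data.shape == (1, 1) and dm.data[0, 0] == 0.0

    def test_duplicated_sample_distance_zero(self, cherry_tree):
        table = FeatureTable(
            pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["S1", "S2"], columns=["A", "B", "C"])
        )
        dm = distance_matrix(table, cherry_tree)
        assert dm.data[0, 1] == 0.0

    def test_entries_equal_pairwise_calls(self, rng):
        n = 8
        tree = simulate_tree(n, seed=11)
        names = tree.leaf_names
        counts = rng.integers(0, 10, size=(5, n))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"S{i}" for i in range(5)], columns=names)
        )
        for metric, func in [
            ("unweighted_unifrac", unweighted_unifrac),
            ("weighted_unifrac", weighted_unifrac),
        ]:
            dm = distance_matrix(table, tree, metric)
            for i, j in itertools.combinations(range(5), 2):
                assert dm.data[i, j] == pytest.approx(
                    func(counts[i], counts[j], names, tree), abs=1e-12
                )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), "m")


class TestPCoA:
    def test_line_configuration_reconstructs_gaps(self):
        points = np.array([[0.0, 1.0], [0.0, 3.0], [0.0, 7.0]])
        dm = DistanceMatrix(["a", "b", "c"], squareform(pdist(points)), "euclidean")
        res = pcoa(dm)
        x = res.coordinates.iloc[:, 0].to_numpy()
        assert abs(x[0] - x[1]) == pytest.approx(2.0, abs=1e-8)
        assert abs(x[1] - x[2]) == pytest.approx(4.0, abs=1e-8)
        assert abs(x[0] - x[2]) == pytest.approx(6.0, abs=1e-8)

    def test_equilateral_configuration(self):
        d = 0.8
        dm = DistanceMatrix(["a", "b", "c"], d * (1 - np.eye(3)), "toy")
        rec = pcoa(dm).distances()
        off = rec.data[np.triu_indices(3, 1)]
        assert off == pytest.approx([d, d, d], abs=1e-8)

    def test_random_euclidean_configuration_reconstructed(self, rng):
        points = rng.normal(size=(12, 4))
        dm = DistanceMatrix(
            [f"s{i}" for i in range(12)], squareform(pdist(points)), "euclidean"
        )
        res = pcoa(dm)
        assert res.correction is None
        np.testing.assert_allclose(res.distances().data, dm.data, atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_non_euclidean_input_corrected_and_flagged(self):
        # violates the triangle-embedding: one huge distance among near-zeros
        d = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 2.8], [1, 1, 2.8, 0]]
        )
        dm = DistanceMatrix(list("abcd"), d, "toy")
        res = pcoa(dm)
        assert res.correction == "lingoes"
        assert np.all(res.eigenvalues >= 0)

    def test_agrees_with_reference_implementation(self, rng):
        points = rng.normal(size=(9, 3))
        dmat = squareform(pdist(points))
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(9)], dmat, "e"))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dmat))
        k = min(3, ours.coordinates.shape[1])
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[:k]), np.sort(ref.eigvals.to_numpy()[:k]), atol=1e-8
        )


def _two_cluster_dm():
    # 4 + 4 tight clusters: 2/C(8,4) = 0.029 is the attainable minimum p
    pts = np.array(
        [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1],
         [5, 5], [5.1, 5], [5, 5.1], [5.1, 5.1]]
    )
    ids = [f"s{i}" for i in range(8)]
    return DistanceMatrix(ids, squareform(pdist(pts)), "euclidean")


class TestPermanova:
    def test_separated_clusters_significant(self):
        dm = _two_cluster_dm()
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.pvalue <= 0.05
        assert res.r_squared > 0.9

    def test_matches_exhaustive_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], squareform(pdist(pts)), "e")
        labels = np.array(["a"] * 3 + ["b"] * 3)
        d2 = dm.data**2
        from azairway.beta import _pseudo_f

        f_obs = _pseudo_f(d2, labels)
        hits = total = 0
        for pos in itertools.combinations(range(6), 3):
            perm = np.array(["b"] * 6)
            perm[list(pos)] = "a"
            hits += _pseudo_f(d2, perm) >= f_obs - 1e-12
            total += 1
        p_exact = hits / total
        res = permanova(dm, labels, n_perm=9999, seed=1)
        assert res.pvalue == pytest.approx(p_exact, abs=0.02)

    def test_agrees_with_reference_implementation(self, rng):
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(pts)), "e")
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=999, seed=3)
        ref = skbio.stats.distance.permanova(dm.to_skbio(), labels, permutations=999, seed=3)
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]), abs=1e-10)
        assert ours.pvalue == pytest.approx(float(ref["p-value"]), abs=0.05)

    def test_deterministic_and_reorder_invariant(self, rng):
        dm = _two_cluster_dm()
        labels = np.array(["a"] * 4 + ["b"] * 4)
        r1 = permanova(dm, labels, n_perm=499, seed=7)
        r2 = permanova(dm, labels, n_perm=499, seed=7)
        assert r1.pvalue == r2.pvalue
        order = rng.permutation(8)
        dm2 = DistanceMatrix(
            [dm.ids[i] for i in order], dm.data[np.ix_(order, order)], "e"
        )
        r3 = permanova(dm2, labels[order], n_perm=499, seed=7)
        assert r3.pseudo_f == pytest.approx(r1.pseudo_f, abs=1e-10)

    def test_group_of_one_rejected(self):
        dm = _two_cluster_dm()
        with pytest.raises(ValueError, match="size"):
            permanova(dm, ["a"] * 7 + ["b"], n_perm=99, seed=0)

    def test_strata_restricts_permutations(self):
        dm = _two_cluster_dm()
        labels = ["a", "b", "a", "b", "a", "b", "a", "b"]
        strata = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
        res = permanova(dm, labels, n_perm=199, seed=5, strata=strata)
        assert 0 < res.pvalue <= 1


def _centroid_fixture(points, sites, phase="EndAZT"):
    ids = [f"s{i}" for i in range(len(points))]
    dm = DistanceMatrix(ids, squareform(pdist(np.asarray(points, float))), "euclidean")
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ids,
                "patient_id": [f"p{i}" for i in range(len(points))],
                "site": sites,
                "phase": [phase] * len(points),
                "time_months": [3.0] * len(points),
            }
        )
    )
    return dm, meta


class TestSputumCentroid:
    def test_single_sputum_sample_reduces_to_pairwise_distance(self):
        dm, meta = _centroid_fixture([[0, 0], [3, 4]], ["LRT", "URT"])
        dist = distance_to_sputum_centroid(dm, meta, "EndAZT")
        assert dist.iloc[0] == pytest.approx(5.0, abs=1e-8)

    def test_identical_profile_gives_zero(self):
        dm, meta = _centroid_fixture([[1, 1], [1, 1], [9, 9]], ["LRT", "URT", "URT"])
        dist = distance_to_sputum_centroid(dm, meta, "EndAZT")
        assert dist["s1"] == pytest.approx(0.0, abs=1e-8)

    def test_planar_closed_form_geometry(self):
        # sputum at (0,0),(4,0),(2,3) -> centroid (2,1); OPS at (5,5) and (2,1)
        points = [[0, 0], [4, 0], [2, 3], [5, 5], [2, 1]]
        sites = ["LRT", "LRT", "LRT", "URT", "URT"]
        dm, meta = _centroid_fixture(points, sites)
        dist = distance_to_sputum_centroid(dm, meta, "EndAZT")
        assert dist["s3"] == pytest.approx(5.0, abs=1e-8)
        assert dist["s4"] == pytest.approx(0.0, abs=1e-8)

    def test_missing_sputum_in_phase_rejected(self):
        dm, meta = _centroid_fixture([[0, 0], [1, 1]], ["URT", "URT"])
        with pytest.raises(ValueError, match="sputum"):
            distance_to_sputum_centroid(dm, meta, "EndAZT")


class TestDPCoA:
    def _equal_distance_inputs(self, counts, d=0.7):
        table = FeatureTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(len(counts))],
                columns=["g1", "g2", "g3"],
            )
        )
        dist = pd.DataFrame(
            d * (1 - np.eye(3)), index=["g1", "g2", "g3"], columns=["g1", "g2", "g3"]
        )
        return table, dist

    def test_pure_sample_sits_on_its_genus(self):
        table, dist = self._equal_distance_inputs([[5, 0, 0], [0, 3, 1]])
        res = dpcoa(table, dist, n_genera=3)
        np.testing.assert_allclose(
            res.coordinates.loc["s0"].to_numpy(),
            res.feature_scores.loc["g1"].to_numpy(),
            atol=1e-10,
        )

    def test_equal_distance_rao_closed_form(self):
        d = 0.7
        counts = [[2, 1, 1], [1, 1, 2], [4, 0, 0], [1, 3, 0]]
        table, dist = self._equal_distance_inputs(counts, d)
        res = dpcoa(table, dist, n_genera=3)
        p = np.asarray(counts, float)
        p /= p.sum(axis=1, keepdims=True)
        x = res.coordinates.to_numpy()
        for i, j in itertools.combinations(range(4), 2):
            expected = (d / 2) * np.sum((p[i] - p[j]) ** 2)
            got = np.sum((x[i] - x[j]) ** 2)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_identical_samples_distance_zero(self):
        table, dist = self._equal_distance_inputs([[2, 1, 1], [2, 1, 1]])
        res = dpcoa(table, dist, n_genera=3)
        x = res.coordinates.to_numpy()
        assert np.linalg.norm(x[0] - x[1]) == pytest.approx(0.0, abs=1e-10)

    def test_too_many_genera_requested(self):
        table, dist = self._equal_distance_inputs([[2, 1, 1]])
        with pytest.raises(ValueError, match="genera"):
            dpcoa(table, dist, n_genera=5)

    def test_cohort_run_top_genus_restriction(self, small_cohort):
        from azairway import collapse_to_genus, genus_distance_matrix

        gt = collapse_to_genus(small_cohort.table, small_cohort.taxonomy)
        gd = genus_distance_matrix(small_cohort.tree, small_cohort.taxonomy)
        res = dpcoa(gt, gd, n_genera=8)
        assert res.feature_scores.shape[0] == 8
        assert res.coordinates.shape[0] == small_cohort.table.shape[0]
        assert res.proportion_explained.sum() <= 1 + 1e-9
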