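"""Distances, UPGMA, bootstrap and cluster summaries."""

import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from labstrain import (
    DistanceMatrix,
    binary_association_distance,
    bootstrap_support,
    cluster_distance_summary,
    encode_binary,
    extract_clusters,
    p_distance,
    upgma,
)
from labstrain.genotype import BinaryMatrix
from labstrain.phylo import encode_alignment
from labstrain.simulate import GeneratorConfig, simulate_strain_population

from _oracles import naive_upgma_cophenetic


def bm_of(rows, ids=None):
    rows = np.asarray(rows, dtype=np.int8)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = [("c", k) for k in range(rows.shape[1])]
    return BinaryMatrix(ids, cols, rows)


def random_dm(rng, n):
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix([f"t{i}" for i in range(n)], d)


class TestAssociationDistance:
    def test_identical_rows_distance_zero(self):
        dm = binary_association_distance(bm_of([[1, 0, 1], [1, 0, 1]]))
        assert dm.d[0, 1] == 0.0

    def test_disjoint_rows_distance_one(self):
        dm = binary_association_distance(bm_of([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert dm.d[0, 1] == 1.0

    def test_hand_computed_dice(self):
        # a=2 shared, b=1 private, c=1 private -> 1 - 4/6
        dm = binary_association_distance(bm_of([[1, 1, 1, 0], [1, 1, 0, 1]]))
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_shared_absences_ignored(self):
        d1 = binary_association_distance(bm_of([[1, 1, 0], [1, 0, 1]])).d[0, 1]
        d2 = binary_association_distance(bm_of([[1, 1, 0, 0, 0], [1, 0, 1, 0, 0]])).d[0, 1]
        assert d1 == d2

    def test_all_zero_row_distance_one_with_warning(self):
        with pytest.warns(UserWarning):
            dm = binary_association_distance(bm_of([[0, 0], [1, 1]]))
        assert dm.d[0, 1] == 1.0

    def test_metric_axioms_except_triangle(self, rng):
        X = (rng.random((10, 20)) < 0.4).astype(np.int8)
        X[:, 0] = 1  # avoid empty rows
        dm = binary_association_distance(bm_of(X))
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert ((dm.d >= 0) & (dm.d <= 1)).all()

    def test_simple_matching_option(self):
        dm = binary_association_distance(bm_of([[1, 1, 0, 0], [1, 0, 0, 0]]),
                                         method="simple")
        assert dm.d[0, 1] == pytest.approx(0.25)


class TestPDistance:
    def test_one_third(self):
        dm = p_distance({"a": "AAT", "b": "AAA"})
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_identical_zero(self):
        assert p_distance({"a": "ACGT", "b": "ACGT"}).d[0, 1] == 0.0

    def test_pairwise_deletion(self):
        dm = p_distance({"a": "AA-", "b": "AAT"})
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            p_distance({"a": "--AT", "b": "AT--"})


class TestUPGMA:
    def test_three_leaf_hand_agglomeration(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(DistanceMatrix(["A", "B", "C"], d))
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == pytest.approx([0.1, 0.3])
        # the cherry is (A,B)
        cherry = min(tree.internal_nodes(), key=lambda n: n.height)
        assert sorted(cherry.leaf_names()) == ["A", "B"]

    def test_two_leaves_cherry_at_half_distance(self):
        tree = upgma(DistanceMatrix(["x", "y"], np.array([[0, 0.4], [0.4, 0]])))
        assert tree.root.height == pytest.approx(0.2)

    def test_matches_naive_reference_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 8))
            dm = random_dm(rng, n)
            tree = upgma(dm)
            coph = tree.cophenetic()
            ddict = {a: {b: dm.d[i, j] for j, b in enumerate(dm.ids)}
                     for i, a in enumerate(dm.ids)}
            ref_coph, ref_heights = naive_upgma_cophenetic(dm.ids, ddict)
            got_heights = sorted(x.height for x in tree.internal_nodes())
            assert got_heights == pytest.approx(ref_heights)
            for a, b in itertools.combinations(dm.ids, 2):
                i, j = dm.ids.index(a), dm.ids.index(b)
                assert coph.d[i, j] == pytest.approx(ref_coph[(a, b)])

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            dm = random_dm(rng, n)
            Z = hierarchy.linkage(squareform(dm.d), method="average")
            scipy_coph = squareform(hierarchy.cophenet(Z))
            assert np.allclose(upgma(dm).cophenetic().d, scipy_coph)

    def test_ultrametric_three_point_condition(self, rng):
        dm = random_dm(rng, 9)
        coph = upgma(dm).cophenetic().d
        for i, j, k in itertools.combinations(range(9), 3):
            a, b, c = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert b == pytest.approx(c)

    def test_min_input_distance_preserved(self, rng):
        dm = random_dm(rng, 8)
        coph = upgma(dm).cophenetic().d
        iu = np.triu_indices(8, 1)
        assert min(coph[iu]) == pytest.approx(min(dm.d[iu]))

    def test_newick_round_trips_through_skbio(self):
        skbio = pytest.importorskip("skbio")
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(DistanceMatrix(["A", "B", "C"], d))
        t = skbio.TreeNode.read([tree.to_newick()])
        assert sorted(x.name for x in t.tips()) == ["A", "B", "C"]
        assert t.find("A").distance(t.find("B")) == pytest.approx(0.2)


class TestBootstrap:
    def block_matrix(self):
        rows = [[1, 1, 1, 0, 0, 0]] * 4 + [[0, 0, 0, 1, 1, 1]] * 4
        return bm_of(rows)

    def test_perfectly_separated_blocks_get_full_support(self):
        tree = bootstrap_support(self.block_matrix(), n_reps=50, seed=1)
        blockA = frozenset(f"s{i}" for i in range(4))
        for node in tree.internal_nodes():
            side = frozenset(node.leaf_names())
            if side in (blockA, frozenset(f"s{i}" for i in range(4, 8))):
                assert node.support == 100.0

    def test_single_replicate_supports_are_binary(self, rng):
        X = (rng.random((6, 12)) < 0.5).astype(np.int8)
        X[:, 0] = 1
        tree = bootstrap_support(bm_of(X), n_reps=1, seed=3)
        assert {n.support for n in tree.internal_nodes()} <= {0.0, 100.0}

    def test_supports_reproducible_and_column_permutation_invariant(self, rng):
        X = (rng.random((7, 20)) < 0.4).astype(np.int8)
        X[:, 0] = 1
        t1 = bootstrap_support(bm_of(X), n_reps=100, seed=7)
        t2 = bootstrap_support(bm_of(X), n_reps=100, seed=7)
        assert [n.support for n in t1.internal_nodes()] == \
            [n.support for n in t2.internal_nodes()]
        perm = rng.permutation(X.shape[1])
        t3 = bootstrap_support(bm_of(X[:, perm]), n_reps=100, seed=7)
        assert [n.support for n in t3.internal_nodes()] == \
            [n.support for n in t1.internal_nodes()]

    def test_supports_stable_across_seeds(self):
        gts, _, _ = simulate_strain_population(GeneratorConfig(seed=2, strains_per_host=4,
                                                               n_singletons=2))
        bm = encode_binary(gts)
        t1 = bootstrap_support(bm, n_reps=1000, seed=1)
        t2 = bootstrap_support(bm, n_reps=1000, seed=2)
        s1 = np.array([n.support for n in t1.internal_nodes()])
        s2 = np.array([n.support for n in t2.internal_nodes()])
        assert np.abs(s1 - s2).max() <= 5.0

    def test_sequence_bootstrap_runs(self):
        seqs = {"a": "ACGTACGTAA", "b": "ACGTACGTAT", "c": "TTTTACGTAA"}
        tree = bootstrap_support(seqs, n_reps=50, seed=0)
        assert sorted(tree.leaf_names()) == ["a", "b", "c"]
        assert all(n.support is not None for n in tree.internal_nodes())


class TestClustersAndSummaries:
    def three_leaf_tree(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        return upgma(DistanceMatrix(["A", "B", "C"], d))

    def test_k2_cut_separates_cherry(self):
        labels = extract_clusters(self.three_leaf_tree(), k=2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_k_equals_leaf_count_gives_singletons(self):
        labels = extract_clusters(self.three_leaf_tree(), k=3)
        assert len(set(labels.values())) == 3

    def test_height_cut(self):
        labels = extract_clusters(self.three_leaf_tree(), height=0.15)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_tied_heights_warn(self):
        d = np.array([
            [0, 0.2, 1.0, 1.0],
            [0.2, 0, 1.0, 1.0],
            [1.0, 1.0, 0, 0.2],
            [1.0, 1.0, 0.2, 0],
        ])
        tree = upgma(DistanceMatrix(list("abcd"), d))
        with pytest.warns(UserWarning):
            extract_clusters(tree, k=3)

    def test_hand_computed_within_summary(self):
        # within distances {0.1, 0.2, 0.3}
        d = np.array([
            [0, 0.1, 0.2, 0.9],
            [0.1, 0, 0.3, 0.9],
            [0.2, 0.3, 0, 0.9],
            [0.9, 0.9, 0.9, 0],
        ])
        s = cluster_distance_summary(DistanceMatrix(list("abcx"), d), ["a", "b", "c"])
        assert s.within_mean == pytest.approx(0.2)
        assert s.within_sd == pytest.approx(0.1)
        assert s.between_mean == pytest.approx(0.9)

    def test_identical_members_zero_within(self):
        d = np.zeros((3, 3))
        s = cluster_distance_summary(DistanceMatrix(list("abc"), d), ["a", "b"])
        assert (s.within_mean, s.within_sd) == (0.0, 0.0)

    def test_unknown_member_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="zzz"):
            cluster_distance_summary(DistanceMatrix(list("ab"), d), ["a", "zzz"])


def test_between_cluster_distance_increases_with_founder_divergence(rng):
    """Pipeline-level monotonicity: founder divergence drives separation."""
    from scipy.stats import spearmanr
    divergences, means = [], []
    # larger within-host walks keep the Dice distance below saturation, so
    # founder spacing remains visible in the between-cluster mean
    for div in (1, 2, 3, 4, 5):
        for rep in range(8):
            cfg = GeneratorConfig(seed=1000 + rep, founder_divergence=div,
                                  within_host_steps=1.5,
                                  strains_per_host=6, n_singletons=0)
            gts, _, truth = simulate_strain_population(cfg)
            dm = binary_association_distance(encode_binary(gts))
            between = []
            ids = [g.strain_id for g in gts]
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    if truth.cluster_of[a] != truth.cluster_of[b]:
                        between.append(dm.d[ids.index(a), ids.index(b)])
            divergences.append(div)
            means.append(np.mean(between))
    rho = spearmanr(divergences, means).statistic
    assert rho > 0.9
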