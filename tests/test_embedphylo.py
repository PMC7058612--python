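import itertools

import numpy as np
import pytest
from skbio import TreeNode

from mitolandscape import embedphylo as ep
from mitolandscape.iohap import MISSING, HaploidGenotypeMatrix, VariantRecord


def make_matrix(calls, ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    ids = ids or [f"s{i}" for i in range(n)]
    variants = [VariantRecord("MT", 10 * (j + 1), "A", "G") for j in range(m)]
    return HaploidGenotypeMatrix(ids, variants, calls)


class TestHammingDistances:
    def test_identical_rows_distance_zero(self):
        d = ep.hamming_distances(make_matrix([[0, 1, 1], [0, 1, 1]]))
        assert d.values[0, 1] == 0.0

    def test_one_mismatch_of_three(self):
        d = ep.hamming_distances(make_matrix([[0, 0, 1], [0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_missing_pairwise_deletion(self):
        d = ep.hamming_distances(make_matrix([[0, MISSING, 1], [0, 1, 0]]))
        assert d.values[0, 1] == pytest.approx(1 / 2)

    def test_zero_overlap_flagged_undefined(self):
        d = ep.hamming_distances(
            make_matrix([[0, MISSING], [MISSING, 1]])
        )
        assert np.isnan(d.values[0, 1])
        assert d.undefined_pairs() == [("s0", "s1")]

    def test_symmetry_on_random_matrices(self, rng):
        calls = rng.integers(-1, 2, size=(20, 40)).astype(np.int8)
        d = ep.hamming_distances(make_matrix(calls))
        finite = np.nan_to_num(d.values, nan=-1.0)
        np.testing.assert_allclose(finite, finite.T)
        assert np.all(np.diag(d.values) == 0)


def newick_splits(newick: str) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each keyed by the side without the
    lexicographically first taxon."""
    tree = TreeNode.read([newick])
    tips = frozenset(t.name for t in tree.tips())
    anchor = min(tips)
    splits = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(side)
    return splits


def additive_distances(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tree.find(taxa[i]).distance(tree.find(taxa[j]))
    return d


class TestNeighborJoining:
    def test_recovers_quartet_split(self):
        # additive distances for ((A,B),(C,D)) with internal branch length 3
        d = np.array(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], float
        )
        nwk = ep.neighbor_joining(ep.DistanceMatrix(list("ABCD"), d))
        assert frozenset("AB") in newick_splits(nwk) or frozenset("CD") in newick_splits(nwk)

    def test_star_distances_accepted(self):
        d = np.ones((4, 4)) - np.eye(4)
        nwk = ep.neighbor_joining(ep.DistanceMatrix(list("ABCD"), d))
        assert set("ABCD") == {t.name for t in TreeNode.read([nwk]).tips()}

    def test_undefined_distances_rejected_with_pairs(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="s0"):
            ep.neighbor_joining(ep.DistanceMatrix([f"s{i}" for i in range(4)], d))

    def test_recovers_random_additive_topologies(self, rng):
        # random bifurcating trees up to 8 taxa: NJ must recover every split
        for trial in range(5):
            n = int(rng.integers(5, 9))
            taxa = [f"t{i}" for i in range(n)]
            nwk_true = _random_tree_newick(rng, taxa)
            true_tree = TreeNode.read([nwk_true])
            d = additive_distances(true_tree, taxa)
            nwk = ep.neighbor_joining(ep.DistanceMatrix(taxa, d))
            assert newick_splits(nwk) == newick_splits(nwk_true)

    def test_two_clade_cohort_deepest_split(self, rng):
        # two clades with disjoint defining variants, plus sample noise
        block = np.zeros((12, 20), dtype=np.int8)
        block[:6, :10] = 1
        noise = (rng.random(block.shape) < 0.03).astype(np.int8)
        matrix = make_matrix(np.clip(block + noise, 0, 1))
        nwk = ep.neighbor_joining(ep.hamming_distances(matrix))
        clade = frozenset(f"s{i}" for i in range(6))
        assert clade in newick_splits(nwk) or frozenset(
            f"s{i}" for i in range(6, 12)
        ) in newick_splits(nwk)


def fitch_bruteforce(newick: str, leaf_states: dict) -> int:
    """Exhaustive minimum changes over all internal-state assignments."""
    tree = TreeNode.read([newick])
    internals = list(tree.non_tips(include_self=True))
    states = sorted(set(leaf_states.values()))
    best = np.inf
    for combo in itertools.product(states, repeat=len(internals)):
        label = {id(node): s for node, s in zip(internals, combo)}
        changes = 0
        for node in tree.traverse(include_self=False):
            s = leaf_states[node.name] if node.is_tip() else label[id(node)]
            parent_s = label[id(node.parent)]
            changes += s != parent_s
        best = min(best, changes)
    return int(best)


class TestFitchParsimony:
    TREE = "((A,B),(C,D));"

    def test_single_change(self):
        score, _ = ep.fitch_parsimony_score(
            self.TREE, {"A": [0], "B": [0], "C": [1], "D": [1]}
        )
        assert score == 1

    def test_incompatible_pattern_needs_two(self):
        score, _ = ep.fitch_parsimony_score(
            self.TREE, {"A": [0], "B": [1], "C": [0], "D": [1]}
        )
        assert score == 2

    def test_constant_site_zero(self):
        score, _ = ep.fitch_parsimony_score(
            self.TREE, {"A": [0], "B": [0], "C": [0], "D": [0]}
        )
        assert score == 0

    def test_missing_leaf_state_skips_site(self):
        score, skipped = ep.fitch_parsimony_score(
            self.TREE, {"A": [0, 0], "B": [0, None], "C": [1, 1], "D": [1, 1]}
        )
        assert score == 1 and skipped == 1

    def test_matches_exhaustive_minimum(self, rng):
        for trial in range(8):
            n = int(rng.integers(4, 9))
            taxa = [chr(65 + i) for i in range(n)]
            nwk = _random_tree_newick(rng, taxa)
            states = {t: int(rng.integers(0, 3)) for t in taxa}
            score, _ = ep.fitch_parsimony_score(nwk, {t: [states[t]] for t in taxa})
            assert score == fitch_bruteforce(nwk, states)


def _random_tree_newick(rng, taxa):
    nodes = [f"{t}:{rng.uniform(0.5, 2.0):.3f}" for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.5, 2.0):.3f}")
    return f"({nodes[0]},{nodes[1]});"


class TestPCA:
    def test_two_clades_separate_on_pc1(self):
        calls = np.zeros((20, 30), dtype=np.int8)
        calls[:10, :15] = 1
        calls[:, 29] = np.tile([0, 1], 10)  # some orthogonal variation
        emb = ep.pca_embed(make_matrix(calls), k=3)
        pc1 = emb.coordinates[:, 0]
        assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()
        assert emb.explained_variance[0] > emb.explained_variance[1:].max()

    def test_explained_variance_sums_below_one(self, sim_cohort):
        _, _, matrix, _ = sim_cohort
        emb = ep.pca_embed(matrix.subset_samples(np.arange(100)), k=20)
        assert emb.explained_variance.sum() <= 1.0 + 1e-9

    def test_duplicated_samples_identical_coordinates(self, rng):
        calls = rng.integers(0, 2, size=(15, 25)).astype(np.int8)
        calls = np.vstack([calls, calls[:1]])
        emb = ep.pca_embed(make_matrix(calls), k=4)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[-1], atol=1e-9)

    def test_k_truncated_with_warning(self, rng):
        calls = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
        with pytest.warns(UserWarning, match="truncating"):
            emb = ep.pca_embed(make_matrix(calls), k=20)
        assert emb.coordinates.shape[1] <= 5


class TestUmap:
    @pytest.fixture(scope="class")
    def clustered_matrix(self):
        rng = np.random.default_rng(2024)
        n_per, n_groups, m = 50, 5, 60
        calls = np.zeros((n_per * n_groups, m), dtype=np.int8)
        for g in range(n_groups):
            calls[g * n_per : (g + 1) * n_per, g * 12 : (g + 1) * 12] = 1
        flip = rng.random(calls.shape) < 0.02
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
        labels = np.repeat(np.arange(n_groups), n_per)
        return make_matrix(calls), labels

    def test_deterministic_given_seed(self, clustered_matrix):
        matrix, _ = clustered_matrix
        a = ep.umap_embed(matrix, seed=1)
        b = ep.umap_embed(matrix, seed=1)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.coordinates.shape[1] == 2

    def test_clusters_recover_haplogroups(self, clustered_matrix):
        from sklearn.cluster import KMeans

        matrix, labels = clustered_matrix
        emb = ep.umap_embed(matrix, seed=1)
        km = KMeans(n_clusters=5, n_init=10, random_state=0).fit(emb.coordinates)
        assert ep.label_concordance(km.labels_, labels) >= 0.8

    def test_neighbor_clipping_warns(self, clustered_matrix):
        matrix, _ = clustered_matrix
        small = matrix.subset_samples(np.arange(40))
        with pytest.warns(UserWarning, match="clipping"):
            ep.umap_embed(small, n_neighbors=100, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ep.umap_embed(make_matrix([[0, 1], [1, 0]]))


class TestLabelConcordance:
    def test_identical_labelings(self):
        assert ep.label_concordance([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_single_cluster_not_positive(self):
        assert ep.label_concordance([0] * 10, [0, 1] * 5) <= 0.0

    def test_random_labels_near_zero(self, rng):
        a = rng.integers(0, 5, 1000)
        b = rng.integers(0, 5, 1000)
        assert abs(ep.label_concordance(a, b)) < 0.05

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ep.label_concordance([1, 2], [1, 2, 3])
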