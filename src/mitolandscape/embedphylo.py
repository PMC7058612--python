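"""Unsupervised sample classification: phylogeny, PCA, UMAP, concordance.

Distance-based neighbor joining on pairwise Hamming distances stands in for
a heuristic parsimony search; Fitch parsimony scoring on the resulting
topology keeps parsimony claims testable.  PCA and UMAP embed the haploid
genotype matrix directly, and the adjusted Rand index quantifies agreement
between embedding-derived clusters and haplogroup labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .iohap import MISSING, HaploidGenotypeMatrix


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN marks undefined pairs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        bad = np.argwhere(np.isnan(self.values))
        return [
            (self.sample_ids[i], self.sample_ids[j]) for i, j in bad if i < j
        ]


@dataclass
class Embedding:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n, k)
    explained_variance: np.ndarray | None = None  # PCA only


def hamming_distances(matrix: HaploidGenotypeMatrix) -> DistanceMatrix:
    """Pairwise fraction of discordant calls over jointly non-missing sites.

    Pairs with zero jointly observed sites are flagged NaN (undefined).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = matrix.calls
    obs = (calls != MISSING).astype(np.int32)
    c = np.where(calls == MISSING, 0, calls).astype(np.int32)
    # mismatches on jointly observed sites: xor restricted to joint support
    joint = obs @ obs.T
    agree11 = c @ c.T
    alt_counts = (c * obs).sum(axis=1)
    # mismatches = joint - (agreements): agreements = n00 + n11
    ones_joint = (c * obs) @ obs.T  # per pair: alt calls of i on joint support
    ones_joint_t = ones_joint.T
    n11 = agree11
    n_mismatch = ones_joint + ones_joint_t - 2 * n11
    del alt_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(joint > 0, n_mismatch / np.maximum(joint, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.sample_ids), d)


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Standard neighbor-joining agglomeration; returns a newick string."""
    if len(dist.sample_ids) < 4:
        raise ValueError("need at least four samples for an unrooted tree")
    bad = dist.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad[:10]}")
    dm = SkbioDistanceMatrix(dist.values, ids=dist.sample_ids)
    tree = nj(dm)
    return str(tree).strip()


def fitch_parsimony_score(
    newick: str, site_patterns: dict[str, list]
) -> tuple[int, int]:
    """Fitch minimum number of state changes summed over sites.

    ``site_patterns`` maps leaf name to its per-site state list; ``None``
    marks a missing state, and any site with a missing leaf state is skipped.
    Returns (total score, number of skipped sites).
    """
    tree = TreeNode.read([newick])
    leaves = [t.name for t in tree.tips()]
    for leaf in leaves:
        if leaf not in site_patterns:
            raise KeyError(f"no states for leaf {leaf!r}")
    n_sites = len(next(iter(site_patterns.values())))
    total = 0
    skipped = 0
    for s in range(n_sites):
        states = {leaf: site_patterns[leaf][s] for leaf in leaves}
        if any(v is None for v in states.values()):
            skipped += 1
            continue
        total += _fitch_one_site(tree, states)
    return total, skipped


def _fitch_one_site(tree: TreeNode, leaf_state: dict[str, object]) -> int:
    """Minimum state changes for one site (unit-cost dynamic program).

    Exact on arbitrary (including multifurcating, unrooted-style) topologies;
    an optimal internal labeling always uses observed states only.
    """
    states = sorted(set(leaf_state.values()), key=repr)
    index = {s: i for i, s in enumerate(states)}
    big = float("inf")

    def post(node: TreeNode) -> np.ndarray:
        if node.is_tip():
            cost = np.full(len(states), big)
            cost[index[leaf_state[node.name]]] = 0.0
            return cost
        cost = np.zeros(len(states))
        for child in node.children:
            child_cost = post(child)
            cost += np.minimum(child_cost, child_cost.min() + 1.0)
        return cost

    return int(post(tree).min())


def pca_embed(matrix: HaploidGenotypeMatrix, k: int = 20) -> Embedding:
    """Top-k principal components of the mean-centered haploid calls.

    Missing calls are mean-imputed per variant; zero-variance variants are
    dropped before decomposition.  When k exceeds the matrix rank the
    returned components are truncated with a warning.
    """
    x = matrix.calls.astype(float)
    x[matrix.calls == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    max_k = min(x.shape[0] - 1, x.shape[1])
    if k > max_k:
        warnings.warn(f"requested {k} components but rank allows {max_k}; truncating")
        k = max_k
    pca = PCA(n_components=k, random_state=0)
    coords = pca.fit_transform(x - x.mean(axis=0))
    return Embedding(list(matrix.sample_ids), coords, pca.explained_variance_ratio_)


def umap_embed(
    matrix: HaploidGenotypeMatrix,
    n_neighbors: int = 100,
    min_dist: float = 0.99,
    seed: int = 0,
) -> Embedding:
    """Two-component UMAP embedding of the haploid calls.

    Defaults (n_neighbors 100, min_dist 0.99) favour global topology over
    tight local clusters.  ``n_neighbors`` is clipped below the sample count
    with a warning; the seed fixes the layout for reproducibility.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least three samples for UMAP")
    import umap  # deferred: heavy import

    if n_neighbors >= matrix.n_samples:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_samples={matrix.n_samples}; clipping"
        )
        n_neighbors = matrix.n_samples - 1
    x = matrix.calls.astype(float)
    x[matrix.calls == MISSING] = 0.5
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(x)
    return Embedding(list(matrix.sample_ids), np.asarray(coords))


def label_concordance(cluster_labels, haplogroup_labels) -> float:
    """Adjusted Rand index between embedding clusters and haplogroup labels."""
    a = list(cluster_labels)
    b = list(haplogroup_labels)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    return float(adjusted_rand_score(a, b))
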