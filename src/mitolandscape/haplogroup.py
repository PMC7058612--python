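"""Haplogroup tree handling, sample assignment, and frequency spectra.

Haplogroups are hierarchically named clades of mitochondrial haplotypes
(e.g. "M", "M7", "M7a"): each character of the name adds one level of the
tree.  Every edge carries one or more defining variant alleles; a
back-mutation on an edge removes a previously acquired allele from the
expected set of all descendants.

Assignment scores a sample's observed variant set against each candidate
node's expected set with the symmetric Kulczynski similarity
``0.5 * (|O ∩ E|/|E| + |O ∩ E|/|O|)`` and returns the best-scoring node,
breaking ties by greater name depth and then lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iohap import HaploidGenotypeMatrix

Variant = tuple[int, str]  # (position, derived allele)


@dataclass(frozen=True)
class EdgeVariant:
    position: int
    allele: str
    back_mutation: bool = False

    @property
    def key(self) -> Variant:
        return (self.position, self.allele)

    def __str__(self) -> str:
        return f"{self.position}{self.allele}" + ("!" if self.back_mutation else "")


@dataclass
class Haplotree:
    """Rooted tree of named haplogroups with defining variants per edge."""

    root: str
    parent: dict[str, str] = field(default_factory=dict)  # child -> parent
    edge_variants: dict[str, list[EdgeVariant]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            node = par
            seen = {child}
            while node != self.root:
                if node in seen or node not in self.parent:
                    raise ValueError(f"tree is not a rooted acyclic hierarchy at {child!r}")
                seen.add(node)
                node = self.parent[node]

    @property
    def nodes(self) -> list[str]:
        return [self.root] + list(self.parent)

    def add_edge(self, parent: str, child: str, variants: list[EdgeVariant]) -> None:
        if child in self.parent:
            raise ValueError(f"node {child!r} already present")
        self.parent[child] = parent
        self.edge_variants[child] = list(variants)

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node]

    def leaves(self) -> list[str]:
        internal = set(self.parent.values())
        return [n for n in self.nodes if n not in internal]

    def path_from_root(self, node: str) -> list[str]:
        if node != self.root and node not in self.parent:
            raise KeyError(f"unknown haplogroup {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path[::-1]

    # -- TSV round trip: child, parent, comma-separated posALLELE[!] tokens --

    def to_tsv(self, path: str) -> None:
        rows = [
            {
                "child": c,
                "parent": p,
                "variants": ",".join(str(v) for v in self.edge_variants[c]),
            }
            for c, p in self.parent.items()
        ]
        pd.DataFrame(rows, columns=["child", "parent", "variants"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str, root: str | None = None) -> "Haplotree":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        children = set(df["child"])
        roots = set(df["parent"]) - children
        if root is None:
            if len(roots) != 1:
                raise ValueError(f"ambiguous root candidates: {sorted(roots)}")
            root = roots.pop()
        tree = cls(root=root)
        for row in df.itertuples():
            variants = []
            for tok in str(row.variants).split(","):
                tok = tok.strip()
                if not tok:
                    continue
                back = tok.endswith("!")
                tok = tok.rstrip("!")
                pos = int("".join(ch for ch in tok if ch.isdigit()))
                allele = "".join(ch for ch in tok if not ch.isdigit())
                variants.append(EdgeVariant(pos, allele, back))
            tree.add_edge(str(row.parent), str(row.child), variants)
        return tree


def expected_variants(tree: Haplotree, node: str) -> set[Variant]:
    """Union of defining variants on the root-to-node path.

    A back-mutation removes its target allele from the accumulated set.
    """
    expected: set[Variant] = set()
    for step in tree.path_from_root(node)[1:]:
        for ev in tree.edge_variants[step]:
            if ev.back_mutation:
                expected.discard(ev.key)
            else:
                expected.add(ev.key)
    return expected


def kulczynski_score(observed: set[Variant], expected: set[Variant]) -> float:
    """Symmetric Kulczynski similarity between observed and expected sets."""
    if not expected:
        raise ValueError("expected set must be non-empty")
    if not observed:
        return 0.0
    shared = len(observed & expected)
    return 0.5 * (shared / len(expected) + shared / len(observed))


@dataclass(frozen=True)
class HaplogroupAssignment:
    sample_id: str
    best_node: str
    score: float
    runner_up_score: float


def assign_haplogroup(
    tree: Haplotree, sample: set[Variant], sample_id: str = ""
) -> HaplogroupAssignment:
    """Assign the best-scoring haplogroup for one sample's variant set.

    Ties are broken by greater name depth, then lexicographic order;
    the root (empty expected set) is never a candidate.
    """
    candidates = [n for n in tree.nodes if n != tree.root]
    if not candidates:
        raise ValueError("tree has no non-root nodes")
    scored = []
    for node in candidates:
        exp = expected_variants(tree, node)
        if not exp:
            continue
        scored.append((kulczynski_score(sample, exp), len(node), node))
    # max score; ties -> deeper name; then lexicographically smaller name
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best = scored[0]
    runner = scored[1][0] if len(scored) > 1 else 0.0
    return HaplogroupAssignment(sample_id, best[2], best[0], runner)


def matrix_variant_sets(matrix: HaploidGenotypeMatrix) -> list[set[Variant]]:
    """Per-sample sets of carried (position, alt allele) pairs."""
    sets: list[set[Variant]] = []
    keys = [(v.position, v.alt_allele) for v in matrix.variants]
    for i in range(matrix.n_samples):
        carried = np.flatnonzero(matrix.calls[i] == 1)
        sets.append({keys[j] for j in carried})
    return sets


def assign_cohort(tree: Haplotree, matrix: HaploidGenotypeMatrix) -> list[HaplogroupAssignment]:
    return [
        assign_haplogroup(tree, s, sid)
        for s, sid in zip(matrix_variant_sets(matrix), matrix.sample_ids)
    ]


def truncate_haplogroup(name: str, depth: int) -> str:
    """First ``depth`` characters of a haplogroup name ("D4b2", 3 -> "D4b")."""
    if not name:
        raise ValueError("haplogroup name must be non-empty")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return name[:depth]


def haplogroup_spectrum(
    assignments: list[HaplogroupAssignment] | list[str],
    strata: dict[str, str] | None,
    depth: int,
) -> pd.DataFrame:
    """Per-stratum relative frequencies of depth-truncated haplogroup names.

    Rows are strata and sum to 1.  ``strata`` maps sample_id to stratum;
    with ``None`` all samples form a single "all" stratum.
    """
    if assignments and isinstance(assignments[0], HaplogroupAssignment):
        pairs = [(a.sample_id, a.best_node) for a in assignments]  # type: ignore[union-attr]
    else:
        pairs = [(str(i), n) for i, n in enumerate(assignments)]  # type: ignore[arg-type]
    rows = []
    for sid, name in pairs:
        stratum = "all" if strata is None else strata.get(sid)
        if stratum is None:
            raise KeyError(f"sample {sid!r} has no stratum")
        rows.append((stratum, truncate_haplogroup(name, depth)))
    df = pd.DataFrame(rows, columns=["stratum", "haplogroup"])
    table = pd.crosstab(df["stratum"], df["haplogroup"])
    return table.div(table.sum(axis=1), axis=0)


def distinct_name_counts(
    assignments: list[HaplogroupAssignment] | list[str], max_depth: int = 9
) -> pd.Series:
    """Cumulative distinct truncated-name counts at depths 1..max_depth."""
    if assignments and isinstance(assignments[0], HaplogroupAssignment):
        names = [a.best_node for a in assignments]  # type: ignore[union-attr]
    else:
        names = list(assignments)  # type: ignore[arg-type]
    counts = {
        d: len({truncate_haplogroup(n, d) for n in names}) for d in range(1, max_depth + 1)
    }
    return pd.Series(counts, name="n_haplogroups")
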