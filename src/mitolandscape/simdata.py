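"""Synthetic cohorts with the statistical structure of mitochondrial WGS data.

The generators emulate, at desk scale, the features the downstream analyses
rely on:

* non-recombining mtDNA haplotypes descending from a hierarchical haplogroup
  tree, with a hypermutable control region (D-loop) and transition-biased
  substitutions;
* regionally heterogeneous haplogroup frequencies across geographic strata;
* recombining phased nuclear haplotypes whose linkage disequilibrium decays
  with physical distance (founder-copying process with crossovers);
* per-sample sequencing-depth pairs encoding a true mtDNA copy number;
* quantitative and binary phenotypes with covariates and optional injected
  mtDNA-variant effects.

A single global seed fans out into fixed per-component substreams, so adding
one generator never perturbs the output of another.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplogroup import EdgeVariant, Haplotree, expected_variants
from .iohap import (
    MT_LENGTH,
    HaploidGenotypeMatrix,
    HaplotypePanel,
    VariantRecord,
    d_loop_annotation,
)

# fixed substream ids: reference sequence, tree, cohort, nuclear, depth/pheno
_STREAMS = {"refseq": 0, "tree": 1, "cohort": 2, "nuclear": 3, "phenotype": 4}

_BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
# transition fraction matching the strongly transition-biased mtDNA spectrum
_DEFAULT_TI_FRACTION = 16.44 / 17.44

_MACRO_LETTERS = "MNDABFGZ"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale of a deep-WGS national-cohort study: ~2000
    samples, the 16,569 bp circular mitochondrial genome, seven geographic
    regions, and a hierarchical haplogroup tree.
    """

    n_samples: int = 2000
    mt_length: int = MT_LENGTH
    n_regions: int = 7
    haplotree_depth: int = 4
    branching: int = 2
    n_macro: int = 4
    max_defining_per_edge: int = 3
    mutation_rate: float = 1e-4  # private substitutions, per site per sample
    dloop_rate_multiplier: float = 5.0
    back_mutation_rate: float = 0.0  # per edge, default off
    ti_fraction: float = _DEFAULT_TI_FRACTION
    # nuclear panel
    n_nuclear_variants: int = 300
    nuclear_length: int = 500_000
    n_founders: int = 12
    recomb_rate: float = 1e-4  # per-bp crossover probability
    # depth model
    n_autosomes: int = 22
    autosomal_depth_mean: float = 30.0
    autosomal_depth_sd: float = 2.0
    chrom_depth_jitter_sd: float = 0.5
    depth_noise_sigma: float = 0.05
    mtcn_median: float = 100.0
    mtcn_log_sd: float = 0.2
    # phenotypes
    n_quant_traits: int = 2
    n_binary_traits: int = 2
    n_pcs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.haplotree_depth <= 9:
            raise ValueError("haplotree_depth must lie in 1..9")
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if self.n_samples < 1 or self.n_nuclear_variants < 0:
            raise ValueError("counts must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.dloop_rate_multiplier < 1:
            raise ValueError("dloop_rate_multiplier must be >= 1")
        if min(self.autosomal_depth_mean, self.depth_noise_sigma, self.mtcn_median) < 0:
            raise ValueError("depth parameters must be non-negative")

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[component]])
        )


@dataclass
class SimTruth:
    """Ground truth recorded alongside the generated data."""

    haplogroups: list[str] = field(default_factory=list)  # per-sample true leaf
    regions: list[str] = field(default_factory=list)
    region_freqs: pd.DataFrame | None = None  # region x leaf, rows sum to 1
    true_mtcn: np.ndarray | None = None
    injected_effects: list[tuple[str, float]] = field(default_factory=list)


def reference_sequence(config: SimConfig) -> np.ndarray:
    """Deterministic synthetic reference base per position (index 0 = pos 1)."""
    rng = config.rng("refseq")
    return _BASES[rng.integers(0, 4, size=config.mt_length)]


def _mutate(rng: np.random.Generator, ref_base: str, ti_fraction: float) -> str:
    """Draw a derived allele with a transition-biased substitution model."""
    if rng.random() < ti_fraction:
        return _TRANSITION_PARTNER[ref_base]
    choices = [b for b in "ACGT" if b != ref_base and b != _TRANSITION_PARTNER[ref_base]]
    return choices[rng.integers(0, len(choices))]


def _child_char(level: int, index: int) -> str:
    """Alternating letter/digit naming: level 2 digits, level 3 letters, ..."""
    if level % 2 == 0:
        return str(index + 1)
    return string.ascii_lowercase[index]


def simulate_haplotree(config: SimConfig) -> Haplotree:
    """Generate a rooted haplogroup tree with defining variants per edge.

    Node names follow the alternating letter/digit scheme (M, M7, M7a, ...);
    defining variant positions are globally unique unless a back-mutation is
    explicitly flagged.
    """
    rng = config.rng("tree")
    refseq = reference_sequence(config)
    pool = rng.permutation(config.mt_length) + 1  # 1-based position pool
    pool_iter = iter(pool.tolist())
    tree = Haplotree(root="ROOT")

    def draw_variants(n: int) -> list[EdgeVariant]:
        out = []
        for _ in range(n):
            pos = next(pool_iter)
            ref = refseq[pos - 1]
            out.append(EdgeVariant(pos, _mutate(rng, ref, config.ti_fraction)))
        return out

    macros = [_MACRO_LETTERS[i] for i in range(config.n_macro)]
    frontier = []
    for name in macros:
        tree.add_edge("ROOT", name, draw_variants(int(rng.integers(1, config.max_defining_per_edge + 1))))
        frontier.append(name)
    for level in range(2, config.haplotree_depth + 1):
        next_frontier = []
        for parent in frontier:
            for k in range(config.branching):
                child = parent + _child_char(level, k)
                variants = draw_variants(int(rng.integers(1, config.max_defining_per_edge + 1)))
                if config.back_mutation_rate > 0 and rng.random() < config.back_mutation_rate:
                    ancestral = sorted(expected_variants(tree, parent))
                    if ancestral:
                        pos, allele = ancestral[rng.integers(0, len(ancestral))]
                        variants.append(EdgeVariant(pos, allele, back_mutation=True))
                tree.add_edge(parent, child, variants)
                next_frontier.append(child)
        frontier = next_frontier
    return tree


def _region_names(config: SimConfig) -> list[str]:
    return [f"region_{i + 1}" for i in range(config.n_regions)]


def simulate_mt_cohort(
    tree: Haplotree,
    config: SimConfig,
    region_freqs: pd.DataFrame | None = None,
) -> tuple[HaploidGenotypeMatrix, SimTruth]:
    """Draw a non-recombining mtDNA cohort from region-specific haplogroups.

    Each sample's haplotype is the defining-variant union along the root
    path of its true (leaf) haplogroup, plus private substitutions at
    ``mutation_rate`` per site — inflated by ``dloop_rate_multiplier``
    inside the control region.  There is no recombination anywhere.
    """
    rng = config.rng("cohort")
    refseq = reference_sequence(config)
    leaves = sorted(tree.leaves())
    regions = _region_names(config)
    if region_freqs is None:
        freqs = rng.dirichlet(np.full(len(leaves), 0.5), size=config.n_regions)
        region_freqs = pd.DataFrame(freqs, index=regions, columns=leaves)
    else:
        regions = list(region_freqs.index)
        leaves = list(region_freqs.columns)

    dloop = d_loop_annotation(config.mt_length)
    all_pos = np.arange(1, config.mt_length + 1)
    in_dloop = np.asarray(dloop.contains(all_pos))
    dloop_pos = all_pos[in_dloop]
    other_pos = all_pos[~in_dloop]
    p_dloop = min(config.mutation_rate * config.dloop_rate_multiplier, 1.0)
    p_other = config.mutation_rate

    leaf_expected = {leaf: expected_variants(tree, leaf) for leaf in leaves}
    sample_regions = [regions[i] for i in rng.integers(0, len(regions), config.n_samples)]
    truth = SimTruth(regions=sample_regions, region_freqs=region_freqs)

    sample_sets: list[set[tuple[int, str]]] = []
    for region in sample_regions:
        leaf = rng.choice(leaves, p=region_freqs.loc[region].to_numpy())
        truth.haplogroups.append(str(leaf))
        carried = set(leaf_expected[str(leaf)])
        defined_pos = {p for p, _ in carried}
        for pos_pool, p_mut in ((dloop_pos, p_dloop), (other_pos, p_other)):
            k = rng.binomial(len(pos_pool), p_mut)
            if k:
                for pos in rng.choice(pos_pool, size=k, replace=False):
                    if int(pos) in defined_pos:
                        continue
                    carried.add((int(pos), _mutate(rng, refseq[pos - 1], config.ti_fraction)))
        sample_sets.append(carried)

    columns = sorted(set().union(*sample_sets)) if sample_sets else []
    col_index = {key: j for j, key in enumerate(columns)}
    calls = np.zeros((config.n_samples, len(columns)), dtype=np.int8)
    for i, carried in enumerate(sample_sets):
        for key in carried:
            calls[i, col_index[key]] = 1
    variants = [
        VariantRecord("MT", pos, str(refseq[pos - 1]), allele) for pos, allele in columns
    ]
    sample_ids = [f"sample_{i:05d}" for i in range(config.n_samples)]
    return HaploidGenotypeMatrix(sample_ids, variants, calls), truth


def simulate_nuclear_panel(config: SimConfig) -> HaplotypePanel:
    """Phased nuclear haplotypes from a founder-copying process with crossovers.

    2N haplotypes are mosaics of ``n_founders`` founder haplotypes; between
    adjacent variants the copied founder switches with probability
    ``1 - exp(-recomb_rate * distance)``, producing distance-dependent LD
    decay in expectation.  ``recomb_rate`` 0 yields exact founder copies.
    """
    if config.n_nuclear_variants < 2:
        raise ValueError("n_nuclear_variants must be >= 2")
    rng = config.rng("nuclear")
    positions = np.sort(
        rng.choice(np.arange(1, config.nuclear_length + 1), size=config.n_nuclear_variants, replace=False)
    )
    freqs = rng.uniform(0.05, 0.5, size=config.n_nuclear_variants)
    founders = (rng.random((config.n_founders, config.n_nuclear_variants)) < freqs).astype(np.int8)

    n_hap = 2 * config.n_samples
    gaps = np.diff(positions)
    p_switch = 1.0 - np.exp(-config.recomb_rate * gaps)
    states = np.empty((n_hap, config.n_nuclear_variants), dtype=np.int64)
    states[:, 0] = rng.integers(0, config.n_founders, size=n_hap)
    switches = rng.random((n_hap, gaps.size)) < p_switch
    new_states = rng.integers(0, config.n_founders, size=(n_hap, gaps.size))
    for j in range(1, config.n_nuclear_variants):
        states[:, j] = np.where(switches[:, j - 1], new_states[:, j - 1], states[:, j - 1])
    haplotypes = founders[states, np.arange(config.n_nuclear_variants)]
    return HaplotypePanel(haplotypes=haplotypes, positions=positions, contig="1")


def simulate_depths_and_phenotypes(
    truth: SimTruth,
    config: SimConfig,
    genotype_matrix: HaploidGenotypeMatrix | None = None,
    injected_effects: list[tuple[int, float]] | None = None,
    injected_binary_effects: list[tuple[int, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample depth summaries and phenotype/covariate tables.

    Depth model: per-sample mean mtDNA depth = true_mtCN / 2 x mean
    autosomal depth x lognormal noise (sigma ``depth_noise_sigma``).
    Quantitative phenotypes are covariate effects + injected variant effect
    beta x allele + standard Gaussian noise; binary phenotypes come from a
    logistic model (injected effects on the log-odds scale).

    ``injected_effects`` lists (variant column index, beta) applied to every
    quantitative trait; ``injected_binary_effects`` the analogue for binary
    traits.  True mtCN values are drawn here and recorded on ``truth``.
    """
    if not truth.regions:
        raise ValueError("truth must be populated by simulate_mt_cohort first")
    rng = config.rng("phenotype")
    n = len(truth.regions)

    # --- depths ---
    true_mtcn = config.mtcn_median * np.exp(rng.normal(0.0, config.mtcn_log_sd, n))
    truth.true_mtcn = true_mtcn
    base_depth = np.maximum(rng.normal(config.autosomal_depth_mean, config.autosomal_depth_sd, n), 1.0)
    chrom_depth = np.maximum(
        base_depth[:, None] + rng.normal(0.0, config.chrom_depth_jitter_sd, (n, config.n_autosomes)),
        0.5,
    )
    noise = np.exp(rng.normal(0.0, config.depth_noise_sigma, n)) if config.depth_noise_sigma > 0 else 1.0
    mt_depth = true_mtcn / 2.0 * chrom_depth.mean(axis=1) * noise
    sample_ids = (
        genotype_matrix.sample_ids
        if genotype_matrix is not None
        else [f"sample_{i:05d}" for i in range(n)]
    )
    depth = pd.DataFrame({"sample_id": sample_ids, "mt_depth": mt_depth})
    for c in range(config.n_autosomes):
        depth[f"depth_chr{c + 1}"] = chrom_depth[:, c]

    # --- covariates ---
    age = rng.normal(60.0, 10.0, n)
    sex = rng.integers(0, 2, n)
    platform = rng.integers(0, 2, n)
    pcs = rng.normal(0.0, 1.0, (n, config.n_pcs))
    region = pd.Categorical(truth.regions)
    region_shift = rng.normal(0.0, 0.1, len(region.categories))

    pheno = pd.DataFrame({"sample_id": sample_ids, "age": age, "sex": sex,
                          "region": truth.regions, "platform": platform})
    for k in range(config.n_pcs):
        pheno[f"PC{k + 1}"] = pcs[:, k]

    dose = None
    if genotype_matrix is not None:
        dose = genotype_matrix.calls.astype(float)

    base_linear = 0.01 * (age - 60.0) + 0.2 * sex + region_shift[region.codes]
    for t in range(config.n_quant_traits):
        y = base_linear + rng.normal(0.0, 1.0, n)
        if injected_effects and dose is not None:
            for col, beta in injected_effects:
                y = y + beta * dose[:, col]
                truth.injected_effects.append((f"quant_{t + 1}:col{col}", beta))
        pheno[f"quant_{t + 1}"] = y
    for t in range(config.n_binary_traits):
        logit = -2.0 + 0.02 * (age - 60.0) + 0.1 * sex + region_shift[region.codes]
        if injected_binary_effects and dose is not None:
            for col, beta in injected_binary_effects:
                logit = logit + beta * dose[:, col]
                truth.injected_effects.append((f"disease_{t + 1}:col{col}", beta))
        prob = 1.0 / (1.0 + np.exp(-logit))
        pheno[f"disease_{t + 1}"] = (rng.random(n) < prob).astype(int)
    return depth, pheno
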