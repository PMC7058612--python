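# Methods

This note documents the models behind each analysis stage, the synthetic
cohort the tests run on, the numerical choices, and the limitations of
both.

## Data model

Mitochondrial genotypes are haploid calls in {0, 1, missing} on the
16,569 bp circular rCRS coordinate system. Heterozygous-style calls on the
mitochondrial contig (heteroplasmy-like) are set to missing on input: the
analyses address homoplasmic alleles only. Multiallelic sites are split
into biallelic records sharing a position; a sample carrying a different
alternative allele is coded 0 for the record under consideration, and
downstream LD and association stages operate on biallelic records only.
Frequency computations use pairwise-complete observations. The D-loop
(control region) is taken as rCRS 16,024–16,569 plus 1–576, with
membership tests that respect the origin wrap-around.

## Haplogroup assignment

A haplotree is a rooted hierarchy of named clades; each edge carries
defining variant alleles, and a back-mutation flag removes a previously
acquired allele from every descendant's expected set. A sample's observed
variant set *O* is scored against each node's expected set *E* with the
symmetric Kulczynski similarity ½(|O∩E|/|E| + |O∩E|/|O|); the best-scoring
node wins, with ties resolved toward greater name depth and then
lexicographic order. The similarity is unweighted: per-variant weighting
schemes used by interactive haplogroup callers are deliberately not
reproduced, because an unweighted set similarity preserves the decision
structure while remaining fully testable (a sample matching a leaf's
expected set exactly always scores 1 there and strictly less at every
ancestor). No hotspot positions are masked by default; an exclusion list
can be supplied. Name depth counts characters including digits, so "D4" is
depth 2 and "D4b" depth 3.

## Unsupervised classification

Sample trees are built by neighbor joining on pairwise Hamming distances
(fraction of discordant calls over jointly observed sites; pairs with no
joint support are flagged undefined and refuse tree construction). NJ
replaces a heuristic parsimony search: it is deterministic, fast at desk
scale, and serves the same downstream purpose (lineage visualization).
Parsimony itself is retained as a scoring function: the per-site minimum
number of state changes on a fixed topology is computed by a unit-cost
dynamic program that is exact for arbitrary (including multifurcating)
trees, verified in tests against exhaustive enumeration of internal
labelings on trees of up to 8 leaves.

PCA mean-imputes missing calls per variant, drops zero-variance variants,
and reports explained-variance ratios for the top 20 components by
default. UMAP runs with n_neighbors = 100 and min_dist = 0.99 (global
topology favored over tight local clusters) and a fixed seed; n_neighbors
is clipped below the sample count with a warning. UMAP internals are
treated as an external library call: only determinism and
clustering-quality properties are part of the test surface. Agreement
between embedding-derived clusters and haplogroup labels is quantified by
the adjusted Rand index.

## Haploid LD

For two variants with alternative-allele frequencies p_x, p_y and joint
haplotype frequency p₁₁ over jointly non-missing samples, D = p₁₁ − p_x
p_y, r² = D²/(p_x(1−p_x)p_y(1−p_y)), and |D′| = |D|/D_max with D_max =
min(p_x(1−p_y), (1−p_x)p_y) for D > 0 and min(p_x p_y, (1−p_x)(1−p_y))
otherwise. Monomorphic inputs yield NaN (an explicit undefined signal) and
are excluded from tables. Nuclear r² is computed on phased haplotypes (2N
gametes). The nuclear comparison samples random common-variant pairs
(MAF ≥ 5 %) within ±8.3 kbp, matching the mitochondrial pair-distance
range; decay is the Pearson correlation of distance with r². Distances
between mtDNA variants use the linear coordinate difference, the
conventional choice; circularity enters only through region membership and
spanning-haplotype extent.

Tag counts are, per common variant, the number of other common variants
with r² ≥ 0.5 (nuclear search restricted to ±5 Mbp; mtDNA unrestricted).
Spanning haplotypes are connected components of the r² ≥ 0.8 graph over
common variants whose positional extent (max − min position) reaches 90 %
of the molecule length; both thresholds are configurable. Because extent
is a coordinate span, a tight cluster of variants that happens to straddle
the origin would overstate its extent — a known limitation, acceptable
because spanning sets are by construction spread across the molecule.
Enrichment of untagged variants in the D-loop is a two-sided Fisher exact
test on the 2×2 of (untagged?) × (in region?).

## Copy number and genome scans

mtCN is estimated per sample as (mean mtDNA depth / mean autosomal depth
of chromosome c) × 2, averaged over autosomes; zero-depth chromosomes are
excluded with a warning. The estimate is scale-invariant in overall
sequencing depth.

The mtDNA–nDNA scan fits, per (mtDNA variant, nuclear variant) pair, a
logistic regression with the haploid mtDNA allele as binary response and
the nuclear dosage plus covariates as predictors — the orientation follows
the study design wording (nuclear variants as explanatory variables).
Separated or non-converged fits are flagged and reported with missing p
rather than dropped; Firth correction is out of scope. The mtCN–nDNA scan
is an ordinary linear regression. Manhattan summaries take the
per-nuclear-variant minimum p across mtDNA variants. Bonferroni thresholds
are base_alpha divided by the product of test counts; the genomic
inflation λ is the median of the implied χ²₁ statistics divided by the
χ²₁ median (≈0.4549).

## Imputation

The imputer is a haploid Li–Stephens-style copying HMM. The hidden state
at each panel site is the reference haplotype being copied; between
adjacent panel sites the state switches to a uniformly drawn haplotype
with probability `switch_rate` (default 10⁻⁸ — effectively zero, encoding
the absence of recombination in mtDNA), and typed target alleles mismatch
the copied allele with probability `error_rate` (default 10⁻³). Typed
sites emit; untyped sites are silent, and their dose is the
posterior-weighted mean of reference alleles. Posteriors come from a
scaled forward–backward pass, verified against explicit path enumeration
on small panels. Typed calls pass through unchanged (dose equal to the
call, info 1).

The info score is the haploid analogue of the standard imputation-quality
metric: 1 − mean d(1−d) / (p̂(1−p̂)) over per-sample doses d with mean p̂;
it is 1 for hard calls, 0 for doses carrying no information beyond the
frequency, and undefined (variant dropped) when p̂ ∈ {0, 1}. Hard calls
threshold doses at 0.5 with ties going to the reference allele.
Post-imputation filtering keeps variants with estimated MAF ≥ 0.5 % and
info ≥ 0.7.

Masking cross-validation hides a fraction (default 50 %) of all panel
calls uniformly at random, re-imputes each sample with itself removed from
the reference (leaving the sample in would make recovery trivial), and
reports overall concordance plus minor-allele concordance per MAF bin
(0–5, 5–10, 10–20, 20–30, 30–40, 40–50 %), where minor-allele concordance
is restricted to masked calls whose true allele is the variant's minor
allele. For cohort-scale validation the reference panel is built from
cohort variants with MAF ≥ 0.5 %: singleton private-mutation columns are
uninformative for a copying model and would dominate the site grid without
affecting what the cross-validation measures.

## PheWAS

Binary traits: logistic regression of case status on dosage with age,
sex, top-20 PCs, geographic region and genotyping platform as covariates;
all samples not affected by the trait under scope are controls; traits
without both cases and controls are skipped with a warning. Quantitative
traits: residuals from an OLS regression on age, sex, PCs and any
trait-specific covariates are rank-transformed by the Blom inverse-normal
(r − 3/8)/(n + ¼) with average ranks for ties, then regressed on dosage
with region and platform additionally included. Dosages (not hard calls)
enter the regressions. The transform makes quantitative results invariant
under any monotone transformation of the raw phenotype. Significance is
flagged at two tiers: study-wide 0.05/(V·P) and variant-wide 0.05/V, both
strict inequalities.

Array-genotype QC applies, in order: sample call rate ≥ 0.9, variant call
rate ≥ 0.99, and concordance ≥ 0.99 with reference (WGS) calls on an
overlap sample set, with per-filter removal counts reported; without an
overlap set the concordance filter is skipped with a warning.

## Synthetic cohorts

The generator draws, from one global seed fanned into fixed per-component
substreams (so adding a generator never perturbs another's output):

* **Haplotree** — alternating letter/digit names (M, M7, M7a, …), default
  depth 4 and branching 2 over 4 macrohaplogroups, 1–3 defining variants
  per edge at globally unique positions, optional back-mutations (off by
  default). Substitutions are transition-biased at the empirical
  mitochondrial Ti fraction (Ti/Tv ≈ 16), so the simulated variant list
  reproduces a strongly transition-dominated spectrum.
* **mtDNA cohort** — default 2000 samples across 7 geographic regions
  (Dirichlet-distributed leaf frequencies per region, rows summing to 1);
  each sample's haplotype is the defining-variant union along its leaf's
  root path plus private substitutions at 10⁻⁴ per site (×5 in the
  D-loop). No recombination anywhere, by construction.
* **Nuclear panel** — 2N phased haplotypes copied from 12 founder
  haplotypes (site frequencies ~U(0.05, 0.5)) with crossovers at 10⁻⁴ per
  bp over a 500 kb region with 300 variants. The crossover rate is far
  above the physical per-generation rate because the founder-copying
  process compresses a population's recombination history into a single
  copying generation; what matters for the analyses is that r² decays with
  distance on the ±8.3 kbp matching scale, which it does.
* **Depths and phenotypes** — true mtCN is lognormal (median 100, log-sd
  0.2); per-chromosome autosomal depths center on 30× and the
  mitochondrial mean depth is mtCN/2 × mean autosomal depth × lognormal
  noise (σ = 0.05). Quantitative phenotypes are covariate effects plus
  optional injected variant effects plus unit Gaussian noise; binary
  phenotypes follow a logistic model at ~12 % baseline prevalence.
  Covariates include age, sex, region, platform and 20 synthetic PCs.

What the generator does **not** emulate: heteroplasmy and its read-level
evidence, nuMT contamination, coalescent-exact genealogies, selection,
sequencing batch artifacts beyond a platform label, and realistic trait
covariance structure. Passing tests therefore demonstrate the correctness
and calibration of the algorithms under the stated generative assumptions,
not the reproduction of any real cohort's numerical results — real-data
quantities (variant counts, exact LD fractions, biobank association
p-values) live on restricted data and are outside this package's reach.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen to make the measured
properties stable: cohorts of 300–2000 samples, 10,000-test null scans for
calibration (λ within 1.00 ± 0.05), 20-seed replication for the
no-decay property of mtDNA, and 2000-haplotype panels for imputation
cross-validation. Forward–backward is scaled per site to avoid underflow;
posterior rows are renormalized and asserted to sum to 1. Degenerate
inputs signal explicitly (NaN for undefined LD or info values, errors for
empty margins, constant phenotypes, all-zero depths) rather than
propagating silently.
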