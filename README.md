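# mitolandscape

Characterization of the mitochondrial genome at cohort scale: variant
spectra, haplogroup assignment, unsupervised sample classification, haploid
linkage disequilibrium, mtDNA copy-number estimation with genome-wide
association scans, haplotype-copying imputation, and a mitochondrial
phenome-wide association study (PheWAS).

The package is aimed at statistical geneticists working with haploid
mitochondrial genotypes called from whole-genome sequencing (WGS) and with
biobank-scale array/phenotype data. Because real mtDNA cohorts are usually
access-restricted, a first-class synthetic-data module generates cohorts
with the statistical structure the analyses assume (tree-structured
non-recombining haplotypes, hypermutable control region, regional
haplogroup heterogeneity, recombining nuclear haplotypes, depth-encoded
copy number, phenotypes with covariates), so every stage is testable
end to end.

## What it computes

* **Variant spectra** — MAF bins (rare < 0.5 %, low-frequency 0.5–5 %,
  common ≥ 5 %), transition/transversion (Ti/Tv) ratio, region membership
  on the circular rCRS coordinate system (D-loop = 16,024–16,569 ∪ 1–576).
* **Haplogroups** — a sample with observed variant set *O* is assigned to
  the haplotree node with expected set *E* maximizing the symmetric
  Kulczynski similarity
  ½ (|O∩E|/|E| + |O∩E|/|O|),
  with ties broken by name depth; spectra are tabulated per geographic
  stratum and name-truncation depth (1–9 letters).
* **Unsupervised classification** — neighbor joining on pairwise Hamming
  distances with exact Fitch parsimony scoring; PCA (top-20 components);
  UMAP (n_neighbors = 100, min_dist = 0.99); adjusted Rand concordance
  with haplogroup labels.
* **Haploid LD** — r² = D²/(p_x q_x p_y q_y) and |D′| = |D|/D_max on
  haplotypes; distance-matched nuclear pair sampling (±8.3 kbp); Pearson
  distance-vs-r² decay; tag counts (r² ≥ 0.5, nuclear window ±5 Mbp);
  spanning haplotypes (connected components of the r² ≥ 0.8 graph covering
  ≥ 90 % of the molecule); Fisher enrichment of untagged variants in the
  D-loop.
* **Copy number** — mtCN = (mean mtDNA depth / mean autosomal depth) × 2,
  averaged over autosomes; logistic mtDNA–nDNA and linear mtCN–nDNA
  genome-wide scans with covariates, gene-window subsetting (±10 kbp) and
  Bonferroni thresholds (e.g. 5.0 × 10⁻⁸/86 = 5.8 × 10⁻¹⁰); QQ tables with
  genomic inflation λ.
* **Imputation** — a haploid Li–Stephens-style copying HMM
  (forward–backward over reference haplotypes, switch rate ≈ 0 for the
  non-recombining mtDNA, emission error rate 10⁻³), IMPUTE-style info
  scores, post-imputation filters (MAF ≥ 0.5 %, info ≥ 0.7), and 50 %
  masking cross-validation with per-MAF-bin minor-allele concordance.
* **PheWAS** — logistic regression for binary traits; linear regression on
  rank-based inverse-normal residuals (Blom offset (r − 3/8)/(n + ¼)) for
  quantitative traits; age, sex, top-20 PCs, region and platform
  covariates; study-wide 0.05/(V·P) and variant-wide 0.05/V flags.

## Worked example

```python
import numpy as np
from mitolandscape import simdata, haplogroup, ldstruct, impute, mtcn

config = simdata.SimConfig(seed=1, n_samples=1000)
tree = simdata.simulate_haplotree(config)
matrix, truth = simdata.simulate_mt_cohort(tree, config)

assignments = haplogroup.assign_cohort(tree, matrix)
accuracy = np.mean([a.best_node == t for a, t in zip(assignments, truth.haplogroups)])
print(f"haplogroup recovery: {accuracy:.1%}")

pairs = ldstruct.mt_pair_table(matrix)
decay = ldstruct.ld_decay_correlation(pairs)
print(f"mtDNA LD decay: R = {decay.pearson_r:.3f}, p = {decay.p_value:.2f}")

panel_nuc = simdata.simulate_nuclear_panel(config)
nuc = ldstruct.ld_decay_correlation(
    ldstruct.matched_nuclear_pairs(panel_nuc, max_distance=8300, n_pairs=2000, seed=2)
)
print(f"nuclear LD decay: R = {nuc.pearson_r:.3f}, p = {nuc.p_value:.1e}")

panel = impute.ReferencePanel.from_matrix(matrix, maf_min=0.005)
cv = impute.cross_validate(panel, mask_fraction=0.5, seed=3)
print(f"imputation concordance (50% masked): {cv.overall_concordance:.1%}")

depth, _ = simdata.simulate_depths_and_phenotypes(truth, config, matrix)
est = mtcn.mtcn_from_table(depth)
err = np.median(np.abs(est.to_numpy() / truth.true_mtcn - 1))
print(f"median mtCN recovery error: {err:.1%}")
```

Output:

```
haplogroup recovery: 100.0%
mtDNA LD decay: R = -0.029, p = 0.23
nuclear LD decay: R = -0.300, p = 3.5e-27
imputation concordance (50% masked): 99.8%
median mtCN recovery error: 3.5%
```

Reading the numbers: every simulated sample is assigned back to its true
haplogroup; the non-recombining mitochondrial cohort shows no
distance-dependent LD decay (R ≈ 0, non-significant) while the recombining
nuclear panel decays clearly (R < 0); hiding half of all reference-panel
calls and re-imputing them recovers 99.8 % of genotypes; and copy numbers
estimated from noisy depth pairs land within a few percent of truth.

A `mitolandscape` console command exposes the same steps
(`simulate`, `stats`, `haplogroup`, `embed`, `ld`, `impute`, `mtcn`);
run `mitolandscape --help` for options.

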