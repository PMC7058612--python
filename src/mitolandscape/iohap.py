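"""Genotype, annotation, and table I/O plus basic variant-spectrum statistics.

The mitochondrial genome is treated as a haploid molecule on the revised
Cambridge Reference Sequence (rCRS): a circular contig of 16,569 bp with
1-based coordinates.  Variant calls are stored as samples x biallelic
variants with values 0 (reference), 1 (alternative) or -1 (missing).
Heteroplasmy-like heterozygous calls on the mitochondrial contig are set to
missing: only homoplasmic alleles are analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

MT_LENGTH = 16569
MISSING = -1

#: canonical control-region (D-loop) bounds on rCRS, wrapping the origin
D_LOOP_INTERVALS = ((16024, 16569), (1, 576))

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant on a named contig (1-based position)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_transition(self) -> bool:
        return (self.ref_allele, self.alt_allele) in _TRANSITIONS


@dataclass
class HaploidGenotypeMatrix:
    """Samples x biallelic variants with calls in {0, 1, MISSING}."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray  # (n_samples, n_variants) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.variants], dtype=np.int64)

    def alt_frequency(self) -> np.ndarray:
        """Alternative-allele frequency per variant over non-missing calls.

        Variants with no observed calls yield NaN.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        n_alt = (self.calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, n_alt / np.maximum(n_obs, 1), np.nan)

    def maf(self) -> np.ndarray:
        af = self.alt_frequency()
        return np.minimum(af, 1.0 - af)

    def subset_variants(self, mask: np.ndarray) -> "HaploidGenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return HaploidGenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx],
        )

    def subset_samples(self, mask: np.ndarray) -> "HaploidGenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return HaploidGenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            calls=self.calls[idx, :],
        )


@dataclass
class RegionAnnotation:
    """Named region as 1-based inclusive intervals, possibly origin-wrapping.

    A wrapping interval (start > end) on a circular contig of length
    ``contig_length`` covers [start, contig_length] plus [1, end].
    """

    name: str
    intervals: list[tuple[int, int]]
    contig_length: int = MT_LENGTH

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("intervals must be non-empty")

    def contains(self, position: int | np.ndarray) -> np.ndarray | bool:
        pos = np.asarray(position)
        hit = np.zeros(pos.shape, dtype=bool)
        for start, end in self.intervals:
            if start <= end:
                hit |= (pos >= start) & (pos <= end)
            else:  # wraps the circular origin
                hit |= (pos >= start) | (pos <= end)
        return bool(hit) if np.isscalar(position) else hit


@dataclass
class HaplotypePanel:
    """Phased nuclear haplotypes: 2N rows x M variants with 0/1 alleles."""

    haplotypes: np.ndarray  # (2N, M) int8, complete
    positions: np.ndarray  # (M,) int64, 1-based, ascending
    contig: str = "1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix and positions are inconsistent")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be ascending")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequency(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1 - af)


def d_loop_annotation(contig_length: int = MT_LENGTH) -> RegionAnnotation:
    """The rCRS control region: 16,024-16,569 plus 1-576."""
    return RegionAnnotation("D-loop", list(D_LOOP_INTERVALS), contig_length)


def read_region_tsv(path: str, contig_length: int = MT_LENGTH) -> list[RegionAnnotation]:
    """Read a BED-like TSV of name/start/end (1-based inclusive) rows."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("name", sort=False):
        ivals = [(int(r.start), int(r.end)) for r in grp.itertuples()]
        out.append(RegionAnnotation(str(name), ivals, contig_length))
    return out


# ---------------------------------------------------------------------------
# VCF input / output


def _call_from_gt(gt: tuple, alt_index: int) -> int:
    """Map a pysam GT tuple to a haploid call for one split alt allele.

    Haploid GTs map directly; homozygous diploid encodings are accepted
    (0/0 -> 0, k/k -> 1 for the matching alt); heterozygous or partially
    missing genotypes become missing (homoplasmy-only convention).
    """
    alleles = [a for a in gt if a is not None]
    if len(alleles) != len(gt) or not alleles:
        return MISSING
    if len(set(alleles)) > 1:
        return MISSING  # heteroplasmy-like call
    a = alleles[0]
    return 1 if a == alt_index else 0


def read_haploid_vcf(path: str, contig: str) -> HaploidGenotypeMatrix:
    """Read one contig from a VCF into a haploid 0/1/missing matrix.

    Multiallelic rows are split into biallelic records sharing a position;
    a sample carrying a different alternative allele is coded 0 for the
    record under consideration.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path!r}: {exc}") from exc
    with vf:
        contigs_seen = set()
        sample_ids = list(vf.header.samples)
        variants: list[VariantRecord] = []
        columns: list[np.ndarray] = []
        for rec in vf:
            contigs_seen.add(rec.contig)
            if rec.contig != contig:
                continue
            gts = [rec.samples[s].get("GT") or (None,) for s in sample_ids]
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                variants.append(
                    VariantRecord(
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        id=rec.id or ".",
                    )
                )
                columns.append(
                    np.array([_call_from_gt(gt, alt_index) for gt in gts], dtype=np.int8)
                )
    if not variants:
        raise LookupError(
            f"contig {contig!r} not found in {path!r}; saw {sorted(contigs_seen)}"
        )
    calls = np.stack(columns, axis=1) if columns else np.empty((len(sample_ids), 0), np.int8)
    return HaploidGenotypeMatrix(sample_ids, variants, calls)


def write_haploid_vcf(
    matrix: HaploidGenotypeMatrix, path: str, contig_length: int | None = None
) -> None:
    """Write a haploid matrix as an uncompressed VCF with haploid GT fields."""
    header = pysam.VariantHeader()
    contigs = {v.contig for v in matrix.variants}
    for contig in sorted(contigs):
        length = contig_length or (MT_LENGTH if contig in ("MT", "chrM") else 2**29)
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in matrix.sample_ids:
        header.add_sample(s)
    idx = np.lexsort((
        [v.alt_allele for v in matrix.variants],
        [v.position for v in matrix.variants],
        [v.contig for v in matrix.variants],
    ))
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in idx:
            v = matrix.variants[j]
            rec = out.new_record(
                contig=v.contig,
                start=v.position - 1,
                stop=v.position - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
                id=None if v.id == "." else v.id,
            )
            for i, s in enumerate(matrix.sample_ids):
                c = matrix.calls[i, j]
                rec.samples[s]["GT"] = (None,) if c == MISSING else (int(c),)
            out.write(rec)


# ---------------------------------------------------------------------------
# Variant-spectrum statistics

MAF_BINS = ("rare", "low_frequency", "common")


def classify_maf_bin(maf: float) -> str:
    """Bin a minor-allele frequency: rare (<0.5%), low-frequency (<5%), common."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if maf < 0.005:
        return "rare"
    if maf < 0.05:
        return "low_frequency"
    return "common"


def titv_ratio(variants: list[VariantRecord]) -> float:
    """Transition/transversion ratio over single-base substitutions.

    Returns ``inf`` when transversions are absent (undefined ratio is
    signalled, never a silent division).
    """
    if not variants:
        raise ValueError("variant list must be non-empty")
    snvs = [v for v in variants if v.is_snv]
    ti = sum(v.is_transition for v in snvs)
    tv = len(snvs) - ti
    if tv == 0:
        return float("inf")
    return ti / tv


def maf_spectrum(matrix: HaploidGenotypeMatrix) -> pd.Series:
    """Fraction of variants per MAF bin (rare / low_frequency / common)."""
    mafs = matrix.maf()
    bins = [classify_maf_bin(m) for m in mafs if not np.isnan(m)]
    counts = pd.Series(bins).value_counts()
    return counts.reindex(MAF_BINS, fill_value=0) / max(len(bins), 1)


# ---------------------------------------------------------------------------
# Nuclear variant QC


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value from diploid genotype counts.

    Full enumeration over heterozygote counts compatible with the observed
    allele margin; the p-value sums probabilities of all tables no more
    probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | margin) up to a constant, via log-factorials
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(p[p <= obs * (1 + 1e-12)].sum())


def nuclear_variant_qc(
    genotypes: np.ndarray,
    call_rate_min: float = 0.99,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter diploid genotypes (samples x variants, codes 0/1/2, -1 missing).

    Retains variants with call rate >= ``call_rate_min``, MAF >= ``maf_min``
    and Hardy-Weinberg exact p >= ``hwe_p_min``.  Returns the filtered matrix
    and the boolean keep-mask.  Monomorphic variants fall to the MAF filter.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    obs = g >= 0
    call_rate = obs.sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(obs, g, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    maf = np.minimum(af, 1 - af)
    keep = (call_rate >= call_rate_min) & (maf >= maf_min)
    for j in np.flatnonzero(keep):
        col = g[obs[:, j], j]
        counts = np.bincount(col, minlength=3)
        if hwe_exact_pvalue(int(counts[0]), int(counts[1]), int(counts[2])) < hwe_p_min:
            keep[j] = False
    return g[:, keep], keep


# ---------------------------------------------------------------------------
# Depth and phenotype tables


def read_depth_tsv(path: str) -> pd.DataFrame:
    """Read a per-sample depth table (sample_id, mt_depth, depth_chr*)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "mt_depth" not in df.columns:
        raise ValueError("depth table requires sample_id and mt_depth columns")
    return df


def read_pheno_tsv(path: str) -> pd.DataFrame:
    """Read a phenotype/covariate table keyed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table requires a sample_id column")
    return df
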