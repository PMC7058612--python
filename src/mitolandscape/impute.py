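"""Haploid mtDNA genotype imputation by a haplotype-copying hidden Markov model.

Each target haplotype is modelled as an imperfect mosaic copy of the
reference haplotypes (Li-Stephens style).  The hidden state at every panel
site is the reference haplotype being copied; between adjacent panel sites
the state switches to a uniformly drawn haplotype with probability
``switch_rate`` (near zero for the non-recombining mitochondrial genome),
and typed target alleles mismatch the copied allele with probability
``error_rate``.  Forward-backward posteriors give per-variant expected
alternative-allele doses in [0, 1]; untyped-variant doses are the
posterior-weighted average of the reference alleles.

Imputation quality per variant is summarized by an info score comparing the
mean posterior dose variance with the binomial variance at the estimated
allele frequency, and by masking cross-validation (concordance of imputed
hard calls with held-out truth, overall and per MAF bin among true
minor-allele carriers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iohap import MISSING, HaploidGenotypeMatrix

#: per-adjacent-site copying switch probability; near zero reflects the
#: absence of recombination in mtDNA
DEFAULT_SWITCH_RATE = 1e-8
DEFAULT_ERROR_RATE = 1e-3

MAF_BIN_EDGES = (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class ReferencePanel:
    """Complete haploid reference haplotypes (K x M) with variant positions."""

    haplotypes: np.ndarray  # (K, M) int8, values 0/1 only
    positions: np.ndarray  # (M,)
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise ValueError("panel needs at least two haplotypes")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("panel haplotypes must be complete 0/1 calls")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotypes and positions are inconsistent")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @classmethod
    def from_matrix(
        cls, matrix: HaploidGenotypeMatrix, maf_min: float = 0.0
    ) -> "ReferencePanel":
        """Build a panel from a complete cohort matrix, optionally MAF-filtered."""
        if (matrix.calls == MISSING).any():
            raise ValueError("reference panel requires complete calls")
        keep = matrix.maf() >= maf_min
        sub = matrix.subset_variants(keep)
        ids = [f"{v.position}:{v.ref_allele}:{v.alt_allele}" for v in sub.variants]
        return cls(sub.calls.copy(), sub.positions, ids)


@dataclass
class ImputedDosage:
    """Posterior expected alt-allele doses with per-variant info scores."""

    sample_ids: list[str]
    positions: np.ndarray
    doses: np.ndarray  # (n, M) in [0, 1]
    imputed: np.ndarray  # (n, M) bool: True where the call was not typed
    info: np.ndarray | None = None  # (M,), filled by attach_info

    def hard_calls(self) -> np.ndarray:
        """Threshold doses at 0.5; a tie at exactly 0.5 resolves to reference."""
        return (self.doses > 0.5).astype(np.int8)

    def estimated_af(self) -> np.ndarray:
        return self.doses.mean(axis=0)


def _forward_backward(
    panel: ReferencePanel,
    typed_mask: np.ndarray,
    typed_calls: np.ndarray,
    switch_rate: float,
    error_rate: float,
) -> np.ndarray:
    """Copying-state posterior (M x K) for one target haplotype.

    Emissions apply at typed sites only; transitions act between every pair
    of adjacent panel sites (switch to a uniform haplotype with probability
    ``switch_rate``).
    """
    hap = panel.haplotypes
    k = panel.n_haplotypes
    m = panel.n_variants
    # per-site emission vectors (all-ones at untyped sites)
    alpha = np.empty((m, k))
    scale = np.empty(m)

    def emission(j: int) -> np.ndarray | None:
        if not typed_mask[j]:
            return None
        match = hap[:, j] == typed_calls[j]
        return np.where(match, 1.0 - error_rate, error_rate)

    f = np.full(k, 1.0 / k)
    e = emission(0)
    if e is not None:
        f = f * e
    scale[0] = f.sum()
    if scale[0] == 0:
        raise ValueError("zero likelihood: target incompatible with panel at error_rate 0")
    f = f / scale[0]
    alpha[0] = f
    stay = 1.0 - switch_rate
    for j in range(1, m):
        f = stay * f + switch_rate * (1.0 / k)
        e = emission(j)
        if e is not None:
            f = f * e
        scale[j] = f.sum()
        if scale[j] == 0:
            raise ValueError(
                "zero likelihood: target incompatible with panel at error_rate 0"
            )
        f = f / scale[j]
        alpha[j] = f

    b = np.full(k, 1.0)
    post = np.empty((m, k))
    post[m - 1] = alpha[m - 1] * b
    post[m - 1] /= post[m - 1].sum()
    for j in range(m - 2, -1, -1):
        e = emission(j + 1)
        be = b if e is None else b * e
        b = stay * be + switch_rate * be.mean()
        b = b / b.sum()
        post[j] = alpha[j] * b
        post[j] /= post[j].sum()
    return post


def haploid_impute(
    panel: ReferencePanel,
    target: HaploidGenotypeMatrix,
    switch_rate: float = DEFAULT_SWITCH_RATE,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> ImputedDosage:
    """Impute all panel variants for each target sample.

    Target variants must be a subset of the panel's (matched on position and
    alleles when available); missing calls in the target are treated as
    untyped.  Returned doses cover every panel variant; typed calls keep
    their observed 0/1 value with an imputed flag of False.
    """
    if panel.n_variants == 0 or target.n_samples == 0:
        raise ValueError("panel and target must be non-empty")
    panel_index = {int(p): j for j, p in enumerate(panel.positions)}
    missing_vars = [v.position for v in target.variants if int(v.position) not in panel_index]
    if missing_vars:
        raise KeyError(f"target variants absent from panel at positions {missing_vars[:10]}")
    col_of = np.array([panel_index[int(v.position)] for v in target.variants])

    n = target.n_samples
    m = panel.n_variants
    doses = np.empty((n, m))
    imputed = np.ones((n, m), dtype=bool)
    hapf = panel.haplotypes.astype(float)
    for i in range(n):
        typed_mask = np.zeros(m, dtype=bool)
        typed_calls = np.zeros(m, dtype=np.int8)
        obs = target.calls[i] != MISSING
        typed_mask[col_of[obs]] = True
        typed_calls[col_of[obs]] = target.calls[i][obs]
        post = _forward_backward(panel, typed_mask, typed_calls, switch_rate, error_rate)
        doses[i] = np.einsum("mk,km->m", post, hapf)
        doses[i, typed_mask] = typed_calls[typed_mask]
        imputed[i, typed_mask] = False
    np.clip(doses, 0.0, 1.0, out=doses)
    return ImputedDosage(list(target.sample_ids), panel.positions.copy(), doses, imputed)


def info_score(doses: np.ndarray) -> float:
    """Imputation info: 1 − mean posterior variance / (p̂(1−p̂)), haploid form.

    For a haploid dose d the posterior allele variance is d(1−d).  Equals 1
    when every dose is a hard 0/1 call and 0 when doses carry no information
    beyond the allele frequency.  NaN signals an undefined score (estimated
    frequency 0 or 1).
    """
    d = np.asarray(doses, float)
    if d.size < 2:
        raise ValueError("need at least two samples")
    p = d.mean()
    if p <= 0.0 or p >= 1.0:
        return float("nan")
    mean_var = float((d * (1.0 - d)).mean())
    return 1.0 - mean_var / (p * (1.0 - p))


def attach_info(dosage: ImputedDosage) -> ImputedDosage:
    dosage.info = np.array(
        [info_score(dosage.doses[:, j]) for j in range(dosage.doses.shape[1])]
    )
    return dosage


def post_imputation_filter(
    dosage: ImputedDosage, maf_min: float = 0.005, info_min: float = 0.7
) -> ImputedDosage:
    """Retain variants with estimated MAF ≥ ``maf_min`` and info ≥ ``info_min``."""
    if dosage.info is None:
        attach_info(dosage)
    af = dosage.estimated_af()
    maf = np.minimum(af, 1 - af)
    keep = (maf >= maf_min) & (np.nan_to_num(dosage.info, nan=-1.0) >= info_min)
    return ImputedDosage(
        list(dosage.sample_ids),
        dosage.positions[keep],
        dosage.doses[:, keep],
        dosage.imputed[:, keep],
        dosage.info[keep],
    )


@dataclass
class CrossValidationResult:
    overall_concordance: float
    minor_allele_concordance: pd.Series  # per MAF bin
    n_masked: int


def cross_validate(
    panel: ReferencePanel,
    mask_fraction: float = 0.5,
    seed: int = 0,
    switch_rate: float = DEFAULT_SWITCH_RATE,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> CrossValidationResult:
    """Masking cross-validation of the panel against itself (leave-one-out).

    A ``mask_fraction`` of all calls is hidden uniformly at random; each
    sample is then imputed from the panel with itself removed, and imputed
    hard calls (dose > 0.5 -> alt, ties -> reference) are compared with the
    held-out truth.  Minor-allele concordance is computed per MAF bin over
    masked calls whose true allele is the variant's minor allele.
    """
    if not 0.0 <= mask_fraction <= 1.0:
        raise ValueError("mask_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k, m = panel.haplotypes.shape
    mask = rng.random((k, m)) < mask_fraction
    # a fully masked sample has no typed sites; re-draw its mask row
    for i in range(k):
        guard = 0
        while mask[i].all() and m > 0:
            warnings.warn(f"mask emptied sample {i}; re-drawing")
            mask[i] = rng.random(m) < mask_fraction
            guard += 1
            if guard > 100:
                mask[i, 0] = False

    af = panel.haplotypes.mean(axis=0)
    maf = np.minimum(af, 1 - af)
    minor_allele = (af <= 0.5).astype(np.int8)  # alt is minor iff alt freq <= 0.5
    bins = pd.IntervalIndex.from_breaks(MAF_BIN_EDGES, closed="right")

    n_match = 0
    n_total = 0
    bin_match = np.zeros(len(bins))
    bin_total = np.zeros(len(bins))
    keep_rows = np.ones(k, dtype=bool)
    for i in range(k):
        if not mask[i].any():
            continue
        keep_rows[:] = True
        keep_rows[i] = False
        sub_panel = ReferencePanel(
            panel.haplotypes[keep_rows], panel.positions, panel.variant_ids
        )
        calls = panel.haplotypes[i].astype(np.int8).copy()
        calls[mask[i]] = MISSING
        target = _bare_target(calls, panel, f"cv_{i}")
        dosage = haploid_impute(sub_panel, target, switch_rate, error_rate)
        hard = dosage.hard_calls()[0]
        truth = panel.haplotypes[i]
        hit = hard[mask[i]] == truth[mask[i]]
        n_match += int(hit.sum())
        n_total += int(mask[i].sum())
        is_minor = truth == minor_allele
        sel = mask[i] & is_minor
        if sel.any():
            which_bin = np.searchsorted(MAF_BIN_EDGES[1:], maf[sel], side="left")
            ok = hard[sel] == truth[sel]
            np.add.at(bin_match, which_bin, ok)
            np.add.at(bin_total, which_bin, 1)

    overall = 1.0 if n_total == 0 else n_match / n_total
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(bin_total > 0, bin_match / np.maximum(bin_total, 1), np.nan)
    labels = [f"{int(a * 100)}-{int(b * 100)}%" for a, b in zip(MAF_BIN_EDGES[:-1], MAF_BIN_EDGES[1:])]
    return CrossValidationResult(
        overall_concordance=float(overall),
        minor_allele_concordance=pd.Series(per_bin, index=labels, name="concordance"),
        n_masked=n_total,
    )


def _bare_target(calls: np.ndarray, panel: ReferencePanel, sample_id: str) -> HaploidGenotypeMatrix:
    # placeholder alleles: imputation matches target to panel on position
    from .iohap import VariantRecord

    variants = [VariantRecord("MT", int(p), "A", "G") for p in panel.positions]
    return HaploidGenotypeMatrix([sample_id], variants, calls.reshape(1, -1))
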