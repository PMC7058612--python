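"""mtDNA copy-number estimation and mtDNA/mtCN vs nuclear genome scans.

The copy number per cell is estimated from sequencing depth as

    mtCN_c = mean mtDNA depth / mean depth of autosome c x 2

averaged over autosomes (diploid nuclear genome, hence the factor 2).

Genome-wide scans follow the study design: for each (mtDNA variant, nuclear
variant) pair a logistic regression with the haploid mtDNA allele as the
binary response and the nuclear dosage plus covariates as predictors; for
mtCN a linear regression of copy number on dosage plus covariates.
Bonferroni thresholds divide a base genome-wide alpha by the number of
mtDNA variants tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .iohap import MISSING, HaploidGenotypeMatrix


@dataclass
class DepthSummary:
    """Mean sequencing depth of the mitochondrial contig and each autosome."""

    sample_id: str
    mean_mt_depth: float
    mean_autosomal_depths: np.ndarray  # per-chromosome mean coverage

    def __post_init__(self) -> None:
        self.mean_autosomal_depths = np.asarray(self.mean_autosomal_depths, float)
        if self.mean_mt_depth < 0 or (self.mean_autosomal_depths < 0).any():
            raise ValueError("depths must be non-negative")


def estimate_mtcn(depth: DepthSummary) -> float:
    """Copy number: mean over autosomes of (mt depth / autosomal depth x 2).

    Chromosomes with zero depth are excluded with a warning; all-zero
    autosomal depth is an error.
    """
    auto = depth.mean_autosomal_depths
    ok = auto > 0
    if not ok.any():
        raise ValueError(f"sample {depth.sample_id!r} has no positive autosomal depth")
    if not ok.all():
        warnings.warn(
            f"sample {depth.sample_id!r}: excluding {int((~ok).sum())} zero-depth chromosomes"
        )
    per_chrom = depth.mean_mt_depth / auto[ok] * 2.0
    return float(per_chrom.mean())


def mtcn_from_table(depth_table: pd.DataFrame) -> pd.Series:
    """Vectorized mtCN per sample from an iohap depth table."""
    chrom_cols = [c for c in depth_table.columns if c.startswith("depth_chr")]
    if not chrom_cols:
        raise ValueError("depth table has no depth_chr* columns")
    values = [
        estimate_mtcn(
            DepthSummary(str(r.sample_id), float(r.mt_depth),
                         np.array([getattr(r, c) for c in chrom_cols]))
        )
        for r in depth_table.itertuples()
    ]
    return pd.Series(values, index=depth_table["sample_id"].to_numpy(), name="mtcn")


def bonferroni_threshold(base_alpha: float, divisors: list[int]) -> float:
    """Bonferroni-corrected threshold: base_alpha / product(divisors)."""
    if base_alpha <= 0:
        raise ValueError("base_alpha must be positive")
    for d in divisors:
        if d < 1:
            raise ValueError(f"divisors must be >= 1, got {d}")
    return base_alpha / float(np.prod([float(d) for d in divisors]))


def _design(dosage: np.ndarray, covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(dosage, dtype=float), dosage.astype(float)]
    if covariates is not None:
        cov = pd.get_dummies(pd.DataFrame(covariates), drop_first=True, dtype=float)
        cols.extend(cov.to_numpy(float).T)
    return np.column_stack(cols)


@dataclass
class ScanRow:
    ndna_variant: int
    mt_variant: str
    effect: float
    se: float
    p_value: float
    flagged: bool = False


def mt_ndna_scan(
    mt: HaploidGenotypeMatrix,
    ndna_dosage: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mt_maf_min: float = 0.05,
) -> pd.DataFrame:
    """Logistic scan: each common mtDNA allele regressed on each nuclear dosage.

    Separation or non-convergence flags the row (p omitted as NaN) rather
    than dropping it silently.
    """
    keep = np.flatnonzero(mt.maf() >= mt_maf_min)
    ndna = np.asarray(ndna_dosage, float)
    rows: list[ScanRow] = []
    for jm in keep:
        y_full = mt.calls[:, jm]
        ok_y = y_full != MISSING
        label = f"{mt.variants[jm].position}{mt.variants[jm].alt_allele}"
        for jn in range(ndna.shape[1]):
            y = y_full[ok_y].astype(float)
            x = _design(ndna[ok_y, jn], None if covariates is None else covariates[ok_y])
            rows.append(_fit_logit(y, x, jn, label))
    return _scan_frame(rows)


def _fit_logit(y: np.ndarray, x: np.ndarray, jn: int, label: str) -> ScanRow:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=50)
        if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse[1]):
            raise sm.tools.sm_exceptions.PerfectSeparationError
        return ScanRow(jn, label, float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]))
    except Exception:
        return ScanRow(jn, label, float("nan"), float("nan"), float("nan"), flagged=True)


def mtcn_ndna_scan(
    mtcn: np.ndarray,
    ndna_dosage: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Linear scan: mtCN regressed on each nuclear dosage plus covariates."""
    y = np.asarray(mtcn, float)
    if np.std(y) == 0:
        raise ValueError("mtCN is constant; scan undefined")
    ndna = np.asarray(ndna_dosage, float)
    rows = []
    for jn in range(ndna.shape[1]):
        x = _design(ndna[:, jn], covariates)
        fit = sm.OLS(y, x).fit()
        rows.append(ScanRow(jn, "mtCN", float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])))
    return _scan_frame(rows)


def _scan_frame(rows: list[ScanRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ndna_variant": [r.ndna_variant for r in rows],
            "mt_variant": [r.mt_variant for r in rows],
            "effect": [r.effect for r in rows],
            "se": [r.se for r in rows],
            "p_value": [r.p_value for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    )


def manhattan_min_p(scan: pd.DataFrame) -> pd.Series:
    """Per-nuclear-variant minimum p across mtDNA variants (Manhattan input)."""
    return scan.dropna(subset=["p_value"]).groupby("ndna_variant")["p_value"].min()


def gene_window_subset(
    positions: np.ndarray,
    gene_intervals: pd.DataFrame,
    window: int = 10_000,
    chroms: np.ndarray | None = None,
) -> np.ndarray:
    """Flag variants within ±``window`` bp of any listed gene (inclusive).

    ``gene_intervals`` needs start/end columns (1-based) and, when variant
    ``chroms`` are supplied, a chrom column.
    """
    pos = np.asarray(positions)
    flag = np.zeros(pos.shape, dtype=bool)
    if gene_intervals.empty:
        return flag
    for row in gene_intervals.itertuples():
        hit = (pos >= row.start - window) & (pos <= row.end + window)
        if chroms is not None and hasattr(row, "chrom"):
            hit &= np.asarray(chroms) == row.chrom
        flag |= hit
    return flag


_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


def qq_lambda(p_values: np.ndarray) -> tuple[pd.DataFrame, float]:
    """QQ table (sorted observed vs expected p) and genomic inflation lambda.

    lambda = median of the implied chi-square(1) statistics divided by the
    chi-square(1) median (~0.4549); 1 under a well-calibrated null.
    """
    p = np.asarray(p_values, float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    lam = float(np.median(stats.chi2.isf(p, df=1)) / _CHI2_MEDIAN)
    return pd.DataFrame({"expected": expected, "observed": obs}), lam
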