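"""Phenome-wide association of imputed mtDNA dosages with biobank phenotypes.

Binary traits are analysed by logistic regression of case status on the
variant dosage with age, sex, top principal components, geographic region
and genotyping platform as covariates; everyone not affected by the trait
under scope serves as control.  Quantitative traits are first residualized
on age, sex, PCs and any trait-specific covariates, rank-transformed to a
standard normal (Blom offset (r − 3/8)/(n + 1/4), average ranks for ties),
and then regressed linearly on dosage with region and platform covariates.

Two Bonferroni tiers flag results: study-wide 0.05/(V x P) over V variants
and P phenotypes, and variant-wide 0.05/V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri


def rank_normalize_residuals(
    values: np.ndarray, covariates: pd.DataFrame | np.ndarray | None = None
) -> np.ndarray:
    """Rank-based inverse-normal transform of covariate-adjusted residuals.

    Residuals come from an ordinary least-squares regression on the
    covariates (values themselves when none are given); ranks use the Blom
    offset (r − 3/8)/(n + 1/4) with average ranks for ties.  The output is
    mean ~0, variance ~1 and preserves the residual rank order; any monotone
    transform of the input yields identical output.
    """
    y = np.asarray(values, float)
    if y.size < 3:
        raise ValueError("need at least three values")
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")
    if covariates is not None:
        cov = pd.get_dummies(pd.DataFrame(covariates), drop_first=True, dtype=float)
        x = np.column_stack([np.ones(y.size), cov.to_numpy(float)])
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    else:
        resid = y
    from scipy.stats import rankdata

    ranks = rankdata(resid, method="average")
    return ndtri((ranks - 3.0 / 8.0) / (y.size + 1.0 / 4.0))


@dataclass(frozen=True)
class TraitSpec:
    """Declared phenotype: name, kind ("binary"/"quantitative"), extra covariates."""

    name: str
    kind: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait kind {self.kind!r}")


STANDARD_COVARIATES = ("age", "sex")
STRATIFICATION_COVARIATES = ("region", "platform")


def _pc_columns(pheno: pd.DataFrame, n_pcs: int) -> list[str]:
    return [c for c in (f"PC{i + 1}" for i in range(n_pcs)) if c in pheno.columns]


def _design_frame(pheno: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    return pd.get_dummies(pheno[columns], drop_first=True, dtype=float)


def run_phewas(
    doses: np.ndarray,
    variant_labels: list[str],
    pheno: pd.DataFrame,
    traits: list[TraitSpec],
    n_pcs: int = 20,
    include_stratification: bool = True,
) -> pd.DataFrame:
    """Association of each dosage column with each declared trait.

    Returns a table with effect (log-odds for binary, beta for quantitative),
    standard error, 95% CI, p, counts, and a flag for non-converged or
    separated logistic fits.  Traits without both cases and controls are
    skipped with a warning.
    """
    doses = np.asarray(doses, float)
    if doses.shape[0] != len(pheno):
        raise ValueError("dosage rows must align with the phenotype table")
    pcs = _pc_columns(pheno, n_pcs)
    strat = [c for c in STRATIFICATION_COVARIATES if c in pheno.columns]
    base = [c for c in STANDARD_COVARIATES if c in pheno.columns]
    rows = []
    for trait in traits:
        y_raw = pheno[trait.name].to_numpy()
        ok = ~pd.isna(y_raw)
        extra = [c for c in trait.covariates if c in pheno.columns]
        if trait.kind == "binary":
            y = y_raw[ok].astype(float)
            if len(np.unique(y)) < 2:
                warnings.warn(f"trait {trait.name!r} has no cases or no controls; skipped")
                continue
            cov_cols = base + pcs + (strat if include_stratification else []) + extra
            cov = _design_frame(pheno.loc[ok], cov_cols).to_numpy(float)
            for j, label in enumerate(variant_labels):
                rows.append(
                    _logistic_row(y, doses[ok, j], cov, label, trait.name)
                )
        else:
            adj_cols = base + pcs + extra
            adj = _design_frame(pheno.loc[ok], adj_cols) if adj_cols else None
            z = rank_normalize_residuals(y_raw[ok].astype(float), adj)
            cov_cols = strat if include_stratification else []
            cov = (
                _design_frame(pheno.loc[ok], cov_cols).to_numpy(float)
                if cov_cols
                else np.empty((int(ok.sum()), 0))
            )
            for j, label in enumerate(variant_labels):
                rows.append(_linear_row(z, doses[ok, j], cov, label, trait.name))
    return pd.DataFrame(rows)


def _logistic_row(y, dose, cov, variant, trait) -> dict:
    x = np.column_stack([np.ones(y.size), dose, cov])
    n_case = int(y.sum())
    n_control = int(y.size - n_case)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=50)
        if not np.isfinite(fit.bse[1]):
            raise ValueError("non-finite standard error")
        beta, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
        return {
            "variant": variant, "phenotype": trait, "kind": "binary",
            "effect": beta, "se": se,
            "or": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * se)),
            "ci_high": float(np.exp(beta + 1.96 * se)),
            "p": p, "n_case": n_case, "n_control": n_control, "flagged": False,
        }
    except Exception:
        return {
            "variant": variant, "phenotype": trait, "kind": "binary",
            "effect": np.nan, "se": np.nan, "or": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
            "n_case": n_case, "n_control": n_control, "flagged": True,
        }


def _linear_row(z, dose, cov, variant, trait) -> dict:
    x = np.column_stack([np.ones(z.size), dose, cov])
    fit = sm.OLS(z, x).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return {
        "variant": variant, "phenotype": trait, "kind": "quantitative",
        "effect": beta, "se": se, "or": np.nan,
        "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se,
        "p": float(fit.pvalues[1]), "n_case": int(z.size), "n_control": 0,
        "flagged": False,
    }


def apply_threshold_flags(
    results: pd.DataFrame, n_variants: int, n_phenotypes: int
) -> pd.DataFrame:
    """Flag study-wide (p < 0.05/(V·P)) and variant-wide (p < 0.05/V) hits."""
    if n_variants < 1 or n_phenotypes < 1:
        raise ValueError("variant and phenotype counts must be >= 1")
    out = results.copy()
    study = 0.05 / (n_variants * n_phenotypes)
    variant_wide = 0.05 / n_variants
    out["passes_study_wide"] = out["p"] < study
    out["passes_variant_wide"] = out["p"] < variant_wide
    out[["passes_study_wide", "passes_variant_wide"]] = out[
        ["passes_study_wide", "passes_variant_wide"]
    ].fillna(False)
    return out


def array_qc(
    calls: np.ndarray,
    sample_call_rate_min: float = 0.9,
    variant_call_rate_min: float = 0.99,
    reference_calls: np.ndarray | None = None,
    overlap_samples: np.ndarray | None = None,
    concordance_min: float = 0.99,
) -> tuple[np.ndarray, dict]:
    """Array-genotype QC: sample call rate, variant call rate, WGS concordance.

    ``calls`` is samples x variants with -1 for missing.  The three filters
    apply in the stated order; with no overlap set the concordance filter is
    skipped with a warning.  Returns (filtered matrix, removal report).
    """
    g = np.asarray(calls)
    report = {}
    sample_cr = (g != -1).mean(axis=1)
    keep_samples = sample_cr >= sample_call_rate_min
    report["samples_removed"] = int((~keep_samples).sum())
    g = g[keep_samples]

    variant_cr = (g != -1).mean(axis=0) if g.size else np.array([])
    keep_variants = variant_cr >= variant_call_rate_min
    report["variants_removed_call_rate"] = int((~keep_variants).sum())
    g = g[:, keep_variants]

    if reference_calls is None or overlap_samples is None or len(overlap_samples) == 0:
        warnings.warn("no overlap samples; concordance filter skipped")
        report["variants_removed_concordance"] = 0
        return g, report
    ref = np.asarray(reference_calls)[:, keep_variants]
    overlap_idx = np.asarray(overlap_samples)
    sub = np.asarray(calls)[overlap_idx][:, keep_variants]
    both = (sub != -1) & (ref != -1)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(
            both.sum(axis=0) > 0,
            ((sub == ref) & both).sum(axis=0) / np.maximum(both.sum(axis=0), 1),
            1.0,
        )
    keep_conc = conc >= concordance_min
    report["variants_removed_concordance"] = int((~keep_conc).sum())
    return g[:, keep_conc], report
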