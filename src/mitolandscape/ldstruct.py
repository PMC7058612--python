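"""Haploid linkage-disequilibrium structure of the mitochondrial genome.

The suite contrasts the non-recombining mtDNA with recombining nuclear DNA:
pairwise r² and |D′| on haplotypes, a distance-matched sample of nuclear
pairs (±8.3 kbp, the mtDNA pair-distance range), the distance-vs-r² decay
correlation, per-variant tag counts (r² ≥ 0.5; nuclear search limited to
±5 Mbp), detection of strong-LD haplotypes spanning the whole circular
molecule (r² ≥ 0.8 components), and a Fisher test for enrichment of
untagged variants in the control region.

Distances between mtDNA variants use the linear rCRS coordinate difference
(conventional practice); circular geometry enters only when measuring the
positional extent of spanning haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .iohap import MISSING, HaploidGenotypeMatrix, HaplotypePanel, RegionAnnotation


def _joint_freqs(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """(px, py, p11, n) over jointly non-missing haploid calls."""
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n == 0:
        return np.nan, np.nan, np.nan, 0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    return float(xs.mean()), float(ys.mean()), float((xs * ys).mean()), n


def haploid_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype r²: D² / (px qx py qy) with D = p11 − px·py.

    Computed over jointly non-missing calls; NaN signals an undefined value
    (either variant monomorphic on the joint support).
    """
    px, py, p11, n = _joint_freqs(x, y)
    if n == 0 or px in (0.0, 1.0) or py in (0.0, 1.0):
        return float("nan")
    d = p11 - px * py
    return d * d / (px * (1 - px) * py * (1 - py))


def abs_dprime(x: np.ndarray, y: np.ndarray) -> float:
    """|D′| = |D| / Dmax on jointly non-missing haploid calls (NaN if undefined)."""
    px, py, p11, n = _joint_freqs(x, y)
    if n == 0 or px in (0.0, 1.0) or py in (0.0, 1.0):
        return float("nan")
    d = p11 - px * py
    if d >= 0:
        dmax = min(px * (1 - py), (1 - px) * py)
    else:
        dmax = min(px * py, (1 - px) * (1 - py))
    if dmax == 0:
        return float("nan")
    return abs(d) / dmax


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """All-pairs r² for complete 0/1 call columns (no missing)."""
    x = calls.astype(float)
    p = x.mean(axis=0)
    xc = x - p
    n = x.shape[0]
    cov = xc.T @ xc / n
    var = p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov**2 / np.outer(var, var)
    return r2


def mt_pair_table(
    matrix: HaploidGenotypeMatrix, maf_min: float = 0.05
) -> pd.DataFrame:
    """LD table over all common mtDNA variant pairs (source "mt")."""
    keep = np.flatnonzero(matrix.maf() >= maf_min)
    if keep.size < 2:
        raise ValueError("need at least two common variants")
    pos = matrix.positions[keep]
    rows = []
    for a in range(keep.size):
        for b in range(a + 1, keep.size):
            i, j = keep[a], keep[b]
            r2 = haploid_r2(matrix.calls[:, i], matrix.calls[:, j])
            dp = abs_dprime(matrix.calls[:, i], matrix.calls[:, j])
            if np.isnan(r2):
                continue
            rows.append((i, j, int(pos[a]), int(pos[b]), int(abs(pos[b] - pos[a])), r2, dp, "mt"))
    return pd.DataFrame(
        rows, columns=["i", "j", "pos_i", "pos_j", "distance", "r2", "abs_dprime", "source"]
    )


def matched_nuclear_pairs(
    panel: HaplotypePanel,
    max_distance: int = 8300,
    n_pairs: int = 2000,
    seed: int = 0,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Random common-variant pairs within ±``max_distance`` bp (source "nuclear").

    Distance matching mirrors the mtDNA pair-distance range (±8.3 kbp) so
    the nuclear r² distribution is comparable to the mitochondrial one.
    """
    common = np.flatnonzero(panel.maf() >= maf_min)
    if common.size < 2:
        raise ValueError("panel has fewer than two common variants")
    pos = panel.positions[common]
    ii, jj = np.triu_indices(common.size, k=1)
    dist = np.abs(pos[jj] - pos[ii])
    ok = dist <= max_distance
    if not ok.any():
        raise ValueError(f"no qualifying pairs within {max_distance} bp")
    ii, jj, dist = ii[ok], jj[ok], dist[ok]
    rng = np.random.default_rng(seed)
    take = rng.choice(ii.size, size=min(n_pairs, ii.size), replace=False)
    rows = []
    for k in take:
        i, j = common[ii[k]], common[jj[k]]
        x = panel.haplotypes[:, i]
        y = panel.haplotypes[:, j]
        r2 = haploid_r2(x, y)
        if np.isnan(r2):
            continue
        rows.append(
            (int(i), int(j), int(panel.positions[i]), int(panel.positions[j]),
             int(dist[k]), r2, abs_dprime(x, y), "nuclear")
        )
    return pd.DataFrame(
        rows, columns=["i", "j", "pos_i", "pos_j", "distance", "r2", "abs_dprime", "source"]
    )


@dataclass(frozen=True)
class DecayResult:
    pearson_r: float
    p_value: float
    n_pairs: int


def ld_decay_correlation(pairs: pd.DataFrame) -> DecayResult:
    """Pearson correlation between pair distance and r² with two-sided p.

    NaN/NaN signals the degenerate case of zero variance in either vector.
    """
    d = pairs["distance"].to_numpy(float)
    r2 = pairs["r2"].to_numpy(float)
    if np.unique(d).size < 3:
        raise ValueError("need at least three pairs with distinct distances")
    if np.std(d) == 0 or np.std(r2) == 0:
        return DecayResult(float("nan"), float("nan"), len(pairs))
    res = stats.pearsonr(d, r2)
    return DecayResult(float(res.statistic), float(res.pvalue), len(pairs))


def tag_counts(
    calls_or_panel: HaploidGenotypeMatrix | HaplotypePanel,
    r2_threshold: float = 0.5,
    window: int | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Per-common-variant count of common tag variants with r² ≥ threshold.

    For nuclear panels the search is restricted to ±``window`` bp (default
    use 5,000,000); for mtDNA pass ``window=None`` (unrestricted).  Returns a
    table with columns variant index, position, tag count and untagged flag.
    """
    if isinstance(calls_or_panel, HaplotypePanel):
        calls = calls_or_panel.haplotypes
        positions = calls_or_panel.positions
        maf = calls_or_panel.maf()
    else:
        calls = np.where(calls_or_panel.calls == MISSING, 0, calls_or_panel.calls)
        positions = calls_or_panel.positions
        maf = calls_or_panel.maf()
    common = np.flatnonzero(maf >= maf_min)
    if common.size == 0:
        raise ValueError("no common variants present")
    sub = calls[:, common].astype(float)
    r2 = _pairwise_r2(sub)
    np.fill_diagonal(r2, 0.0)
    pos = positions[common]
    in_window = (
        np.ones_like(r2, dtype=bool)
        if window is None
        else np.abs(pos[:, None] - pos[None, :]) <= window
    )
    counts = np.nansum((r2 >= r2_threshold) & in_window, axis=1).astype(int)
    return pd.DataFrame(
        {
            "variant": common,
            "position": pos,
            "n_tags": counts,
            "untagged": counts == 0,
        }
    )


def untagged_fraction(tag_table: pd.DataFrame) -> float:
    return float(tag_table["untagged"].mean())


@dataclass(frozen=True)
class SpanningHaplotype:
    members: tuple[int, ...]  # variant column indices
    positions: tuple[int, ...]
    extent_bp: int
    extent_fraction: float


def _positional_extent(positions: np.ndarray, length: int) -> int:
    """Span (bp) of member positions along the reference coordinate.

    The span is the linear max-min coordinate difference; on the circular
    molecule this equals the arc obtained by cutting at the origin, so a
    component qualifies as "spanning" when its members stretch across most
    of the reference coordinate system.
    """
    pos = np.asarray(positions)
    return int(pos.max() - pos.min())


def spanning_haplotypes(
    matrix: HaploidGenotypeMatrix,
    r2_threshold: float = 0.8,
    extent_fraction_min: float = 0.9,
    maf_min: float = 0.05,
    mt_length: int | None = None,
) -> list[SpanningHaplotype]:
    """Strong-LD variant sets spanning (almost) the entire circular molecule.

    Common variants form a graph with edges r² ≥ ``r2_threshold``; connected
    components whose circular positional extent reaches
    ``extent_fraction_min`` of the molecule length are reported.
    """
    from .iohap import MT_LENGTH

    length = mt_length or MT_LENGTH
    maf = matrix.maf()
    common = np.flatnonzero(maf >= maf_min)
    if common.size == 0:
        return []
    calls = np.where(matrix.calls == MISSING, 0, matrix.calls)[:, common].astype(float)
    r2 = _pairwise_r2(calls)
    np.fill_diagonal(r2, 0.0)
    adj = sparse.csr_matrix(np.nan_to_num(r2) >= r2_threshold)
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    out = []
    pos_all = matrix.positions
    for comp in range(n_comp):
        members = common[labels == comp]
        if members.size < 2:
            continue
        pos = pos_all[members]
        extent = _positional_extent(pos, length)
        frac = extent / length
        if frac >= extent_fraction_min:
            out.append(
                SpanningHaplotype(
                    members=tuple(int(m) for m in members),
                    positions=tuple(int(p) for p in pos),
                    extent_bp=extent,
                    extent_fraction=frac,
                )
            )
    return sorted(out, key=lambda s: s.positions)


def dloop_untagged_enrichment(
    tag_table: pd.DataFrame, annotation: RegionAnnotation
) -> tuple[float, float]:
    """Fisher's exact test of (untagged?) x (in region?) for common variants.

    Returns (sample odds ratio, two-sided p).  An empty margin makes the
    odds ratio undefined (inf or NaN), which is passed through unchanged.
    """
    in_region = np.asarray(annotation.contains(tag_table["position"].to_numpy()))
    untagged = tag_table["untagged"].to_numpy(bool)
    if in_region.all() or (~in_region).all():
        raise ValueError("need at least one variant inside and outside the region")
    table = [
        [int((untagged & in_region).sum()), int((untagged & ~in_region).sum())],
        [int((~untagged & in_region).sum()), int((~untagged & ~in_region).sum())],
    ]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p)
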