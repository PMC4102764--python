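"""Ligand-induced change calling on count data from two nascent-RNA libraries.

Each region's reads in the treated library are tested against the pooled
(vehicle + treated) reads with a two-sided exact binomial test whose null
success probability is the treated library's share of the total depth
(equivalently, a conditional Poisson test for equal depth-normalized
rates).  P-values are Benjamini-Hochberg adjusted across all tested
regions, and a region is called up (down) when its depth-normalized fold
change strictly exceeds ``min_fold`` (falls below ``1/min_fold``) and its
q-value is strictly below ``max_fdr`` - the "FDR < 0.1 and more than
twofold" rule.

Replicates, when present, are expected to be summed into one track per
condition before counting.  For a time course, each later timepoint is
tested against t0; see :func:`call_changes_timecourse`.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, StrandedCoverage, ValidationError

FOLD_CHANGE_MIN = 2.0
FDR_MAX = 0.1
#: pseudocount applied to both conditions for fold-change computation only
PSEUDOCOUNT = 1.0


def count_region_reads(
    cov: StrandedCoverage,
    regions: Sequence[GenomicInterval],
    strand_mode: str = "match",
) -> np.ndarray:
    """Summed per-base coverage within each region.

    ``strand_mode="match"`` counts the region's own strand (which must
    then be + or -); ``"both"`` sums the two strands and is the mode used
    for divergent sites.
    """
    if strand_mode not in ("match", "both"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    out = np.zeros(len(regions), dtype=np.float64)
    for i, region in enumerate(regions):
        size = cov.chrom_sizes.get(region.chrom)
        if size is None or region.end > size:
            raise ValidationError(f"region outside chromosome: {region}")
        if strand_mode == "match":
            if region.strand not in ("+", "-"):
                raise ValidationError(
                    f"strand_mode='match' needs a stranded region: {region}"
                )
            strands = (region.strand,)
        else:
            strands = ("+", "-")
        out[i] = sum(
            float(cov.vector(region.chrom, s)[region.start : region.end]
                  .sum(dtype=np.float64))
            for s in strands
        )
    return out


def median_ratio_size_factor(
    counts_vehicle: Sequence[float], counts_ligand: Sequence[float]
) -> float:
    """Median-of-ratios depth factor: ligand depth relative to vehicle.

    Equal-depth libraries under strong induction are compositionally
    shifted: unchanged regions lose count share to induced ones.  The
    median per-region count ratio over regions observed in both
    conditions estimates the relative effective depth under the
    assumption that most regions are unchanged.  Multiply the vehicle
    library size by this factor to get the effective ligand library size.
    """
    cv = np.asarray(counts_vehicle, dtype=np.float64)
    cl = np.asarray(counts_ligand, dtype=np.float64)
    both = (cv > 0) & (cl > 0)
    if not both.any():
        return 1.0
    return float(np.median(cl[both] / cv[both]))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Standard step-up BH adjustment; input order preserved in the output.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=np.float64)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _binom_p(k: int, n: int, p0: float) -> float:
    if n == 0:
        return 1.0
    return stats.binomtest(k, n, p0, alternative="two-sided").pvalue


def call_changes(
    counts_vehicle: Sequence[float],
    counts_ligand: Sequence[float],
    lib_vehicle: float,
    lib_ligand: float,
    min_fold: float = FOLD_CHANGE_MIN,
    max_fdr: float = FDR_MAX,
    region_ids: Optional[Sequence[str]] = None,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> pd.DataFrame:
    """Two-library differential calling over a set of regions.

    Returns one row per region with raw and per-million-normalized counts,
    the pseudocounted depth-normalized log2 fold change, the binomial
    p-value, the BH q-value and a status in {up, down, unchanged}.
    Zero-count regions get p = 1 by convention.
    """
    cv = np.asarray(counts_vehicle, dtype=np.float64)
    cl = np.asarray(counts_ligand, dtype=np.float64)
    if cv.shape != cl.shape:
        raise ValidationError("count vectors must have equal length")
    if np.any(cv < 0) or np.any(cl < 0):
        raise ValidationError("counts must be nonnegative")
    if lib_vehicle <= 0 or lib_ligand <= 0:
        raise ValidationError("library sizes must be positive")
    n = cv.size
    ids = list(region_ids) if region_ids is not None else [f"region_{i}" for i in range(n)]
    if len(ids) != n:
        raise ValidationError("region_ids length mismatch")

    p0 = lib_ligand / (lib_vehicle + lib_ligand)
    kv = np.rint(cv).astype(np.int64)
    kl = np.rint(cl).astype(np.int64)
    pvals = np.array(
        [_binom_p(int(kl[i]), int(kv[i] + kl[i]), p0) for i in range(n)]
    )
    qvals = benjamini_hochberg(pvals) if n else np.array([])

    norm_v = cv / lib_vehicle * 1e6
    norm_l = cl / lib_ligand * 1e6
    fold = ((cl + PSEUDOCOUNT) / lib_ligand) / ((cv + PSEUDOCOUNT) / lib_vehicle)
    log2fc = np.log2(fold)

    status = np.full(n, "unchanged", dtype=object)
    signif = qvals < max_fdr if n else np.array([], dtype=bool)
    zero = (kv + kl) == 0
    up = signif & (fold > min_fold) & ~zero
    down = signif & (fold < 1.0 / min_fold) & ~zero
    status[up] = "up"
    status[down] = "down"

    df = pd.DataFrame(
        {
            "region_id": ids,
            "count_vehicle": cv,
            "count_ligand": cl,
            "norm_vehicle": norm_v,
            "norm_ligand": norm_l,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "status": status,
        }
    )
    if regions is not None:
        if len(regions) != n:
            raise ValidationError("regions length mismatch")
        df.insert(1, "chrom", [r.chrom for r in regions])
        df.insert(2, "start", [r.start for r in regions])
        df.insert(3, "end", [r.end for r in regions])
        df.insert(4, "strand", [r.strand for r in regions])
    return df


def call_changes_timecourse(
    counts_by_timepoint: Sequence[Sequence[float]],
    lib_by_timepoint: Sequence[float],
    min_fold: float = FOLD_CHANGE_MIN,
    max_fdr: float = FDR_MAX,
    region_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Flag regions changing at any post-treatment timepoint relative to t0.

    Each timepoint after the first is tested against the first with
    :func:`call_changes`; a region is changing when any timepoint passes,
    and its reported sign and statistics are those of the most significant
    timepoint.
    """
    if len(counts_by_timepoint) < 2:
        raise ValidationError("need a t0 and at least one later timepoint")
    if len(lib_by_timepoint) != len(counts_by_timepoint):
        raise ValidationError("one library size per timepoint required")
    per_tp = [
        call_changes(
            counts_by_timepoint[0],
            counts_by_timepoint[t],
            lib_by_timepoint[0],
            lib_by_timepoint[t],
            min_fold=min_fold,
            max_fdr=max_fdr,
            region_ids=region_ids,
        )
        for t in range(1, len(counts_by_timepoint))
    ]
    n = len(per_tp[0])
    best_rows = []
    for i in range(n):
        rows = [df.iloc[i] for df in per_tp]
        changing = [r for r in rows if r["status"] != "unchanged"]
        pick = min(
            changing if changing else rows, key=lambda r: (r["p_value"], -abs(r["log2_fold_change"]))
        )
        row = pick.copy()
        row["status"] = pick["status"] if changing else "unchanged"
        best_rows.append(row)
    out = pd.DataFrame(best_rows).reset_index(drop=True)
    out["timepoint"] = [
        1 + min(range(len(per_tp)), key=lambda t: per_tp[t].iloc[i]["p_value"])
        for i in range(n)
    ]
    return out
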