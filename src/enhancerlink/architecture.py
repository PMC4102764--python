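"""CTCF/cohesin co-peak boundaries and functional domains.

Sites where CTCF and the cohesin subunit RAD21 co-occur with similarly
high occupancy (caller score > 15 on both, score ratio < 3) are treated
as boundaries of functional domains.  Boundaries are paired left-to-right
with the closest score-similar partner to form domains; neighboring
domains separated by < 100 kb are merged into active domains; regulated
genes and their enhancers are then located within the merged domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, ValidationError

BOUNDARY_MIN_SCORE = 15.0
SCORE_RATIO_LIMIT = 3.0
DOMAIN_MERGE_GAP_BP = 100_000


@dataclass
class Boundary:
    """Intersection of a CTCF peak and a RAD21 peak at one site."""

    interval: GenomicInterval
    ctcf_score: float
    rad21_score: float

    @property
    def combined_score(self) -> float:
        return min(self.ctcf_score, self.rad21_score)

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class FunctionalDomain:
    """Interval spanning the midpoints of two paired boundaries."""

    interval: GenomicInterval
    left: Boundary
    right: Boundary

    @property
    def length(self) -> int:
        return self.interval.length


def _score_ratio(a: float, b: float) -> float:
    lo, hi = min(a, b), max(a, b)
    if lo <= 0:
        return np.inf
    return hi / lo


def call_boundaries(
    ctcf_peaks: Sequence[Peak],
    rad21_peaks: Sequence[Peak],
    min_score: float = BOUNDARY_MIN_SCORE,
    ratio_limit: float = SCORE_RATIO_LIMIT,
) -> List[Boundary]:
    """Overlapping CTCF/RAD21 co-peaks with similarly high scores.

    Both scores must strictly exceed ``min_score`` and their ratio must be
    strictly below ``ratio_limit``.  A CTCF peak overlapping several RAD21
    peaks pairs with the largest-overlap one (ties leftmost).
    """
    by_chrom: Dict[str, List[Peak]] = {}
    for p in rad21_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for peaks in by_chrom.values():
        peaks.sort(key=lambda p: p.interval.start)

    boundaries: List[Boundary] = []
    for cp in ctcf_peaks:
        cands = by_chrom.get(cp.interval.chrom, [])
        best: Optional[Peak] = None
        best_bp = 0
        for rp in cands:
            bp = cp.interval.overlap_bp(rp.interval)
            if bp > best_bp:  # strict: ties keep the leftmost (first seen)
                best, best_bp = rp, bp
        if best is None:
            continue
        if cp.score <= min_score or best.score <= min_score:
            continue
        if _score_ratio(cp.score, best.score) >= ratio_limit:
            continue
        inter = GenomicInterval(
            cp.interval.chrom,
            max(cp.interval.start, best.interval.start),
            min(cp.interval.end, best.interval.end),
        )
        boundaries.append(Boundary(inter, cp.score, best.score))
    boundaries.sort(key=lambda b: (b.interval.chrom, b.midpoint))
    return boundaries


def pair_domains(
    boundaries: Sequence[Boundary],
    ratio_limit: float = SCORE_RATIO_LIMIT,
) -> Tuple[List[FunctionalDomain], List[Boundary]]:
    """Pair each boundary with the closest score-similar one to its right.

    Scanning left to right per chromosome, an unconsumed boundary pairs
    with the nearest unconsumed boundary to its right whose combined-score
    ratio (larger/smaller) is strictly below ``ratio_limit``; both are
    consumed.  Boundaries skipped inside a formed domain are retired
    unpaired - pairing them later would produce overlapping domains.
    Returns (domains, unpaired boundaries); domains are pairwise disjoint.
    """
    by_chrom: Dict[str, List[Boundary]] = {}
    for b in boundaries:
        by_chrom.setdefault(b.interval.chrom, []).append(b)
    domains: List[FunctionalDomain] = []
    free: List[Boundary] = []
    for chrom in sorted(by_chrom):
        bs = sorted(by_chrom[chrom], key=lambda b: b.midpoint)
        consumed = [False] * len(bs)
        i = 0
        while i < len(bs):
            if consumed[i]:
                i += 1
                continue
            partner = None
            for j in range(i + 1, len(bs)):
                if consumed[j]:
                    continue
                if _score_ratio(bs[i].combined_score, bs[j].combined_score) < ratio_limit:
                    partner = j
                    break
            if partner is None:
                free.append(bs[i])
                consumed[i] = True
            else:
                left, right = bs[i], bs[partner]
                if right.midpoint <= left.midpoint:
                    free.append(left)
                    consumed[i] = True
                else:
                    domains.append(
                        FunctionalDomain(
                            GenomicInterval(chrom, left.midpoint, right.midpoint),
                            left,
                            right,
                        )
                    )
                    # retire skipped boundaries: they cannot pair without overlap
                    for j in range(i + 1, partner):
                        if not consumed[j]:
                            free.append(bs[j])
                            consumed[j] = True
                    consumed[i] = consumed[partner] = True
            i += 1
    domains.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return domains, free


def merge_active_domains(
    domains: Sequence[FunctionalDomain],
    max_gap_bp: int = DOMAIN_MERGE_GAP_BP,
) -> List[GenomicInterval]:
    """Transitively merge consecutive domains separated by < ``max_gap_bp``.

    The merged interval runs from the first left boundary midpoint to the
    last right boundary midpoint.  Idempotent: merging the result again
    changes nothing.
    """
    by_chrom: Dict[str, List[FunctionalDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: d.interval.start)
        cur_start, cur_end = ds[0].interval.start, ds[0].interval.end
        for d in ds[1:]:
            gap = d.interval.start - cur_end
            if gap < max_gap_bp:  # strict
                cur_end = max(cur_end, d.interval.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = d.interval.start, d.interval.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def domain_length_stats(intervals: Sequence[GenomicInterval]) -> Dict[str, float]:
    lengths = np.array([iv.length for iv in intervals], dtype=np.float64)
    if lengths.size == 0:
        return {"n": 0, "median_bp": 0.0, "mean_bp": 0.0}
    return {
        "n": int(lengths.size),
        "median_bp": float(np.median(lengths)),
        "mean_bp": float(lengths.mean()),
    }


def assign_to_domains(
    gene_features: Sequence[Tuple[str, GenomicInterval, Sequence[GenomicInterval]]],
    merged_domains: Sequence[GenomicInterval],
) -> Tuple[pd.DataFrame, float]:
    """Per-gene domain residency of a gene and its regulatory regions.

    ``gene_features`` holds (gene_id, gene interval with strand, list of
    assigned regulatory-region intervals).  A gene is inside iff its TSS
    and ALL of its regions lie within a single merged domain; a gene with
    no regions is counted by TSS membership alone.  Returns the per-gene
    table and the fraction inside.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for d in merged_domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    rows = []
    for gene_id, giv, regions in gene_features:
        tss = giv.start if giv.strand == "+" else giv.end - 1
        inside = False
        for d in by_chrom.get(giv.chrom, []):
            if not (d.start <= tss < d.end):
                continue
            if all(
                r.chrom == d.chrom and r.start >= d.start and r.end <= d.end
                for r in regions
            ):
                inside = True
                break
        rows.append({"gene_id": gene_id, "n_regions": len(regions), "inside": inside})
    df = pd.DataFrame(rows, columns=["gene_id", "n_regions", "inside"])
    fraction = float(df["inside"].mean()) if len(df) else 0.0
    return df, fraction
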