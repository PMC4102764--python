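"""Peak-set integration for a signal-factor cistrome.

Overlap reports between cistromes, classification of binding sites into
GRO-seq-positive (overlapping a divergent transcription site, hence
active) versus GRO-seq-negative (silent/parking), summit-centered
coverage profiles, distances to the closest gene TSS, and targeted
scanning for direct repeats (DR0-DR5) of the nuclear-receptor half-site
AGGTCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    DivergentSite,
    GeneModel,
    GenomicInterval,
    Peak,
    StrandedCoverage,
    ValidationError,
)

HALF_SITE = "AGGTCA"
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class OverlapReport:
    pairs: List[Tuple[int, int, int]]  # (index in a, index in b, overlap bp)
    a_only: int
    b_only: int
    a_and_b: int  # a-side peaks overlapping >=1 b peak


@dataclass
class ClassifiedPeak:
    peak: Peak
    gro_class: str  # "positive" | "negative"
    matched_site: Optional[DivergentSite] = None

    def __post_init__(self):
        if (self.gro_class == "positive") != (self.matched_site is not None):
            raise ValidationError(
                "gro_class positive iff a matched divergent site is present"
            )


@dataclass
class MotifHit:
    interval: GenomicInterval
    repeat_class: str  # "DR0".."DR5"
    strand: str  # strand of the first half-site
    mismatches: Tuple[int, int]


def _tree_of(peaks: Sequence[Peak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    return trees


def overlap_peaks(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap_bp: int = 1
) -> OverlapReport:
    """All (a, b) peak pairs sharing at least ``min_overlap_bp`` bases.

    Venn counts are taken on a's side: an a-peak overlapping any number of
    b-peaks counts once toward the intersection.
    """
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    trees = _tree_of(b)
    pairs: List[Tuple[int, int, int]] = []
    a_hit = 0
    b_hit: set = set()
    for i, pa in enumerate(a):
        tree = trees.get(pa.interval.chrom)
        found = False
        if tree is not None:
            for iv in sorted(tree.overlap(pa.interval.start, pa.interval.end)):
                bp = min(pa.interval.end, iv.end) - max(pa.interval.start, iv.begin)
                if bp >= min_overlap_bp:
                    pairs.append((i, iv.data, bp))
                    b_hit.add(iv.data)
                    found = True
        if found:
            a_hit += 1
    return OverlapReport(
        pairs=pairs,
        a_only=len(a) - a_hit,
        b_only=len(b) - len(b_hit),
        a_and_b=a_hit,
    )


def classify_by_gro(
    peaks: Sequence[Peak], sites: Sequence[DivergentSite]
) -> List[ClassifiedPeak]:
    """Label each peak positive iff it overlaps >=1 divergent-site interval.

    The partition is exhaustive and exclusive; when a peak overlaps several
    sites the leftmost-starting one is recorded as the match.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, s in enumerate(sites):
        trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end, i
        )
    out: List[ClassifiedPeak] = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        hits = (
            sorted(tree.overlap(p.interval.start, p.interval.end),
                   key=lambda iv: (iv.begin, iv.data))
            if tree is not None
            else []
        )
        if hits:
            out.append(ClassifiedPeak(p, "positive", sites[hits[0].data]))
        else:
            out.append(ClassifiedPeak(p, "negative", None))
    assert sum(c.gro_class == "positive" for c in out) + sum(
        c.gro_class == "negative" for c in out
    ) == len(peaks)
    return out


def summit_profile(
    peaks: Sequence[Peak],
    cov: StrandedCoverage,
    window_bp: int = 3000,
    bin_bp: int = 25,
) -> Tuple[np.ndarray, np.ndarray]:
    """Binned coverage in a fixed window around each peak summit.

    Row i covers ``[summit - window/2, summit + window/2)`` in ``bin_bp``
    bins, summing both strands; bins falling outside the chromosome are 0.
    Returns the (peaks x bins) matrix and the column-mean profile.
    """
    if window_bp % bin_bp != 0 or (window_bp // bin_bp) % 2 != 0:
        raise ValidationError("window must be an even multiple of the bin size")
    n_bins = window_bp // bin_bp
    mat = np.zeros((len(peaks), n_bins), dtype=np.float64)
    half = window_bp // 2
    for i, p in enumerate(peaks):
        chrom = p.interval.chrom
        size = cov.chrom_sizes.get(chrom)
        if size is None:
            raise ValidationError(f"peak {p.name}: unknown chromosome {chrom}")
        center = p.summit_pos
        combined = cov.vector(chrom, "+") + cov.vector(chrom, "-")
        w_start = center - half
        for b in range(n_bins):
            s = w_start + b * bin_bp
            e = s + bin_bp
            s_clip, e_clip = max(0, s), min(size, e)
            if s_clip < e_clip:
                mat[i, b] = combined[s_clip:e_clip].sum(dtype=np.float64)
    return mat, mat.mean(axis=0) if len(peaks) else np.zeros(n_bins)


def tss_distance_stats(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    near_bp: int = 10_000,
) -> Tuple[pd.DataFrame, float]:
    """Signed distance from each peak midpoint to the closest gene TSS.

    The sign is gene-strand-oriented: negative means upstream of the gene.
    Closest is by absolute distance, ties broken toward the
    lexicographically smaller gene_id.  Also returns the fraction of peaks
    whose absolute distance exceeds ``near_bp``.
    """
    if not genes:
        raise ValidationError("gene list must be nonempty")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    tss_sorted = {
        chrom: sorted(gs, key=lambda g: (g.tss, g.gene_id))
        for chrom, gs in by_chrom.items()
    }
    rows = []
    for p in peaks:
        mid = p.interval.midpoint
        cands = tss_sorted.get(p.interval.chrom)
        if cands is None:
            raise ValidationError(
                f"peak {p.name}: no genes on chromosome {p.interval.chrom}"
            )
        positions = [g.tss for g in cands]
        k = int(np.searchsorted(positions, mid))
        cand_idx = set()
        for j in (k - 1, k):
            if 0 <= j < len(cands):
                # leftmost gene of a run of identical TSSs has the smallest id
                cand_idx.add(int(np.searchsorted(positions, positions[j], "left")))
        best = min(
            (cands[j] for j in cand_idx),
            key=lambda g: (abs(mid - g.tss), g.gene_id),
        )
        signed = mid - best.tss if best.interval.strand == "+" else best.tss - mid
        rows.append(
            {
                "peak": p.name,
                "chrom": p.interval.chrom,
                "midpoint": mid,
                "gene_id": best.gene_id,
                "distance": signed,
            }
        )
    df = pd.DataFrame(rows, columns=["peak", "chrom", "midpoint", "gene_id", "distance"])
    frac_beyond = (
        float((df["distance"].abs() > near_bp).mean()) if len(df) else 0.0
    )
    return df, frac_beyond


def _mismatches(seq: str, pattern: str) -> int:
    # N never matches
    return sum(1 for a, b in zip(seq, pattern) if a != b or a == "N")


def scan_dr_repeats(
    sequence: str,
    half_site: str = HALF_SITE,
    max_mismatch_per_half: int = 1,
    spacers: Iterable[int] = range(0, 6),
    chrom: str = "seq",
) -> List[MotifHit]:
    """Scan for direct repeats of a nuclear-receptor half-site.

    For each strand and spacer n in ``spacers``, report every window where
    both 6-mers match ``half_site`` with at most ``max_mismatch_per_half``
    mismatches each (``N`` never matches).  DR_n hits are
    ``2*len(half) + n`` long; coordinates are on the forward strand, and
    ``strand`` records the strand carrying the repeat.  Overlapping hits
    of different spacer classes are all reported.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValidationError("sequence must be over the alphabet {A,C,G,T,N}")
    half_len = len(half_site)
    hits: List[MotifHit] = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for spacer in spacers:
            w = 2 * half_len + spacer
            for i in range(0, L - w + 1):
                m1 = _mismatches(s[i : i + half_len], half_site)
                if m1 > max_mismatch_per_half:
                    continue
                m2 = _mismatches(s[i + half_len + spacer : i + w], half_site)
                if m2 > max_mismatch_per_half:
                    continue
                if strand == "+":
                    start = i
                else:
                    start = L - (i + w)
                hits.append(
                    MotifHit(
                        GenomicInterval(chrom, start, start + w, strand),
                        f"DR{spacer}",
                        strand,
                        (m1, m2),
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.repeat_class, h.strand))
    return hits
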