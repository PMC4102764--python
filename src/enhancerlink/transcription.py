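"""Transcript-unit calling, RPKM, divergent-site detection.

The caller segments each strand of a nascent-transcription (GRO-seq-style)
coverage track into maximal nonzero runs, bridges short zero gaps, and
filters on length and RPKM.  Divergent sites pair opposite-strand units
whose 5' ends lie within a maximum distance and point away from each
other; such sites mark active promoters and enhancers.

Two thresholds carry the biology and are exposed as parameters: the
genome-wide expression floor (0.006 RPKM) used when measuring the
transcribed fraction of the genome, and the site floor (0.2 RPKM) used
when calling divergent sites.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import (
    DivergentSite,
    GenomicInterval,
    StrandedCoverage,
    TranscriptUnit,
    ValidationError,
    merge_intervals,
)

#: Expression floor below which the genome is considered untranscribed.
GENOME_RPKM_FLOOR = 0.006
#: Expression floor for a divergent site (on the stronger of the two units).
SITE_RPKM_FLOOR = 0.2
#: Maximum distance between the two 5' ends of a divergent site (strict).
SITE_MAX_GAP_BP = 300


def rpkm(read_count: float, length_bp: int, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    return read_count / ((length_bp / 1e3) * (library_size / 1e6))


def _runs_with_gaps(mask: np.ndarray, max_gap_bp: int) -> List[Tuple[int, int]]:
    """Maximal nonzero runs of ``mask``, merging runs separated by short gaps."""
    nz = np.flatnonzero(mask)
    if nz.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(nz) > max_gap_bp + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [nz.size - 1]))
    return [(int(nz[s]), int(nz[e]) + 1) for s, e in zip(starts, ends)]


def call_transcript_units(
    cov: StrandedCoverage,
    library_size: float,
    min_rpkm: float = GENOME_RPKM_FLOOR,
    min_length_bp: int = 50,
    max_gap_bp: int = 50,
) -> List[TranscriptUnit]:
    """Segment both strands of a coverage track into transcript units.

    Per strand, maximal runs of nonzero coverage are merged when separated
    by at most ``max_gap_bp`` bases of zero signal, then discarded when
    shorter than ``min_length_bp`` or below ``min_rpkm``.  Units on
    opposite strands may overlap freely.
    """
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    units: List[TranscriptUnit] = []
    for chrom in cov.chrom_sizes:
        for strand in ("+", "-"):
            vec = cov.vector(chrom, strand)
            for start, end in _runs_with_gaps(vec != 0, max_gap_bp):
                length = end - start
                if length < min_length_bp:
                    continue
                count = float(vec[start:end].sum(dtype=np.float64))
                value = rpkm(count, length, library_size)
                if value < min_rpkm:
                    continue
                units.append(
                    TranscriptUnit(
                        GenomicInterval(chrom, start, end, strand), count, value
                    )
                )
    return units


def transcribed_fraction(
    units: Sequence[TranscriptUnit], chrom_sizes: Dict[str, int]
) -> float:
    """Fraction of the genome covered by the union of units on both strands."""
    total = sum(chrom_sizes.values())
    if total <= 0:
        raise ValidationError("empty genome")
    for u in units:
        size = chrom_sizes.get(u.interval.chrom)
        if size is None or u.interval.end > size:
            raise ValidationError(f"unit outside genome: {u.interval}")
    covered = sum(
        e - s
        for _, s, e in merge_intervals(
            (u.interval.chrom, u.interval.start, u.interval.end) for u in units
        )
    )
    return covered / total


def _check_sorted(units: Sequence[TranscriptUnit], label: str) -> None:
    keys = [(u.interval.chrom, u.interval.start) for u in units]
    if keys != sorted(keys):
        raise ValidationError(f"{label} unit list must be sorted by coordinate")


def detect_divergent_sites(
    plus_units: Sequence[TranscriptUnit],
    minus_units: Sequence[TranscriptUnit],
    max_gap_bp: int = SITE_MAX_GAP_BP,
    min_rpkm: float = SITE_RPKM_FLOOR,
    require_both: bool = False,
) -> List[DivergentSite]:
    """Pair divergently oriented units into initiation sites.

    A (minus, plus) pair on one chromosome qualifies when the plus unit's
    5' end lies at, or to the right of, the minus unit's 5' end (the two
    transcripts point away from a common center), the distance between the
    5' ends is strictly below ``max_gap_bp``, and the stronger unit's RPKM
    strictly exceeds ``min_rpkm`` (both units when ``require_both``).
    Each unit joins at most one site; pairs are chosen greedily by
    smallest gap, ties broken leftmost.  The site interval spans the two
    5' ends.
    """
    for units, strand, label in ((plus_units, "+", "plus"), (minus_units, "-", "minus")):
        _check_sorted(units, label)
        for u in units:
            if u.interval.strand != strand:
                raise ValidationError(f"{label} list contains a {u.interval.strand} unit")

    candidates: List[Tuple[int, int, int, int]] = []  # (gap, site_start, mi, pi)
    plus_by_chrom: Dict[str, List[int]] = {}
    for pi, pu in enumerate(plus_units):
        plus_by_chrom.setdefault(pu.interval.chrom, []).append(pi)
    for chrom, pidx in plus_by_chrom.items():
        p5 = np.array([plus_units[pi].five_prime for pi in pidx])
        order = np.argsort(p5, kind="stable")
        p5_sorted = p5[order]
        for mi, mu in enumerate(minus_units):
            if mu.interval.chrom != chrom:
                continue
            m5 = mu.five_prime
            lo = int(np.searchsorted(p5_sorted, m5, side="left"))
            hi = int(np.searchsorted(p5_sorted, m5 + max_gap_bp, side="left"))
            for k in range(lo, hi):
                pi = pidx[int(order[k])]
                pu = plus_units[pi]
                gap = pu.five_prime - m5
                if require_both:
                    ok = min(pu.rpkm, mu.rpkm) > min_rpkm
                else:
                    ok = max(pu.rpkm, mu.rpkm) > min_rpkm
                if ok:
                    candidates.append((gap, m5, mi, pi))

    candidates.sort()
    used_plus: set = set()
    used_minus: set = set()
    sites: List[DivergentSite] = []
    for gap, m5, mi, pi in candidates:
        if pi in used_plus or mi in used_minus:
            continue
        used_plus.add(pi)
        used_minus.add(mi)
        pu, mu = plus_units[pi], minus_units[mi]
        site_iv = GenomicInterval(pu.interval.chrom, m5, pu.five_prime + 1)
        sites.append(
            DivergentSite(
                site_iv, pu, mu, gap, max(pu.rpkm, mu.rpkm), name=""
            )
        )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    for i, s in enumerate(sites):
        s.name = f"ds_{i}"
    return sites
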