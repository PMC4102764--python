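"""Shared coordinate model.

All coordinates in the package are 0-based, half-open ``[start, end)``,
the native convention of BED and bedGraph.  GTF input (1-based, closed) is
converted at the I/O boundary.  Strand is one of ``+``, ``-`` or ``.``;
``.`` is permitted on peaks only, never on transcripts, because nascent
transcription is intrinsically stranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an input violates the coordinate or format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chromosome name must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        return self.overlap_bp(other) >= min_overlap_bp


@dataclass
class Peak:
    """A scored interval from a peak caller (MACS2-score semantics).

    ``summit`` is an offset within the interval; when a caller does not
    report one, the interval midpoint is used.
    """

    interval: GenomicInterval
    name: str
    score: float = 0.0
    summit: Optional[int] = None

    def __post_init__(self):
        if self.score < 0:
            raise ValidationError(f"peak {self.name}: negative score {self.score}")
        if self.summit is not None and not (
            0 <= self.summit < self.interval.length
        ):
            raise ValidationError(
                f"peak {self.name}: summit offset {self.summit} outside interval"
            )

    @property
    def summit_pos(self) -> int:
        """Absolute genomic position of the summit."""
        if self.summit is None:
            return self.interval.midpoint
        return self.interval.start + self.summit


@dataclass
class GeneModel:
    """A gene as a stranded span with a single transcription start site."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got "
                f"{self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class TranscriptUnit:
    """A called transcribed interval on one strand.

    ``read_count`` is the summed per-base coverage within the interval;
    ``rpkm = read_count / ((length/1e3) * (library_size/1e6))``.
    """

    interval: GenomicInterval
    read_count: float
    rpkm: float

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValidationError("transcript units must be stranded")

    @property
    def five_prime(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class DivergentSite:
    """A pair of opposite-strand transcripts initiating away from each other.

    The site interval spans the two 5' ends (1 bp if they coincide); the
    ``span`` property covers both transcript bodies and is what carries the
    eRNA signal.
    """

    interval: GenomicInterval
    plus_unit: TranscriptUnit
    minus_unit: TranscriptUnit
    gap: int
    max_rpkm: float
    name: str = ""

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.interval.chrom,
            min(self.minus_unit.interval.start, self.plus_unit.interval.start),
            max(self.minus_unit.interval.end, self.plus_unit.interval.end),
        )


class StrandedCoverage:
    """Dense per-base, per-strand read coverage for one library.

    One float64 vector per chromosome and strand; ``total()`` is the
    library's coverage mass (equals the read count when each read deposits
    one unit of coverage).
    """

    def __init__(self, chrom_sizes: Dict[str, int]):
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        self.data: Dict[str, Dict[str, np.ndarray]] = {
            chrom: {
                "+": np.zeros(size, dtype=np.float64),
                "-": np.zeros(size, dtype=np.float64),
            }
            for chrom, size in self.chrom_sizes.items()
        }

    def vector(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    def add_record(self, chrom: str, start: int, end: int, value: float, strand: str):
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= size):
            raise ValidationError(
                f"record {chrom}:{start}-{end} outside chromosome of length {size}"
            )
        self.data[chrom][strand][start:end] += value

    def total(self, strand: Optional[str] = None) -> float:
        strands = [strand] if strand else ["+", "-"]
        return float(
            sum(self.data[c][s].sum(dtype=np.float64)
                for c in self.data for s in strands)
        )

    def pooled_with(self, other: "StrandedCoverage") -> "StrandedCoverage":
        """Base-wise sum of two libraries over identical chromosomes."""
        if self.chrom_sizes != other.chrom_sizes:
            raise ValidationError("cannot pool coverage over different genomes")
        out = StrandedCoverage(self.chrom_sizes)
        for c in self.data:
            for s in ("+", "-"):
                out.data[c][s] = self.data[c][s] + other.data[c][s]
        return out


def merge_intervals(
    intervals: Iterable[Tuple[str, int, int]]
) -> List[Tuple[str, int, int]]:
    """Union of (chrom, start, end) triples as a sorted, disjoint list."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    out: List[Tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        merged: List[List[int]] = []
        for start, end in sorted(by_chrom[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out.extend((chrom, s, e) for s, e in merged)
    return out
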