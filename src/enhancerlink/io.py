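"""Readers and writers for the standard formats the pipeline touches.

BED and bedGraph are consumed as written (0-based half-open); GTF (1-based
closed) is converted to the internal convention on read.  All tabular
outputs are TSV with a one-line ``#``-prefixed header.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import gffutils
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    StrandedCoverage,
    ValidationError,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed input lines; names the offending line number."""


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad size") from exc
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: PathLike) -> List[Peak]:
    """Read BED3/BED5/BED6 peaks; column 7, when present, is a summit offset.

    Missing score -> 0; missing name -> ``peak_<n>``; input order preserved.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak_{len(peaks)}"
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            summit: Optional[int] = None
            if len(fields) > 6 and fields[6] not in ("", "."):
                try:
                    summit = int(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad summit") from exc
            peaks.append(
                Peak(GenomicInterval(fields[0], start, end, strand), name, score, summit)
            )
    return peaks


def write_bed(peaks: Sequence[Peak], path: PathLike) -> None:
    """Write peaks as BED with name, score, strand and summit-offset columns."""
    with open(path, "w") as fh:
        for p in peaks:
            summit = "." if p.summit is None else str(p.summit)
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}"
                f"\t{iv.strand}\t{summit}\n"
            )


def _read_bedgraph_into(
    cov: StrandedCoverage, path: PathLike, strand: str
) -> None:
    seen = {c: [] for c in cov.chrom_sizes}
    overlap_warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad record") from exc
            chrom = fields[0]
            if chrom not in cov.chrom_sizes:
                raise ValidationError(f"{path}: line {lineno}: unknown chrom {chrom}")
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: start >= end")
            if end > cov.chrom_sizes[chrom]:
                raise ValidationError(
                    f"{path}: line {lineno}: record beyond end of {chrom}"
                )
            if not overlap_warned:
                for s, e in seen[chrom]:
                    if start < e and s < end:
                        warnings.warn(
                            f"{path}: overlapping bedGraph records; values are summed",
                            stacklevel=3,
                        )
                        overlap_warned = True
                        break
                seen[chrom].append((start, end))
            cov.add_record(chrom, start, end, value, strand)


def read_bedgraph_pair(
    plus_path: PathLike, minus_path: PathLike, chrom_sizes: Dict[str, int]
) -> StrandedCoverage:
    """Build dense stranded coverage from a plus/minus bedGraph pair.

    Uncovered bases are 0; overlapping records are summed with a warning.
    """
    cov = StrandedCoverage(chrom_sizes)
    _read_bedgraph_into(cov, plus_path, "+")
    _read_bedgraph_into(cov, minus_path, "-")
    return cov


def write_bedgraph(cov: StrandedCoverage, strand: str, path: PathLike) -> None:
    """Write one strand of a coverage track, run-length-encoding equal values."""
    import numpy as np

    with open(path, "w") as fh:
        for chrom in cov.chrom_sizes:
            vec = cov.vector(chrom, strand)
            if not vec.any():
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_gtf(path: PathLike) -> List[GeneModel]:
    """Read gene models from GTF, one per gene_id spanning all its records.

    GTF 1-based closed coordinates become 0-based half-open; the TSS is the
    strand-appropriate end of the unioned span.
    """
    spans: Dict[str, List] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: unparseable GTF") from exc
            if feat.strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: line {lineno}: unknown strand {feat.strand!r}"
                )
            gene_ids = feat.attributes.get("gene_id")
            if not gene_ids:
                raise ParseError(f"{path}: line {lineno}: missing gene_id")
            gid = gene_ids[0]
            start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
            if gid in spans:
                chrom, s, e, strand = spans[gid]
                if chrom != feat.seqid or strand != feat.strand:
                    raise ValidationError(
                        f"{path}: gene {gid}: records disagree on chrom/strand"
                    )
                spans[gid] = [chrom, min(s, start0), max(e, end0), strand]
            else:
                spans[gid] = [feat.seqid, start0, end0, feat.strand]
                order.append(gid)
    return [
        GeneModel(gid, GenomicInterval(*spans[gid][:3], strand=spans[gid][3]))
        for gid in order
    ]


def write_gtf(genes: Sequence[GeneModel], path: PathLike, source: str = "enhancerlink") -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def write_tsv(df: pd.DataFrame, path: PathLike, comment: str = "") -> None:
    """Write a DataFrame as TSV with a one-line ``#``-prefixed header."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"## {comment}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (``#`` header, ``##`` comments)."""
    columns: Optional[List[str]] = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if not line.startswith("##"):
                columns = line.lstrip("#").rstrip("\n").split("\t")
            pos = fh.tell()
            line = fh.readline()
        if columns is None:
            raise ParseError(f"{path}: expected a '#'-prefixed header line")
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", header=None, names=columns)
    return df
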