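"""3C-seq-style interaction-frequency statistics at megabase resolution.

Reads anchored at one bait are mapped onto fixed 1-Mb windows tiling the
genome; per-bin counts are expressed as interaction frequencies (reads
per bin normalized so the frequencies total 1000).  Bins are classified
by regulatory content - target (contains a regulated gene or assigned
enhancer), active (inside a merged CTCF/cohesin domain but no regulated
region), else inactive - and class frequency distributions are compared
with an unpaired two-tailed Welch t-test, optionally restricted to
interchromosomal (trans) bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, ValidationError

BIN_BP = 1_000_000
FREQ_TOTAL = 1000.0
BIN_CLASSES = ("inactive", "active", "target")


@dataclass
class InteractionRecord:
    bait_id: str
    bait: GenomicInterval
    prey_chrom: str
    prey_pos: int
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValidationError("interaction count must be >= 1")


def read_interactions(path) -> List[InteractionRecord]:
    """Read (bait_id, bait_chrom, bait_start, bait_end, prey_chrom,
    prey_pos, count) rows from TSV; ``#`` lines are skipped."""
    records: List[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValidationError(f"{path}: line {lineno}: expected 7 columns")
            records.append(
                InteractionRecord(
                    fields[0],
                    GenomicInterval(fields[1], int(fields[2]), int(fields[3])),
                    fields[4],
                    int(fields[5]),
                    int(fields[6]),
                )
            )
    return records


def write_interactions(records: Sequence[InteractionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#bait_id\tbait_chrom\tbait_start\tbait_end\tprey_chrom\tprey_pos\tcount\n")
        for r in records:
            fh.write(
                f"{r.bait_id}\t{r.bait.chrom}\t{r.bait.start}\t{r.bait.end}"
                f"\t{r.prey_chrom}\t{r.prey_pos}\t{r.count}\n"
            )


def genome_bins(chrom_sizes: Dict[str, int], bin_bp: int = BIN_BP) -> pd.DataFrame:
    """Fixed windows [k*bin, (k+1)*bin) per chromosome, last one truncated."""
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_bp):
            rows.append({"chrom": chrom, "start": start, "end": min(start + bin_bp, size)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_interactions(
    records: Sequence[InteractionRecord],
    chrom_sizes: Dict[str, int],
    bin_bp: int = BIN_BP,
) -> pd.DataFrame:
    """Per-bin read counts and normalized frequencies for one bait.

    ``frequency_i = 1000 * count_i / sum(counts)``; all frequencies are 0
    (with a warning) when there are no reads.
    """
    baits = {r.bait_id for r in records}
    if len(baits) > 1:
        raise ValidationError(f"records mix baits: {sorted(baits)}")
    bins = genome_bins(chrom_sizes, bin_bp)
    counts = np.zeros(len(bins), dtype=np.float64)
    index: Dict[str, int] = {}
    offset = 0
    n_per_chrom: Dict[str, int] = {}
    for chrom, size in chrom_sizes.items():
        index[chrom] = offset
        n_per_chrom[chrom] = -(-size // bin_bp)
        offset += n_per_chrom[chrom]
    for r in records:
        size = chrom_sizes.get(r.prey_chrom)
        if size is None or not (0 <= r.prey_pos < size):
            raise ValidationError(
                f"prey position {r.prey_chrom}:{r.prey_pos} outside genome"
            )
        counts[index[r.prey_chrom] + r.prey_pos // bin_bp] += r.count
    total = counts.sum()
    if total == 0:
        warnings.warn("no interaction reads; all frequencies set to 0", stacklevel=2)
        freq = counts
    else:
        freq = FREQ_TOTAL * counts / total
    out = bins.copy()
    out["count"] = counts
    out["frequency"] = freq
    return out


def classify_bins(
    bins: pd.DataFrame,
    merged_domains: Sequence[GenomicInterval],
    target_regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Label each bin target > active > inactive (exhaustive, exclusive).

    Target: overlaps >=1 regulated region (gene or assigned enhancer).
    Active: else, overlaps >=1 merged active domain.  Inactive: neither.
    """
    def overlaps_any(row, ivs: Sequence[GenomicInterval]) -> bool:
        return any(
            iv.chrom == row["chrom"] and iv.start < row["end"] and row["start"] < iv.end
            for iv in ivs
        )

    classes = []
    for _, row in bins.iterrows():
        if overlaps_any(row, target_regions):
            classes.append("target")
        elif overlaps_any(row, merged_domains):
            classes.append("active")
        else:
            classes.append("inactive")
    out = bins.copy()
    out["bin_class"] = classes
    assert set(out["bin_class"]).issubset(BIN_CLASSES)
    return out


def compare_classes(
    bins: pd.DataFrame,
    exclude_cis_chrom: Optional[str] = None,
    equal_var: bool = False,
) -> dict:
    """Class-wise frequency summaries and pairwise two-tailed t-tests.

    Welch (unequal-variance) by default; ``equal_var=True`` gives the
    pooled-variance test.  ``exclude_cis_chrom`` drops the bait's own
    chromosome to isolate interchromosomal signal.  Comparisons with
    fewer than 2 bins on either side are skipped with a warning.
    """
    data = bins
    if exclude_cis_chrom is not None:
        data = bins[bins["chrom"] != exclude_cis_chrom]
    groups = {
        cls: data.loc[data["bin_class"] == cls, "frequency"].to_numpy(dtype=np.float64)
        for cls in BIN_CLASSES
    }
    result: dict = {"classes": {}, "comparisons": {}}
    for cls, values in groups.items():
        result["classes"][cls] = {
            "n": int(values.size),
            "mean": float(values.mean()) if values.size else float("nan"),
            "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        }
    for ca, cb in (("inactive", "active"), ("active", "target"), ("inactive", "target")):
        a, b = groups[ca], groups[cb]
        key = f"{ca}_vs_{cb}"
        if a.size < 2 or b.size < 2:
            warnings.warn(f"comparison {key} skipped: fewer than 2 bins", stacklevel=2)
            result["comparisons"][key] = None
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t_stat, p_val = 0.0, 1.0  # identical constant groups
        else:
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
        result["comparisons"][key] = {"t": float(t_stat), "p": float(p_val)}
    return result
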