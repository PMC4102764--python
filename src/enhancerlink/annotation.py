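"""Linking active, changing regulatory regions to regulated genes.

A signal-factor binding region qualifies for annotation when it is
GRO-positive (overlaps a divergent transcription site) and that site's
transcription changes upon ligand.  Each qualifying region is assigned to
the closest gene with changing expression by |region midpoint - TSS|;
concordant signs (region and gene both up, or both down) make it an
enhancer, discordant signs a silencer.  The silencer rule is the
package's declared operationalization of the enhancer/silencer split.

No distance cap is applied by default - very-long-range assignments are
the point of the method - but ``max_distance_bp`` can cap it, and
``required_domains`` can restrict assignments to pairs sharing one
CTCF/cohesin merged domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cistrome import ClassifiedPeak
from .intervals import GeneModel, GenomicInterval, ValidationError

UPSTREAM_PROXIMAL_BP = 10_000


@dataclass
class AnnotationSummary:
    enhancers: int
    silencers: int
    assigned: int
    dropped_by_cap: int
    regulated_genes: int
    enhancers_per_gene: Dict[int, int]
    fraction_upstream_10kb: float

    def as_dict(self) -> dict:
        return {
            "enhancers": self.enhancers,
            "silencers": self.silencers,
            "assigned": self.assigned,
            "dropped_by_cap": self.dropped_by_cap,
            "regulated_genes": self.regulated_genes,
            "enhancers_per_gene": {str(k): v for k, v in sorted(self.enhancers_per_gene.items())},
            "fraction_upstream_10kb": self.fraction_upstream_10kb,
        }


def _signed_distance(mid: int, gene: GeneModel) -> int:
    """Gene-strand-oriented distance; negative = upstream of the gene."""
    return mid - gene.tss if gene.interval.strand == "+" else gene.tss - mid


def _interval_within(iv: GenomicInterval, dom: GenomicInterval) -> bool:
    return iv.chrom == dom.chrom and iv.start >= dom.start and iv.end <= dom.end


def annotate(
    classified_peaks: Sequence[ClassifiedPeak],
    site_records: pd.DataFrame,
    gene_records: pd.DataFrame,
    genes: Sequence[GeneModel],
    max_distance_bp: Optional[int] = None,
    required_domains: Optional[Sequence[GenomicInterval]] = None,
) -> Tuple[pd.DataFrame, AnnotationSummary]:
    """Assign changing, GRO-positive regions to closest changing genes.

    ``site_records`` and ``gene_records`` are :func:`~enhancerlink.
    differential.call_changes` outputs indexed by ``region_id`` matching
    the matched divergent-site names and gene ids respectively.  Ties in
    distance go to the more significantly changing gene, then to the
    lexicographically smaller gene_id.  Returns one row per assignment
    plus a summary; the identity assigned = enhancers + silencers is
    asserted on every run.
    """
    if not genes:
        raise ValidationError("gene list must be nonempty")
    site_idx = site_records.set_index("region_id")
    gene_idx = gene_records.set_index("region_id")
    gene_by_id = {g.gene_id: g for g in genes}

    changing_genes = [
        g for g in genes
        if g.gene_id in gene_idx.index
        and gene_idx.loc[g.gene_id, "status"] != "unchanged"
    ]
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in changing_genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)

    rows = []
    dropped = 0
    for cp in classified_peaks:
        if cp.gro_class != "positive":
            continue
        site_id = cp.matched_site.name
        if site_id not in site_idx.index:
            raise ValidationError(
                f"region {cp.peak.name}: no differential record for site {site_id}"
            )
        srec = site_idx.loc[site_id]
        if srec["status"] == "unchanged":
            continue
        mid = cp.peak.interval.midpoint
        cands = by_chrom.get(cp.peak.interval.chrom, [])
        if required_domains is not None:
            doms = [
                d for d in required_domains
                if _interval_within(cp.peak.interval, d)
            ]
            cands = [
                g for g in cands
                if any(
                    d.start <= g.tss < d.end and d.chrom == g.interval.chrom
                    for d in doms
                )
            ]
        if not cands:
            continue
        best = min(
            cands,
            key=lambda g: (
                abs(mid - g.tss),
                gene_idx.loc[g.gene_id, "p_value"],
                g.gene_id,
            ),
        )
        distance = abs(mid - best.tss)
        if max_distance_bp is not None and distance > max_distance_bp:
            dropped += 1
            continue
        grec = gene_idx.loc[best.gene_id]
        site_sign = np.sign(srec["log2_fold_change"])
        gene_sign = np.sign(grec["log2_fold_change"])
        reg_class = "enhancer" if site_sign == gene_sign else "silencer"
        rows.append(
            {
                "region": cp.peak.name,
                "chrom": cp.peak.interval.chrom,
                "region_midpoint": mid,
                "site_id": site_id,
                "site_status": srec["status"],
                "site_log2fc": srec["log2_fold_change"],
                "gene_id": best.gene_id,
                "gene_status": grec["status"],
                "gene_log2fc": grec["log2_fold_change"],
                "reg_class": reg_class,
                "signed_distance": _signed_distance(mid, best),
            }
        )

    columns = [
        "region", "chrom", "region_midpoint", "site_id", "site_status",
        "site_log2fc", "gene_id", "gene_status", "gene_log2fc", "reg_class",
        "signed_distance",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["chrom", "region_midpoint", "region"]).reset_index(drop=True)
    n_enh = int((df["reg_class"] == "enhancer").sum())
    n_sil = int((df["reg_class"] == "silencer").sum())
    assert n_enh + n_sil == len(df)
    hist = enhancers_per_gene(df)
    upstream = (
        float(((df["signed_distance"] > -UPSTREAM_PROXIMAL_BP)
               & (df["signed_distance"] <= 0)).mean())
        if len(df)
        else 0.0
    )
    summary = AnnotationSummary(
        enhancers=n_enh,
        silencers=n_sil,
        assigned=len(df),
        dropped_by_cap=dropped,
        regulated_genes=df["gene_id"].nunique(),
        enhancers_per_gene=hist,
        fraction_upstream_10kb=upstream,
    )
    return df, summary


def enhancers_per_gene(assignments: pd.DataFrame) -> Dict[int, int]:
    """Histogram of regions-per-gene: {count: number of genes with it}."""
    if len(assignments) == 0:
        return {}
    per_gene = assignments.groupby("gene_id").size()
    hist = per_gene.value_counts().sort_index()
    out = {int(k): int(v) for k, v in hist.items()}
    assert sum(k * v for k, v in out.items()) == len(assignments)
    return out


def tss_distance_distribution(
    assignments: pd.DataFrame, bins: Sequence[float]
) -> Tuple[pd.DataFrame, float]:
    """Bin signed region-to-TSS distances; also report the fraction of
    assignments within 10 kb upstream of the TSS (distance in (-10000, 0])."""
    edges = np.asarray(bins, dtype=np.float64)
    if np.any(np.diff(edges) <= 0):
        raise ValidationError("bins must be strictly increasing")
    d = assignments["signed_distance"].to_numpy(dtype=np.float64)
    counts, _ = np.histogram(d, bins=edges)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    upstream = (
        float(((d > -UPSTREAM_PROXIMAL_BP) & (d <= 0)).mean()) if d.size else 0.0
    )
    return table, upstream
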