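"""End-to-end orchestration: transcripts -> classification -> differential
-> annotation -> domains -> contacts, from a single flat config.

Every stage logs its input/output record counts (the funnel numbers) and
writes its outputs before the next stage starts, so a failing stage
leaves all prior results on disk.  The summary JSON embeds the resolved
configuration and asserts the bookkeeping identities:
gro_positive + gro_negative = total peaks, assigned = enhancers +
silencers, and every regulated gene carries at least one assignment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import annotation, architecture, cistrome, differential, interactions, io as elio, transcription
from .intervals import GenomicInterval, ValidationError

log = logging.getLogger("enhancerlink")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration.

    Threshold defaults are the study's printed constants: 300-bp site
    gap, 0.2 RPKM site floor, 0.006 RPKM genome floor, 2-fold change at
    FDR 0.1, boundary score 15 with 3-fold score-ratio limit, 100-kb
    domain merge gap, 1-Mb contact bins and a 3-kb profile window.
    """

    chrom_sizes: str = ""
    gtf: str = ""
    vehicle_plus: str = ""
    vehicle_minus: str = ""
    ligand_plus: str = ""
    ligand_minus: str = ""
    signal_peaks: str = ""
    ctcf_peaks: str = ""
    rad21_peaks: str = ""
    interactions_path: str = ""
    out_dir: str = "results"
    site_gap_bp: int = 300
    site_min_rpkm: float = 0.2
    genome_min_rpkm: float = 0.006
    min_fold: float = 2.0
    max_fdr: float = 0.1
    boundary_min_score: float = 15.0
    score_ratio_limit: float = 3.0
    domain_merge_gap_bp: int = 100_000
    contact_bin_bp: int = 1_000_000
    profile_window_bp: int = 3_000
    profile_bin_bp: int = 25
    unit_min_length_bp: int = 50
    unit_max_gap_bp: int = 50
    seed: int = 0

    REQUIRED = (
        "chrom_sizes", "gtf", "vehicle_plus", "vehicle_minus",
        "ligand_plus", "ligand_minus", "signal_peaks", "ctcf_peaks",
        "rad21_peaks",
    )

    def validate(self) -> None:
        for name in self.REQUIRED:
            value = getattr(self, name)
            if not value:
                raise ValidationError(f"config field {name!r} is missing")
            if not Path(value).exists():
                raise ValidationError(
                    f"config field {name!r}: no such file {value!r}"
                )
        for name in ("site_gap_bp", "site_min_rpkm", "genome_min_rpkm",
                     "min_fold", "max_fdr", "boundary_min_score",
                     "score_ratio_limit", "domain_merge_gap_bp",
                     "contact_bin_bp", "profile_window_bp", "profile_bin_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name!r} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_units_bed(units, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tread_count\tstrand\trpkm\n")
        for i, u in enumerate(units):
            iv = u.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\ttu_{i}\t{u.read_count:g}"
                f"\t{iv.strand}\t{u.rpkm:.6g}\n"
            )


def _write_sites_bed(sites, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tgap\tstrand\tmax_rpkm\n")
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.name}\t{s.gap}\t."
                f"\t{s.max_rpkm:.6g}\n"
            )


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; return the result bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.as_dict()}
    stage = "setup"

    def begin(name: str) -> None:
        nonlocal stage
        stage = name
        log.info("stage %s: starting", name)

    try:
        begin("load_inputs")
        chrom_sizes = elio.read_chrom_sizes(config.chrom_sizes)
        genes = elio.read_gtf(config.gtf)
        signal_peaks = elio.read_bed(config.signal_peaks)
        ctcf = elio.read_bed(config.ctcf_peaks)
        rad21 = elio.read_bed(config.rad21_peaks)
        cov_v = elio.read_bedgraph_pair(
            config.vehicle_plus, config.vehicle_minus, chrom_sizes
        )
        cov_l = elio.read_bedgraph_pair(
            config.ligand_plus, config.ligand_minus, chrom_sizes
        )
        lib_v, lib_l = cov_v.total(), cov_l.total()
        log.info(
            "loaded %d genes, %d signal peaks, libraries %.0f/%.0f",
            len(genes), len(signal_peaks), lib_v, lib_l,
        )

        begin("transcripts")
        pooled = cov_v.pooled_with(cov_l)
        units = transcription.call_transcript_units(
            pooled, lib_v + lib_l,
            min_rpkm=config.genome_min_rpkm,
            min_length_bp=config.unit_min_length_bp,
            max_gap_bp=config.unit_max_gap_bp,
        )
        frac = transcription.transcribed_fraction(units, chrom_sizes)
        _write_units_bed(units, out / "transcript_units.bed")
        log.info("called %d units; transcribed fraction %.3f", len(units), frac)

        begin("divergent_sites")
        plus = sorted(
            (u for u in units if u.interval.strand == "+"),
            key=lambda u: (u.interval.chrom, u.interval.start),
        )
        minus = sorted(
            (u for u in units if u.interval.strand == "-"),
            key=lambda u: (u.interval.chrom, u.interval.start),
        )
        sites = transcription.detect_divergent_sites(
            plus, minus,
            max_gap_bp=config.site_gap_bp, min_rpkm=config.site_min_rpkm,
        )
        _write_sites_bed(sites, out / "divergent_sites.bed")
        log.info("detected %d divergent sites", len(sites))

        begin("classify")
        classified = cistrome.classify_by_gro(signal_peaks, sites)
        n_pos = sum(c.gro_class == "positive" for c in classified)
        n_neg = len(classified) - n_pos
        cls_df = pd.DataFrame(
            {
                "peak": [c.peak.name for c in classified],
                "chrom": [c.peak.interval.chrom for c in classified],
                "start": [c.peak.interval.start for c in classified],
                "end": [c.peak.interval.end for c in classified],
                "gro_class": [c.gro_class for c in classified],
                "site_id": [
                    c.matched_site.name if c.matched_site else "" for c in classified
                ],
            }
        )
        elio.write_tsv(cls_df, out / "classified_peaks.tsv")
        log.info("classified peaks: %d positive, %d negative", n_pos, n_neg)

        begin("differential")
        gene_regions = [g.interval for g in genes]
        gene_ids = [g.gene_id for g in genes]
        gcv = differential.count_region_reads(cov_v, gene_regions, "match")
        gcl = differential.count_region_reads(cov_l, gene_regions, "match")
        # median-of-ratios normalization over genes guards the change calls
        # against library-composition shifts caused by strong induction
        size_factor = differential.median_ratio_size_factor(gcv, gcl)
        lib_l_eff = lib_v * size_factor
        log.info("ligand/vehicle effective depth factor %.4f", size_factor)
        gene_records = differential.call_changes(
            gcv, gcl, lib_v, lib_l_eff,
            min_fold=config.min_fold, max_fdr=config.max_fdr,
            region_ids=gene_ids, regions=gene_regions,
        )
        site_spans = [s.span for s in sites]
        scv = differential.count_region_reads(cov_v, site_spans, "both")
        scl = differential.count_region_reads(cov_l, site_spans, "both")
        site_records = differential.call_changes(
            scv, scl, lib_v, lib_l_eff,
            min_fold=config.min_fold, max_fdr=config.max_fdr,
            region_ids=[s.name for s in sites], regions=site_spans,
        )
        elio.write_tsv(gene_records, out / "differential_genes.tsv")
        elio.write_tsv(site_records, out / "differential_sites.tsv")
        changing_sites = int((site_records["status"] != "unchanged").sum())
        changing_genes = int((gene_records["status"] != "unchanged").sum())
        site_status = dict(zip(site_records["region_id"], site_records["status"]))
        changing_rxr = sum(
            1 for c in classified
            if c.gro_class == "positive"
            and site_status.get(c.matched_site.name) != "unchanged"
        )
        log.info(
            "changing: %d genes, %d sites, %d changing sites bound by the signal factor",
            changing_genes, changing_sites, changing_rxr,
        )

        begin("annotate")
        assignments, summary = annotation.annotate(
            classified, site_records, gene_records, genes
        )
        elio.write_tsv(assignments, out / "assignments.tsv")
        log.info(
            "assigned %d regions (%d enhancers, %d silencers) to %d genes",
            summary.assigned, summary.enhancers, summary.silencers,
            summary.regulated_genes,
        )

        begin("domains")
        bounds = architecture.call_boundaries(
            ctcf, rad21,
            min_score=config.boundary_min_score,
            ratio_limit=config.score_ratio_limit,
        )
        domains, free = architecture.pair_domains(
            bounds, ratio_limit=config.score_ratio_limit
        )
        merged = architecture.merge_active_domains(
            domains, max_gap_bp=config.domain_merge_gap_bp
        )
        dstats = architecture.domain_length_stats(
            [d.interval for d in domains]
        )
        mstats = architecture.domain_length_stats(merged)
        gene_by_id = {g.gene_id: g for g in genes}
        features = []
        for gid, rows in assignments.groupby("gene_id"):
            g = gene_by_id[gid]
            regions = [
                GenomicInterval(r["chrom"], r["region_midpoint"],
                                r["region_midpoint"] + 1)
                for _, r in rows.iterrows()
            ]
            features.append((gid, g.interval, regions))
        residency_df, residency = architecture.assign_to_domains(features, merged)
        bdf = pd.DataFrame(
            {
                "chrom": [b.interval.chrom for b in bounds],
                "start": [b.interval.start for b in bounds],
                "end": [b.interval.end for b in bounds],
                "ctcf_score": [b.ctcf_score for b in bounds],
                "rad21_score": [b.rad21_score for b in bounds],
                "combined_score": [b.combined_score for b in bounds],
            }
        )
        elio.write_tsv(bdf, out / "boundaries.tsv")
        ddf = pd.DataFrame(
            {
                "chrom": [d.interval.chrom for d in domains],
                "start": [d.interval.start for d in domains],
                "end": [d.interval.end for d in domains],
                "length": [d.length for d in domains],
            }
        )
        elio.write_tsv(ddf, out / "functional_domains.tsv")
        mdf = pd.DataFrame(
            {
                "chrom": [m.chrom for m in merged],
                "start": [m.start for m in merged],
                "end": [m.end for m in merged],
            }
        )
        elio.write_tsv(mdf, out / "merged_domains.tsv")
        elio.write_tsv(residency_df, out / "domain_residency.tsv")
        log.info(
            "%d boundaries -> %d domains (+%d unpaired) -> %d merged; "
            "residency %.2f", len(bounds), len(domains), len(free),
            len(merged), residency,
        )

        contact_stats = None
        if config.interactions_path:
            begin("contacts")
            records = interactions.read_interactions(config.interactions_path)
            bins = interactions.bin_interactions(
                records, chrom_sizes, bin_bp=config.contact_bin_bp
            )
            target_regions = [
                gene_by_id[gid].interval for gid in assignments["gene_id"].unique()
            ] + [
                GenomicInterval(r["chrom"], r["region_midpoint"],
                                r["region_midpoint"] + 1)
                for _, r in assignments.iterrows()
            ]
            binned = interactions.classify_bins(bins, merged, target_regions)
            bait_chrom = records[0].bait.chrom if records else None
            contact_stats = interactions.compare_classes(
                binned, exclude_cis_chrom=bait_chrom
            )
            elio.write_tsv(binned, out / "contact_bins.tsv")
            with open(out / "contact_stats.json", "w") as fh:
                json.dump(contact_stats, fh, indent=2)
            log.info("contacts: %s", contact_stats["comparisons"])

        begin("summary")
        assert n_pos + n_neg == len(signal_peaks)
        assert summary.enhancers + summary.silencers == summary.assigned
        if summary.assigned:
            assert assignments.groupby("gene_id").size().min() >= 1
        summary_dict = {
            "total_signal_peaks": len(signal_peaks),
            "gro_positive": n_pos,
            "gro_negative": n_neg,
            "n_transcript_units": len(units),
            "transcribed_fraction": frac,
            "n_divergent_sites": len(sites),
            "changing_genes": changing_genes,
            "changing_sites": changing_sites,
            "changing_sites_signal_bound": changing_rxr,
            "annotation": summary.as_dict(),
            "active_enhancer_fraction": (
                summary.enhancers / len(signal_peaks) if signal_peaks else 0.0
            ),
            "n_boundaries": len(bounds),
            "n_domains": len(domains),
            "n_unpaired_boundaries": len(free),
            "domain_length": dstats,
            "n_merged_domains": len(merged),
            "merged_domain_length": mstats,
            "fraction_genes_in_domains": residency,
            "contacts": contact_stats,
            "config": config.as_dict(),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary_dict, fh, indent=2)
        bundle.update(
            summary=summary_dict,
            units=units,
            sites=sites,
            classified=classified,
            gene_records=gene_records,
            site_records=site_records,
            assignments=assignments,
            annotation_summary=summary,
            boundaries=bounds,
            domains=domains,
            merged_domains=merged,
            residency=residency_df,
            contact_stats=contact_stats,
            genes=genes,
        )
        return bundle
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def config_for_synthetic(truth, out_dir) -> PipelineConfig:
    """Pipeline config pointing at a synthetic dataset's files."""
    p = truth.paths
    return PipelineConfig(
        chrom_sizes=str(p["chrom_sizes"]),
        gtf=str(p["gtf"]),
        vehicle_plus=str(p["vehicle_plus"]),
        vehicle_minus=str(p["vehicle_minus"]),
        ligand_plus=str(p["ligand_plus"]),
        ligand_minus=str(p["ligand_minus"]),
        signal_peaks=str(p["rxr_peaks"]),
        ctcf_peaks=str(p["ctcf_peaks"]),
        rad21_peaks=str(p["rad21_peaks"]),
        interactions_path=str(p.get("interactions", "")),
        out_dir=str(out_dir),
        seed=truth.spec.seed,
    )


def demo(out_dir, seed: int = 0, noise: bool = True, spec=None) -> tuple:
    """Generate a synthetic study and run the full pipeline on it.

    Returns (ground truth, result bundle).
    """
    from .simulate import SyntheticSpec, generate

    out = Path(out_dir)
    if spec is None:
        spec = SyntheticSpec(seed=seed, noise=noise)
    truth = generate(spec, out / "data")
    config = config_for_synthetic(truth, out / "results")
    return truth, run_all(config)
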