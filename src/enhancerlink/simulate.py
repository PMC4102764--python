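"""Synthetic genome with planted regulatory ground truth.

The generator emulates the statistical structure of a ligand-response
nascent-transcription study in a compact genome: gene bodies with
elongation signal, short divergent initiation at promoters and enhancers
(two outward-pointing 300-500 bp transcripts whose 5' ends sit a fixed
distance apart), Poisson read noise on per-region counts, ligand-induced
fold changes at a subset of genes and their enhancers, CTCF/RAD21
co-peak boundaries delimiting functional domains, silent (untranscribed)
signal-factor sites, and interaction read pairs enriched toward
regulated regions.

Scale conventions
-----------------
Planted RPKM values are chosen on the scale of the compact genome: with
the default 1e6 reads over 10 Mb the mean depth is 0.1x genome-wide and
about 0.5x over the transcribed 20%, so an ordinary gene sits near
basal_gene_rpkm = 600 (~0.6x depth) and an eRNA arm near
basal_erna_rpkm = 50 (~20 expected reads per arm).  Keeping the field's
conventional RPKM values for a 2.5-Gb genome here would leave well under
one expected read per eRNA arm and nothing downstream would be
detectable; see docs/methods.md.

Both conditions are "sequenced" to the same depth (expected total =
``library_size`` each), so ligand induction shifts library composition
exactly as in a real experiment: raw-count ratios of induced regions are
compressed below the planted transcription-rate fold change while
depth-normalized (RPKM) ratios recover it.

Filler (noncoding background) transcripts absorb the read mass not
attributed to planted genes and eRNAs and top the transcribed genome
fraction up to ``target_transcribed_fraction``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as elio
from .intervals import GenomicInterval, Peak, ValidationError

BIN_BP = 1_000_000


class PlacementError(ValueError):
    """Requested feature density does not fit the genome."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults are the study conditions.

    ``library_size`` is the expected total coverage mass per condition
    (one unit per read).  ``boundary_score_range`` bounds the base score
    from which CTCF/RAD21 co-peak scores are drawn; within-site and
    within-domain score ratios are kept below 3 for true boundaries and
    at or above 3 for planted decoys.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_500_000
    n_genes: int = 200
    n_enhancers: int = 300
    n_silent_sites: int = 250
    fraction_ligand_induced: float = 0.25
    gene_fold_change: float = 4.0
    erna_fold_change: float = 4.0
    basal_gene_rpkm: float = 600.0
    basal_erna_rpkm: float = 50.0
    target_transcribed_fraction: float = 0.20
    divergent_gap_bp: int = 150
    gene_length_range: Tuple[int, int] = (4_000, 8_000)
    erna_length_range: Tuple[int, int] = (300, 500)
    n_domains: int = 20
    boundary_score_range: Tuple[float, float] = (20.0, 60.0)
    domain_gap_small_bp: Tuple[int, int] = (40_000, 80_000)
    domain_gap_large_bp: Tuple[int, int] = (120_000, 180_000)
    library_size: float = 1_000_000.0
    noise: bool = True
    overdispersion: Optional[float] = None  # negative-binomial shape; None = Poisson
    n_interaction_reads: int = 3000
    interaction_trans_fraction: float = 0.8
    interaction_class_weights: Tuple[float, float, float] = (1.0, 2.0, 3.0)

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_genes", "n_enhancers",
                     "n_silent_sites", "n_domains"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 <= self.fraction_ligand_induced <= 1.0):
            raise ValidationError("fraction_ligand_induced must lie in [0, 1]")
        for name in ("gene_fold_change", "erna_fold_change"):
            if getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must exceed 1")
        if not (0 < self.divergent_gap_bp < 300):
            raise ValidationError("divergent_gap_bp must lie in (0, 300)")
        if self.library_size <= 0:
            raise ValidationError("library_size must be positive")
        if not (0.0 < self.target_transcribed_fraction < 0.9):
            raise ValidationError("target_transcribed_fraction must lie in (0, 0.9)")


@dataclass
class GroundTruth:
    """Everything planted, for parameter-recovery tests."""

    spec: SyntheticSpec
    chrom_sizes: Dict[str, int]
    genes: List[dict]
    promoter_arms: List[dict]
    enhancers: List[dict]
    fillers: List[dict]
    divergent_sites: List[dict]
    silent_sites: List[dict]
    boundaries: List[dict]
    decoy_boundaries: List[dict]
    domains: List[dict]
    merged_domains: List[dict]
    bin_classes: Dict[str, List[str]]
    bait: Optional[dict]
    ligand_scale: float
    paths: Dict[str, Path]

    @property
    def active_enhancers(self) -> List[dict]:
        return [e for e in self.enhancers if e["active"]]

    @property
    def induced_genes(self) -> List[dict]:
        return [g for g in self.genes if g["induced"]]


def _u(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _layout_chrom(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    chrom: str,
    n_dom: int,
    n_genes: int,
) -> dict:
    """Deterministic per-chromosome layout skeleton.

    Domains (each holding a run of gene slots) occupy the head ~78% of
    the chromosome, alternating mergeable (< 100 kb) and non-mergeable
    gaps; the tail stays domain-free so that megabase binning yields
    inactive bins and room for filler transcription.
    """
    L = spec.chrom_length
    head = max(10_000, L // 100)
    domain_zone_end = int(L * 0.78)
    dom_pad = 2_000

    genes_per_dom = [n_genes // n_dom + (1 if k < n_genes % n_dom else 0)
                     for k in range(n_dom)]
    gaps = []
    for i in range(n_dom - 1):
        lo, hi = (spec.domain_gap_small_bp if i % 2 == 0
                  else spec.domain_gap_large_bp)
        gaps.append(int(_u(rng, lo, hi)))
    budget = domain_zone_end - head - sum(gaps) - n_dom * 2 * dom_pad
    if n_genes > 0:
        slot_w = min(26_000, budget // max(n_genes, 1))
    else:
        slot_w = 26_000
    if slot_w < 22_000:
        raise PlacementError(
            f"{chrom}: cannot fit {n_genes} genes in {n_dom} domains on "
            f"{L} bp; reduce n_genes/n_domains or enlarge chrom_length"
        )
    domains = []
    x = head
    for k in range(n_dom):
        width = genes_per_dom[k] * slot_w + 2 * dom_pad
        domains.append({"start": x, "end": x + width, "n_genes": genes_per_dom[k]})
        x += width
        if k < n_dom - 1:
            x += gaps[k]
    return {
        "chrom": chrom,
        "head": head,
        "dom_pad": dom_pad,
        "slot_w": slot_w,
        "domains": domains,
        "gaps": gaps,
        "filler_zone": (domain_zone_end + 5_000, int(L * 0.98)),
    }


def _mean_counts(
    lam: float, rng: np.random.Generator, spec: SyntheticSpec
) -> float:
    if not spec.noise:
        return lam
    if spec.overdispersion:
        shape = spec.overdispersion
        lam = rng.gamma(shape, lam / shape)
    return float(rng.poisson(lam))


def generate(
    spec: SyntheticSpec, out_dir, write_fasta: bool = False
) -> GroundTruth:
    """Write the synthetic study to ``out_dir`` and return its ground truth.

    Outputs: chrom.sizes, genes.gtf, stranded bedGraph pairs for the
    vehicle and ligand conditions, BED peak sets for the signal factor
    (RXR), lineage factor (PU.1), cofactor (P300), CTCF and RAD21,
    interaction read pairs for one bait, a ground-truth TSV, and
    optionally a FASTA with consensus DR motifs planted at active
    enhancers.  Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_test").write_text("")
        (out / ".write_test").unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}") from exc

    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_sizes = {c: spec.chrom_length for c in chroms}

    n_dom_per = [spec.n_domains // spec.n_chroms
                 + (1 if i < spec.n_domains % spec.n_chroms else 0)
                 for i in range(spec.n_chroms)]
    n_gene_per = [spec.n_genes // spec.n_chroms
                  + (1 if i < spec.n_genes % spec.n_chroms else 0)
                  for i in range(spec.n_chroms)]
    if any(n < 1 for n in n_dom_per):
        raise PlacementError("need at least one domain per chromosome")

    layouts = [
        _layout_chrom(spec, rng, chroms[i], n_dom_per[i], n_gene_per[i])
        for i in range(spec.n_chroms)
    ]

    genes: List[dict] = []
    promoter_arms: List[dict] = []
    enhancers: List[dict] = []
    divergent_sites: List[dict] = []
    silent_sites: List[dict] = []
    boundaries: List[dict] = []
    decoys: List[dict] = []
    domains: List[dict] = []
    merged: List[dict] = []
    fillers: List[dict] = []

    half_gap = spec.divergent_gap_bp // 2
    gap_rem = spec.divergent_gap_bp - half_gap  # exact planted 5' distance

    # --- domains, boundaries, genes, promoters -------------------------------
    for ci, lay in enumerate(layouts):
        chrom = lay["chrom"]
        slot_w = lay["slot_w"]
        tss_off = slot_w // 2
        lo_s, hi_s = spec.boundary_score_range
        for dk, dom in enumerate(lay["domains"]):
            dom_id = f"dom_{chrom}_{dk}"
            base = _u(rng, max(25.0, lo_s), max(40.0, lo_s + 15.0))
            scores = {}
            for side, pos in (("L", dom["start"]), ("R", dom["end"])):
                b = base * _u(rng, 0.85, 1.2)
                ctcf = b * _u(rng, 0.9, 1.1)
                rad21 = b * _u(rng, 0.9, 1.1)
                boundaries.append(
                    {
                        "id": f"bnd_{chrom}_{dk}{side}",
                        "chrom": chrom,
                        "start": pos - 200,
                        "end": pos + 200,
                        "ctcf_score": round(ctcf, 3),
                        "rad21_score": round(rad21, 3),
                        "domain_id": dom_id,
                    }
                )
            domains.append(
                {"id": dom_id, "chrom": chrom, "start": dom["start"],
                 "end": dom["end"], "bin": dom["start"] // BIN_BP,
                 "fully_in_first_bin": dom["end"] <= BIN_BP}
            )
            slot = dom["start"] + lay["dom_pad"]
            for g in range(dom["n_genes"]):
                gid = f"gene_{chrom}_{dk}_{g}"
                strand = "+" if rng.random() < 0.5 else "-"
                glen = int(rng.integers(*spec.gene_length_range))
                glen = min(glen, slot_w - tss_off - 1_000)
                tss = slot + tss_off
                if strand == "+":
                    start, end = tss, tss + glen
                else:
                    start, end = tss - glen + 1, tss + 1
                genes.append(
                    {
                        "id": gid, "chrom": chrom, "start": start, "end": end,
                        "strand": strand, "tss": tss, "domain_id": dom_id,
                        "slot_start": slot, "induced": False,
                        "fold": 1.0, "n_enh": 0,
                    }
                )
                # divergent initiation upstream of the promoter
                alen = int(rng.integers(*spec.erna_length_range))
                if strand == "+":
                    a5 = tss - spec.divergent_gap_bp
                    arm = {"chrom": chrom, "start": a5 - alen + 1, "end": a5 + 1,
                           "strand": "-"}
                    minus5, plus5 = a5, tss
                else:
                    a5 = tss + spec.divergent_gap_bp
                    arm = {"chrom": chrom, "start": a5, "end": a5 + alen,
                           "strand": "+"}
                    minus5, plus5 = tss, a5
                arm.update({"id": f"parm_{gid}", "gene_id": gid})
                promoter_arms.append(arm)
                divergent_sites.append(
                    {"id": f"pds_{gid}", "chrom": chrom, "minus5": minus5,
                     "plus5": plus5, "gap": plus5 - minus5, "kind": "promoter",
                     "ref_id": gid}
                )
                slot += slot_w

    # --- ligand-induced gene selection ---------------------------------------
    n_induced = int(round(spec.n_genes * spec.fraction_ligand_induced))
    eligible = [
        g for g in genes
        if next(d for d in domains if d["id"] == g["domain_id"])["fully_in_first_bin"]
    ]
    pool = eligible if len(eligible) >= n_induced else genes
    idx = rng.choice(len(pool), size=n_induced, replace=False) if n_induced else []
    for i in sorted(int(j) for j in np.atleast_1d(idx)):
        pool[i]["induced"] = True
        pool[i]["fold"] = spec.gene_fold_change

    # --- enhancers ------------------------------------------------------------
    slot_w_min = min(lay["slot_w"] for lay in layouts)
    max_per_gene = min(4, (slot_w_min // 2 - 700 - 3_000) // 2_500 + 1)
    if max_per_gene < 1:
        raise PlacementError("gene slots too narrow for any enhancer")
    if spec.n_enhancers > spec.n_genes * max_per_gene:
        raise PlacementError(
            f"cannot place {spec.n_enhancers} enhancers near {spec.n_genes} "
            f"genes (max {max_per_gene} per gene); reduce n_enhancers"
        )
    induced_genes = [g for g in genes if g["induced"]]
    if spec.n_enhancers < len(induced_genes):
        raise PlacementError("n_enhancers must cover every induced gene")
    for g in induced_genes:
        g["n_enh"] = 1
    budget = spec.n_enhancers - len(induced_genes)
    order = rng.permutation(len(genes))
    while budget > 0:
        progressed = False
        for j in order:
            if budget == 0:
                break
            g = genes[int(j)]
            if g["n_enh"] < max_per_gene:
                g["n_enh"] += 1
                budget -= 1
                progressed = True
        if not progressed:
            break

    for g in genes:
        for k in range(g["n_enh"]):
            off = 3_000 + 2_500 * k
            center = g["tss"] - off if g["strand"] == "+" else g["tss"] + off
            lm = int(rng.integers(*spec.erna_length_range))
            lp = int(rng.integers(*spec.erna_length_range))
            minus5 = center - half_gap
            plus5 = center + gap_rem
            eid = f"enh_{g['id']}_{k}"
            active = bool(g["induced"])
            enhancers.append(
                {
                    "id": eid, "chrom": g["chrom"], "center": center,
                    "peak_start": center - 200, "peak_end": center + 200,
                    "minus_arm": (minus5 - lm + 1, minus5 + 1),
                    "plus_arm": (plus5, plus5 + lp),
                    "target_gene": g["id"], "active": active,
                    "fold": spec.erna_fold_change if active else 1.0,
                    "domain_id": g["domain_id"],
                }
            )
            divergent_sites.append(
                {"id": f"eds_{eid}", "chrom": g["chrom"], "minus5": minus5,
                 "plus5": plus5, "gap": plus5 - minus5, "kind": "enhancer",
                 "ref_id": eid}
            )

    # --- fillers: top transcription up to the target genome fraction ---------
    for lay in layouts:
        chrom = lay["chrom"]
        planted = sum(g["end"] - g["start"] for g in genes if g["chrom"] == chrom)
        planted += sum(a["end"] - a["start"] for a in promoter_arms
                       if a["chrom"] == chrom)
        planted += sum(
            (e["minus_arm"][1] - e["minus_arm"][0])
            + (e["plus_arm"][1] - e["plus_arm"][0])
            for e in enhancers if e["chrom"] == chrom
        )
        deficit = int(spec.target_transcribed_fraction * spec.chrom_length) - planted
        z_lo, z_hi = lay["filler_zone"]
        pos = z_lo
        fi = 0
        while deficit > 600 and pos < z_hi - 1_000:
            flen = int(min(rng.integers(3_000, 10_000), deficit))
            flen = min(flen, z_hi - pos - 200)
            if flen < 600:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            fillers.append(
                {"id": f"fill_{chrom}_{fi}", "chrom": chrom, "start": pos,
                 "end": pos + flen, "strand": strand}
            )
            deficit -= flen
            pos += flen + int(rng.integers(1_000, 2_000))
            fi += 1
        if deficit > int(0.01 * spec.chrom_length):
            raise PlacementError(
                f"{chrom}: filler zone too small to reach the target "
                "transcribed fraction; reduce target or feature density"
            )

    # --- silent signal-factor sites and boundary decoys in the gaps ----------
    free_zones: List[Tuple[str, int, int]] = []
    for lay in layouts:
        chrom = lay["chrom"]
        doms = lay["domains"]
        for k in range(len(doms) - 1):
            free_zones.append((chrom, doms[k]["end"] + 3_000,
                               doms[k + 1]["start"] - 3_000))
        zone_lo = lay["filler_zone"][1] + 2_000
        if zone_lo < spec.chrom_length - 3_000:
            free_zones.append((chrom, zone_lo, spec.chrom_length - 1_000))
    free_zones = [z for z in free_zones if z[2] - z[1] > 5_000]
    capacity = sum((hi - lo) // 2_000 for _, lo, hi in free_zones)
    n_decoy_each = min(2 * spec.n_chroms, max(2, capacity // 20))
    if spec.n_silent_sites + 3 * n_decoy_each > capacity:
        raise PlacementError(
            "not enough untranscribed space for the requested silent sites; "
            "reduce n_silent_sites"
        )
    slots: List[Tuple[str, int]] = []
    for chrom, lo, hi in free_zones:
        slots.extend((chrom, p) for p in range(lo, hi - 600, 2_000))
    pick = rng.choice(len(slots), size=spec.n_silent_sites + 3 * n_decoy_each,
                      replace=False)
    pick = [slots[int(i)] for i in pick]
    for i in range(spec.n_silent_sites):
        chrom, p = pick[i]
        silent_sites.append(
            {"id": f"silent_{i}", "chrom": chrom, "start": p, "end": p + 400}
        )
    lo_s, hi_s = spec.boundary_score_range
    for d in range(n_decoy_each):
        chrom, p = pick[spec.n_silent_sites + 3 * d]
        c = _u(rng, max(16.0, lo_s), hi_s / 2)
        decoys.append(  # co-peak with >= 3-fold score difference
            {"id": f"decoy_ratio_{d}", "chrom": chrom, "start": p, "end": p + 400,
             "ctcf_score": round(c, 3), "rad21_score": round(c * _u(rng, 3.2, 4.5), 3),
             "kind": "ratio"}
        )
        chrom, p = pick[spec.n_silent_sites + 3 * d + 1]
        decoys.append(  # CTCF without cohesin
            {"id": f"decoy_lone_{d}", "chrom": chrom, "start": p, "end": p + 400,
             "ctcf_score": round(_u(rng, lo_s, hi_s), 3), "rad21_score": None,
             "kind": "lone_ctcf"}
        )
        chrom, p = pick[spec.n_silent_sites + 3 * d + 2]
        decoys.append(  # co-peak below the score floor
            {"id": f"decoy_weak_{d}", "chrom": chrom, "start": p, "end": p + 400,
             "ctcf_score": round(_u(rng, 5.0, 14.0), 3),
             "rad21_score": round(_u(rng, 5.0, 14.0), 3), "kind": "weak"}
        )

    # --- expected per-region read masses -------------------------------------
    M = spec.library_size / 1e6
    regions: List[dict] = []  # id, chrom, start, end, strand, lam_v, fold

    for g in genes:
        lam = spec.basal_gene_rpkm * (g["end"] - g["start"]) / 1e3 * M
        regions.append({**{k: g[k] for k in ("id", "chrom", "start", "end", "strand")},
                        "lam_v": lam, "fold": g["fold"]})
        g["lam_v"] = lam
    for a in promoter_arms:
        g = next(x for x in genes if x["id"] == a["gene_id"])
        lam = spec.basal_erna_rpkm * (a["end"] - a["start"]) / 1e3 * M
        regions.append({**{k: a[k] for k in ("id", "chrom", "start", "end", "strand")},
                        "lam_v": lam, "fold": g["fold"]})
    for e in enhancers:
        for arm_key, strand in (("minus_arm", "-"), ("plus_arm", "+")):
            s, en = e[arm_key]
            lam = spec.basal_erna_rpkm * (en - s) / 1e3 * M
            regions.append({"id": f"{e['id']}_{strand}", "chrom": e["chrom"],
                            "start": s, "end": en, "strand": strand,
                            "lam_v": lam, "fold": e["fold"]})
    planted_mass = sum(r["lam_v"] for r in regions)
    filler_len = sum(f["end"] - f["start"] for f in fillers)
    filler_mass = spec.library_size - planted_mass
    if filler_mass <= 0 or (filler_len == 0 and filler_mass > 0.02 * spec.library_size):
        raise PlacementError(
            "library_size too small for the planted RPKM values; "
            "increase library_size or lower basal RPKMs"
        )
    for f in fillers:
        lam = filler_mass * (f["end"] - f["start"]) / filler_len
        regions.append({**{k: f[k] for k in ("id", "chrom", "start", "end", "strand")},
                        "lam_v": lam, "fold": 1.0})

    ligand_raw = sum(r["lam_v"] * r["fold"] for r in regions)
    ligand_scale = spec.library_size / ligand_raw

    # --- sample counts and write coverage ------------------------------------
    cond_records: Dict[str, Dict[str, List[Tuple[str, int, int, float]]]] = {
        "vehicle": {"+": [], "-": []}, "ligand": {"+": [], "-": []}
    }
    for r in regions:
        lam_l = r["lam_v"] * r["fold"] * ligand_scale
        for cond, lam in (("vehicle", r["lam_v"]), ("ligand", lam_l)):
            count = _mean_counts(lam, rng, spec)
            if count <= 0:
                continue
            value = count / (r["end"] - r["start"])
            cond_records[cond][r["strand"]].append(
                (r["chrom"], r["start"], r["end"], value)
            )

    paths: Dict[str, Path] = {}
    paths["chrom_sizes"] = out / "chrom.sizes"
    elio.write_chrom_sizes(chrom_sizes, paths["chrom_sizes"])
    for cond in ("vehicle", "ligand"):
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = out / f"{cond}_{tag}.bedgraph"
            recs = sorted(cond_records[cond][strand],
                          key=lambda t: (t[0], t[1]))
            with open(p, "w") as fh:
                for chrom, s, e, v in recs:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
            paths[f"{cond}_{tag}"] = p

    # --- gene models ----------------------------------------------------------
    from .intervals import GeneModel

    gene_models = [
        GeneModel(g["id"], GenomicInterval(g["chrom"], g["start"], g["end"],
                                           g["strand"]))
        for g in genes
    ]
    paths["gtf"] = out / "genes.gtf"
    elio.write_gtf(gene_models, paths["gtf"])

    # --- peak sets ------------------------------------------------------------
    def peak(chrom, start, end, name, score, summit=None):
        return Peak(GenomicInterval(chrom, start, end), name, score, summit)

    rxr = [peak(e["chrom"], e["peak_start"], e["peak_end"], f"rxr_{e['id']}",
                _u(rng, 20, 80), 200) for e in enhancers]
    rxr += [peak(s["chrom"], s["start"], s["end"], f"rxr_{s['id']}",
                 _u(rng, 20, 80)) for s in silent_sites]
    p300 = [peak(e["chrom"], e["peak_start"] - 50, e["peak_end"] + 50,
                 f"p300_{e['id']}", _u(rng, 15, 60)) for e in enhancers
            if e["active"]]
    pu1 = [peak(e["chrom"], e["peak_start"] - 100, e["peak_end"] + 100,
                f"pu1_{e['id']}", _u(rng, 15, 70))
           for e in enhancers if rng.random() < 0.75]
    pu1 += [peak(s["chrom"], s["start"] - 100, s["end"] + 100,
                 f"pu1_{s['id']}", _u(rng, 15, 70))
            for s in silent_sites if rng.random() < 0.75]
    # standalone lineage-factor peaks at gene promoters (no signal factor)
    pu1 += [peak(g["chrom"], g["tss"] - 250, g["tss"] + 250,
                 f"pu1_prom_{g['id']}", _u(rng, 15, 70))
            for g in genes if rng.random() < 0.5]
    ctcf = [peak(b["chrom"], b["start"], b["end"], f"ctcf_{b['id']}",
                 b["ctcf_score"]) for b in boundaries]
    rad21 = [peak(b["chrom"], b["start"], b["end"], f"rad21_{b['id']}",
                  b["rad21_score"]) for b in boundaries]
    for d in decoys:
        ctcf.append(peak(d["chrom"], d["start"], d["end"], f"ctcf_{d['id']}",
                         d["ctcf_score"]))
        if d["rad21_score"] is not None:
            rad21.append(peak(d["chrom"], d["start"], d["end"],
                              f"rad21_{d['id']}", d["rad21_score"]))
    for name, peaks in (("rxr", rxr), ("pu1", pu1), ("p300", p300),
                        ("ctcf", ctcf), ("rad21", rad21)):
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        paths[f"{name}_peaks"] = out / f"{name}_peaks.bed"
        elio.write_bed(peaks, paths[f"{name}_peaks"])

    # --- expected merged domains and bin classes ------------------------------
    for lay in layouts:
        chrom = lay["chrom"]
        doms = [d for d in domains if d["chrom"] == chrom]
        group: List[dict] = [doms[0]]
        for prev_gap, d in zip(lay["gaps"], doms[1:]):
            if prev_gap < 100_000:
                group.append(d)
            else:
                merged.append({"chrom": chrom, "start": group[0]["start"],
                               "end": group[-1]["end"],
                               "members": [g["id"] for g in group]})
                group = [d]
        merged.append({"chrom": chrom, "start": group[0]["start"],
                       "end": group[-1]["end"],
                       "members": [g["id"] for g in group]})

    bin_classes: Dict[str, List[str]] = {}
    for chrom in chroms:
        n_bins = -(-spec.chrom_length // BIN_BP)
        classes = []
        for b in range(n_bins):
            lo, hi = b * BIN_BP, min((b + 1) * BIN_BP, spec.chrom_length)
            has_reg = any(
                g["chrom"] == chrom and g["start"] < hi and lo < g["end"]
                for g in genes if g["induced"]
            ) or any(
                e["chrom"] == chrom and e["peak_start"] < hi and lo < e["peak_end"]
                for e in enhancers if e["active"]
            )
            has_dom = any(
                m["chrom"] == chrom and m["start"] < hi and lo < m["end"]
                for m in merged
            )
            classes.append("target" if has_reg else "active" if has_dom
                           else "inactive")
        bin_classes[chrom] = classes

    # --- interaction reads ----------------------------------------------------
    bait = None
    from .interactions import InteractionRecord, write_interactions

    active = [e for e in enhancers if e["active"]]
    if active:
        be = active[0]
        bait = {"id": f"bait_{be['id']}", "enhancer_id": be["id"],
                "chrom": be["chrom"], "start": be["peak_start"],
                "end": be["peak_end"]}
        bait_iv = GenomicInterval(bait["chrom"], bait["start"], bait["end"])
        wmap = dict(zip(("inactive", "active", "target"),
                        spec.interaction_class_weights))
        trans_bins = [
            (chrom, b) for chrom in chroms if chrom != bait["chrom"]
            for b in range(len(bin_classes[chrom]))
        ]
        weights = np.array(
            [wmap[bin_classes[c][b]] for c, b in trans_bins], dtype=np.float64
        )
        n_trans = int(round(spec.n_interaction_reads
                            * spec.interaction_trans_fraction))
        n_cis = spec.n_interaction_reads - n_trans
        records: List[InteractionRecord] = []
        if trans_bins and n_trans:
            draws = rng.multinomial(n_trans, weights / weights.sum())
            for (chrom, b), n in zip(trans_bins, draws):
                lo = b * BIN_BP
                hi = min((b + 1) * BIN_BP, spec.chrom_length)
                for _ in range(int(n)):
                    records.append(InteractionRecord(
                        bait["id"], bait_iv, chrom,
                        int(rng.integers(lo, hi)), 1))
        mid = (bait["start"] + bait["end"]) // 2
        for _ in range(n_cis):
            pos = int(np.clip(mid + rng.integers(-500_000, 500_001),
                              0, spec.chrom_length - 1))
            records.append(InteractionRecord(bait["id"], bait_iv,
                                             bait["chrom"], pos, 1))
        paths["interactions"] = out / "interactions.tsv"
        write_interactions(records, paths["interactions"])

    # --- optional FASTA with planted DR motifs --------------------------------
    if write_fasta:
        seq_rng = np.random.default_rng(spec.seed + 1_000_003)
        paths["fasta"] = out / "genome.fa"
        with open(paths["fasta"], "w") as fh:
            for chrom in chroms:
                base = seq_rng.choice(list("ACGT"), size=spec.chrom_length)
                for e in enhancers:
                    if e["chrom"] != chrom:
                        continue
                    spacer = 1 if e["active"] else 4
                    motif = "AGGTCA" + "T" * spacer + "AGGTCA"
                    c = e["center"]
                    base[c : c + len(motif)] = list(motif)
                fh.write(f">{chrom}\n")
                seq = "".join(base)
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    # --- ground-truth table ---------------------------------------------------
    import pandas as pd

    rows = []
    for g in genes:
        rows.append([g["id"], "gene", g["chrom"], g["start"], g["end"],
                     g["strand"], "", g["fold"], g["domain_id"]])
    for e in enhancers:
        rows.append([e["id"], "enhancer" if e["active"] else "basal_enhancer",
                     e["chrom"], e["peak_start"], e["peak_end"], ".",
                     e["target_gene"], e["fold"], e["domain_id"]])
    for s in divergent_sites:
        rows.append([s["id"], "divergent_site", s["chrom"], s["minus5"],
                     s["plus5"] + 1, ".", s["ref_id"], "", ""])
    for s in silent_sites:
        rows.append([s["id"], "silent_site", s["chrom"], s["start"], s["end"],
                     ".", "", "", ""])
    for d in domains:
        rows.append([d["id"], "domain", d["chrom"], d["start"], d["end"],
                     ".", "", "", d["id"]])
    truth_df = pd.DataFrame(
        rows, columns=["id", "type", "chrom", "start", "end", "strand",
                       "target_gene", "true_fold_change", "domain_id"]
    )
    paths["ground_truth"] = out / "ground_truth.tsv"
    elio.write_tsv(truth_df, paths["ground_truth"])

    return GroundTruth(
        spec=spec, chrom_sizes=chrom_sizes, genes=genes,
        promoter_arms=promoter_arms, enhancers=enhancers, fillers=fillers,
        divergent_sites=divergent_sites, silent_sites=silent_sites,
        boundaries=boundaries, decoy_boundaries=decoys, domains=domains,
        merged_domains=merged, bin_classes=bin_classes, bait=bait,
        ligand_scale=ligand_scale, paths=paths,
    )
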