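"""CTCF/RAD21 boundaries, domain pairing, merging, and residency."""

import numpy as np
import pytest

from enhancerlink import io as elio
from enhancerlink.architecture import (
    Boundary,
    FunctionalDomain,
    assign_to_domains,
    call_boundaries,
    domain_length_stats,
    merge_active_domains,
    pair_domains,
)
from enhancerlink.intervals import GenomicInterval, Peak


def peak(start, end, score, chrom="chr1", name="p"):
    return Peak(GenomicInterval(chrom, start, end), name, score)


def boundary(mid, score=30.0, chrom="chr1"):
    return Boundary(
        GenomicInterval(chrom, max(0, mid - 200), mid + 200), score, score
    )


def domain(start, end, chrom="chr1"):
    return FunctionalDomain(
        GenomicInterval(chrom, start, max(end, start + 1)),
        boundary(start), boundary(end),
    )


# ----------------------------------------------------------- boundaries --


def test_score_ratio_acceptance_and_rejection():
    ctcf = [peak(100, 500, 20)]
    assert len(call_boundaries(ctcf, [peak(100, 500, 50)])) == 1   # ratio 2.5
    assert call_boundaries(ctcf, [peak(100, 500, 61)]) == []       # ratio 3.05
    assert call_boundaries([peak(100, 500, 15)], [peak(100, 500, 15)]) == []


def test_boundary_interval_is_intersection():
    (b,) = call_boundaries([peak(100, 500, 20)], [peak(300, 700, 30)])
    assert (b.interval.start, b.interval.end) == (300, 500)
    assert b.combined_score == 20


def test_ctcf_pairs_with_largest_overlap_rad21():
    ctcf = [peak(100, 500, 30)]
    rad21 = [peak(90, 200, 30, name="small"), peak(250, 500, 30, name="big")]
    (b,) = call_boundaries(ctcf, rad21)
    assert (b.interval.start, b.interval.end) == (250, 500)


def test_no_overlap_no_boundary():
    assert call_boundaries([peak(100, 200, 30)], [peak(300, 400, 30)]) == []


# -------------------------------------------------------------- pairing --


def test_pairing_basic_domain():
    bs = [boundary(10_000, 30), boundary(90_000, 40)]
    domains, free = pair_domains(bs)
    assert len(domains) == 1 and free == []
    d = domains[0]
    assert (d.interval.start, d.interval.end) == (10_000, 90_000)
    assert d.length == 80_000


def test_pairing_skips_dissimilar_scores():
    bs = [boundary(10_000, 10), boundary(20_000, 100), boundary(30_000, 12)]
    domains, free = pair_domains(bs)
    # b0 skips the 10x-different neighbor and pairs with the next candidate
    assert len(domains) == 1
    assert (domains[0].interval.start, domains[0].interval.end) == (10_000, 30_000)
    assert [b.combined_score for b in free] == [100]


def test_pairing_consumes_each_boundary_once_and_domains_disjoint():
    rng = np.random.default_rng(9)
    for trial in range(30):
        mids = np.cumsum(rng.integers(1000, 50_000, rng.integers(2, 20)))
        bs = [boundary(int(m), float(rng.uniform(16, 90))) for m in mids]
        domains, free = pair_domains(bs)
        assert 2 * len(domains) + len(free) == len(bs)
        for a, b in zip(domains, domains[1:]):
            assert a.interval.end <= b.interval.start  # pairwise disjoint


# -------------------------------------------------------------- merging --


def test_merge_gap_strictness():
    close = [domain(0, 100_000), domain(150_000, 250_000)]       # gap 50 kb
    assert len(merge_active_domains(close)) == 1
    exact = [domain(0, 100_000), domain(200_000, 300_000)]       # gap 100 kb
    assert len(merge_active_domains(exact)) == 2
    under = [domain(0, 100_000), domain(199_999, 300_000)]       # gap 99 999
    merged = merge_active_domains(under)
    assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 300_000)


def test_merge_is_idempotent_and_matches_transitive_closure():
    rng = np.random.default_rng(13)
    for trial in range(30):
        edges = np.cumsum(rng.integers(20_000, 180_000, 2 * rng.integers(2, 12)))
        domains = [domain(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]
        merged = merge_active_domains(domains)
        # oracle: brute-force union over the strict-gap adjacency relation
        groups = [[domains[0]]]
        for prev, cur in zip(domains, domains[1:]):
            if cur.interval.start - prev.interval.end < 100_000:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        expected = [(g[0].interval.start, g[-1].interval.end) for g in groups]
        assert [(m.start, m.end) for m in merged] == expected
        again = merge_active_domains(
            [FunctionalDomain(m, boundary(m.start), boundary(m.end)) for m in merged]
        )
        assert [(m.start, m.end) for m in again] == [(m.start, m.end) for m in merged]


def test_length_stats():
    stats = domain_length_stats([GenomicInterval("chr1", 0, 100),
                                 GenomicInterval("chr1", 0, 300)])
    assert stats == {"n": 2, "median_bp": 200.0, "mean_bp": 200.0}


# ------------------------------------------------------------ residency --


def test_gene_with_all_regions_inside_is_inside():
    doms = [GenomicInterval("chr1", 0, 100_000)]
    giv = GenomicInterval("chr1", 40_000, 50_000, "+")
    regs = [GenomicInterval("chr1", 10_000, 10_400),
            GenomicInterval("chr1", 60_000, 60_400)]
    df, frac = assign_to_domains([("g", giv, regs)], doms)
    assert frac == 1.0


def test_one_region_beyond_boundary_puts_gene_outside():
    doms = [GenomicInterval("chr1", 0, 100_000)]
    giv = GenomicInterval("chr1", 40_000, 50_000, "+")
    regs = [GenomicInterval("chr1", 10_000, 10_400),
            GenomicInterval("chr1", 120_000, 120_400)]
    df, frac = assign_to_domains([("g", giv, regs)], doms)
    assert frac == 0.0


def test_gene_without_regions_counted_by_tss():
    doms = [GenomicInterval("chr1", 0, 100_000)]
    inside = ("g1", GenomicInterval("chr1", 40_000, 50_000, "+"), [])
    outside = ("g2", GenomicInterval("chr1", 150_000, 160_000, "+"), [])
    df, frac = assign_to_domains([inside, outside], doms)
    assert frac == 0.5


# -------------------------------------------------- planted recovery ----


def test_planted_boundary_and_domain_recovery(small_truth):
    """Planted boundaries/domains are recovered exactly; decoys rejected."""
    ctcf = elio.read_bed(small_truth.paths["ctcf_peaks"])
    rad21 = elio.read_bed(small_truth.paths["rad21_peaks"])
    bounds = call_boundaries(ctcf, rad21)
    planted = sorted(
        (b["chrom"], b["start"], b["end"]) for b in small_truth.boundaries
    )
    assert sorted(
        (b.interval.chrom, b.interval.start, b.interval.end) for b in bounds
    ) == planted

    domains, free = pair_domains(bounds)
    assert free == []
    assert sorted(
        (d.interval.chrom, d.interval.start, d.interval.end) for d in domains
    ) == sorted((d["chrom"], d["start"], d["end"]) for d in small_truth.domains)

    merged = merge_active_domains(domains)
    assert sorted((m.chrom, m.start, m.end) for m in merged) == sorted(
        (m["chrom"], m["start"], m["end"]) for m in small_truth.merged_domains
    )


def test_noise_free_pipeline_residency_is_one(small_nf):
    truth, bundle = small_nf
    assert bundle["summary"]["fraction_genes_in_domains"] == 1.0
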