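"""Peak integration: overlaps, GRO classification, profiles, TSS distances,
direct-repeat motif scanning."""

import numpy as np
import pytest

from enhancerlink.cistrome import (
    classify_by_gro,
    overlap_peaks,
    reverse_complement,
    scan_dr_repeats,
    summit_profile,
    tss_distance_stats,
)
from enhancerlink.intervals import (
    DivergentSite,
    GeneModel,
    GenomicInterval,
    Peak,
    StrandedCoverage,
    TranscriptUnit,
    ValidationError,
)


def peak(start, end, name="p", chrom="chr1", score=1.0, summit=None):
    return Peak(GenomicInterval(chrom, start, end), name, score, summit)


def site(start, end, chrom="chr1", name="s"):
    pu = TranscriptUnit(GenomicInterval(chrom, end - 1, end + 100, "+"), 1, 1)
    mu = TranscriptUnit(GenomicInterval(chrom, max(0, start - 100), start + 1, "-"), 1, 1)
    return DivergentSite(GenomicInterval(chrom, start, end), pu, mu, end - 1 - start, 1.0, name)


# ------------------------------------------------------------- overlaps --


def test_overlap_basic_pair():
    rep = overlap_peaks([peak(100, 200)], [peak(150, 250)])
    assert rep.pairs == [(0, 0, 50)]
    assert (rep.a_only, rep.b_only, rep.a_and_b) == (0, 0, 1)


def test_half_open_adjacency_is_no_overlap():
    rep = overlap_peaks([peak(100, 200)], [peak(200, 300)])
    assert rep.pairs == [] and rep.a_and_b == 0


def test_min_overlap_threshold():
    rep = overlap_peaks([peak(100, 200)], [peak(150, 250)], min_overlap_bp=51)
    assert rep.pairs == []


def _random_peaks(rng, n=60, span=100_000):
    out = []
    for i in range(n):
        s = int(rng.integers(0, span - 500))
        out.append(peak(s, s + int(rng.integers(50, 500)), name=f"p{i}"))
    return out


def test_overlap_counts_match_brute_force_and_are_symmetric():
    rng = np.random.default_rng(5)
    for trial in range(20):
        a = _random_peaks(rng)
        b = _random_peaks(rng)
        rep = overlap_peaks(a, b)
        brute = sorted(
            (i, j, min(pa.interval.end, pb.interval.end)
             - max(pa.interval.start, pb.interval.start))
            for i, pa in enumerate(a)
            for j, pb in enumerate(b)
            if pa.interval.overlap_bp(pb.interval) >= 1
        )
        assert sorted(rep.pairs) == brute
        assert rep.a_and_b == len({i for i, _, _ in brute})
        assert rep.a_only == len(a) - rep.a_and_b
        rev = overlap_peaks(b, a)
        assert sorted((j, i) for i, j, _ in rep.pairs) == sorted(
            (i, j) for i, j, _ in rev.pairs
        )


# --------------------------------------------------------- classification


def test_empty_sites_make_all_negative():
    cls = classify_by_gro([peak(0, 100), peak(200, 300)], [])
    assert all(c.gro_class == "negative" and c.matched_site is None for c in cls)


def test_peak_containing_site_is_positive():
    cls = classify_by_gro([peak(100, 400)], [site(200, 250)])
    assert cls[0].gro_class == "positive"
    assert cls[0].matched_site.name == "s"


def test_partition_is_exhaustive_and_exclusive():
    rng = np.random.default_rng(17)
    for trial in range(30):
        peaks = _random_peaks(rng, n=40)
        sites = [site(int(s), int(s) + 150, name=f"s{k}")
                 for k, s in enumerate(rng.integers(0, 99_000, 15))]
        cls = classify_by_gro(peaks, sites)
        n_pos = sum(c.gro_class == "positive" for c in cls)
        n_neg = sum(c.gro_class == "negative" for c in cls)
        assert n_pos + n_neg == len(peaks)
        for c in cls:
            expected = any(c.peak.interval.overlap_bp(s.interval) >= 1 for s in sites)
            assert (c.gro_class == "positive") == expected


# -------------------------------------------------------------- profiles --


def make_cov(length=10_000):
    return StrandedCoverage({"chr1": length})


def test_delta_coverage_hits_only_central_bin():
    cov = make_cov()
    cov.add_record("chr1", 5000, 5001, 3.0, "+")
    mat, mean = summit_profile([peak(4000, 6000)], cov)  # midpoint summit 5000
    assert mat.shape == (1, 120)
    assert mat[0, 60] == 3.0 and mat.sum() == 3.0
    assert mean[60] == 3.0


def test_uniform_coverage_fills_every_bin():
    cov = make_cov()
    cov.add_record("chr1", 0, 10_000, 1.0, "+")
    mat, _ = summit_profile([peak(4000, 6000)], cov, window_bp=3000, bin_bp=25)
    assert np.allclose(mat, 25.0)


def test_profile_row_sums_match_direct_window_counts():
    rng = np.random.default_rng(8)
    cov = make_cov(50_000)
    cov.data["chr1"]["+"] = rng.poisson(0.3, 50_000).astype(np.float32)
    cov.data["chr1"]["-"] = rng.poisson(0.2, 50_000).astype(np.float32)
    peaks = [peak(int(s), int(s) + 400, name=f"p{i}", summit=int(o))
             for i, (s, o) in enumerate(zip(rng.integers(2000, 47_000, 25),
                                            rng.integers(0, 400, 25)))]
    mat, _ = summit_profile(peaks, cov)
    both = cov.data["chr1"]["+"].astype(np.float64) + cov.data["chr1"]["-"]
    for row, p in zip(mat, peaks):
        c = p.summit_pos
        assert row.sum() == pytest.approx(both[c - 1500 : c + 1500].sum())


def test_out_of_chromosome_bins_are_zero():
    cov = make_cov()
    cov.add_record("chr1", 0, 10_000, 1.0, "+")
    mat, _ = summit_profile([peak(0, 100)], cov)  # summit at 50, window into <0
    n_zero = (mat[0] == 0).sum()
    assert n_zero == (1500 - 50) // 25  # 58 bins fall before the chromosome


def test_window_must_be_even_multiple_of_bin():
    with pytest.raises(ValidationError):
        summit_profile([peak(0, 100)], make_cov(), window_bp=3010, bin_bp=25)
    with pytest.raises(ValidationError):
        summit_profile([peak(0, 100)], make_cov(), window_bp=25, bin_bp=25)


# --------------------------------------------------------- TSS distances --


def gene(gene_id, tss, strand="+", length=5000, chrom="chr1"):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        iv = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
    return GeneModel(gene_id, iv)


def test_peak_at_tss_has_zero_distance():
    df, frac = tss_distance_stats([peak(950, 1050)], [gene("g", 1000)])
    assert df.loc[0, "distance"] == 0 and frac == 0.0


def test_upstream_sign_convention_on_minus_strand():
    # 5 kb 5' of a minus-strand gene's TSS = 5 kb to its right
    g = gene("g", 20_000, strand="-")
    df, _ = tss_distance_stats([peak(24_950, 25_050)], [g])
    assert df.loc[0, "distance"] == -5000


def test_closest_assignment_matches_brute_force():
    rng = np.random.default_rng(31)
    for trial in range(30):
        genes = [gene(f"g{i}", int(t), strand="+" if rng.random() < 0.5 else "-")
                 for i, t in enumerate(rng.integers(5000, 95_000, 12))]
        peaks = _random_peaks(rng, n=25)
        df, frac = tss_distance_stats(peaks, genes, near_bp=10_000)
        for row, p in zip(df.itertuples(), peaks):
            mid = p.interval.midpoint
            best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
            assert row.gene_id == best.gene_id
            assert abs(row.distance) == abs(mid - best.tss)
        assert frac == pytest.approx(
            np.mean([abs(d) > 10_000 for d in df["distance"]])
        )


def test_empty_gene_list_rejected():
    with pytest.raises(ValidationError):
        tss_distance_stats([peak(0, 10)], [])


# ---------------------------------------------------------- motif scans --


def test_dr1_consensus_hit():
    hits = scan_dr_repeats("AGGTCATAGGTCA", max_mismatch_per_half=0)
    assert len(hits) == 1
    h = hits[0]
    assert (h.interval.start, h.interval.end) == (0, 13)
    assert h.repeat_class == "DR1" and h.mismatches == (0, 0) and h.strand == "+"


def test_dr0_consensus_hit():
    hits = scan_dr_repeats("AGGTCAAGGTCA", max_mismatch_per_half=0)
    assert [h.repeat_class for h in hits] == ["DR0"]


def test_n_never_matches():
    # an N inside a half-site always counts as a mismatch
    assert scan_dr_repeats("NGGTCATAGGTCA", max_mismatch_per_half=0) == []
    hits = scan_dr_repeats("NGGTCATAGGTCA", max_mismatch_per_half=1)
    assert any(h.repeat_class == "DR1" and h.mismatches == (1, 0) for h in hits)
    # an N in the spacer is free: the half-sites still match perfectly
    hits = scan_dr_repeats("AGGTCANAGGTCA", max_mismatch_per_half=0)
    assert [h.repeat_class for h in hits] == ["DR1"]


def test_invalid_alphabet_rejected():
    with pytest.raises(ValidationError):
        scan_dr_repeats("AGGTCAXAGGTCA")


def test_reverse_complement_mirror_property():
    rng = np.random.default_rng(41)
    for trial in range(10):
        seq = "".join(rng.choice(list("ACGT"), 200))
        L = len(seq)
        fwd = scan_dr_repeats(seq)
        rev = scan_dr_repeats(reverse_complement(seq))
        mapped = sorted(
            (L - h.interval.end, L - h.interval.start, h.repeat_class) for h in rev
        )
        assert mapped == sorted(
            (h.interval.start, h.interval.end, h.repeat_class) for h in fwd
        )


def _oracle_scan(seq, half="AGGTCA", max_mm=1):
    """Brute-force enumeration of every window on both strands."""
    def mm(a, b):
        return sum(1 for x, y in zip(a, b) if x != y or x == "N")

    out = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for spacer in range(6):
            w = 12 + spacer
            for i in range(L - w + 1):
                if (mm(s[i:i + 6], half) <= max_mm
                        and mm(s[i + 6 + spacer:i + w], half) <= max_mm):
                    start = i if strand == "+" else L - (i + w)
                    out.append((start, start + w, f"DR{spacer}", strand))
    return sorted(out)


def test_scan_matches_exhaustive_oracle():
    rng = np.random.default_rng(53)
    for trial in range(15):
        seq = "".join(rng.choice(list("ACGTN"), 150, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = sorted(
            (h.interval.start, h.interval.end, h.repeat_class, h.strand)
            for h in scan_dr_repeats(seq)
        )
        assert got == _oracle_scan(seq)
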