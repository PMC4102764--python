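"""Transcript-unit segmentation, RPKM, and divergent-site pairing."""

import numpy as np
import pytest

from enhancerlink.intervals import (
    GenomicInterval,
    StrandedCoverage,
    TranscriptUnit,
    ValidationError,
)
from enhancerlink.transcription import (
    call_transcript_units,
    detect_divergent_sites,
    transcribed_fraction,
)


def make_cov(length=10_000, chrom="chr1"):
    return StrandedCoverage({chrom: length})


def unit(strand, start, end, rpkm=1.0, chrom="chr1"):
    return TranscriptUnit(GenomicInterval(chrom, start, end, strand), rpkm, rpkm)


# ---------------------------------------------------------------- units ----


def test_uniform_coverage_closed_form():
    cov = make_cov()
    cov.add_record("chr1", 1000, 2000, 1.0, "+")
    (u,) = call_transcript_units(cov, 1e6, min_rpkm=0)
    assert (u.interval.start, u.interval.end, u.interval.strand) == (1000, 2000, "+")
    assert u.read_count == pytest.approx(1000)
    assert u.rpkm == pytest.approx(1000)  # 1000 / (1 kb x 1 M)


def test_gap_merging_threshold():
    cov = make_cov()
    cov.add_record("chr1", 0, 500, 1.0, "+")
    cov.add_record("chr1", 600, 1000, 1.0, "+")
    merged = call_transcript_units(cov, 1e6, min_rpkm=0, max_gap_bp=200)
    assert len(merged) == 1 and (merged[0].interval.start, merged[0].interval.end) == (0, 1000)
    assert merged[0].read_count == pytest.approx(900)  # gap bases contribute 0
    split = call_transcript_units(cov, 1e6, min_rpkm=0, max_gap_bp=50)
    assert [u.interval.end - u.interval.start for u in split] == [500, 400]


def test_length_and_rpkm_filters():
    cov = make_cov()
    cov.add_record("chr1", 0, 40, 5.0, "+")       # too short
    cov.add_record("chr1", 1000, 2000, 0.001, "+")  # 1 rpkm at lib 1e6
    units = call_transcript_units(cov, 1e6, min_rpkm=0.5, min_length_bp=50)
    assert len(units) == 1 and units[0].interval.start == 1000
    assert call_transcript_units(cov, 1e6, min_rpkm=5.0, min_length_bp=50) == []


def test_segmentation_matches_brute_force():
    """Union length of called units equals an independent base-vector scan."""
    rng = np.random.default_rng(11)
    for trial in range(20):
        cov = make_cov(length=3000)
        vec = (rng.random(3000) < 0.08) * rng.integers(1, 4, 3000)
        cov.data["chr1"]["+"] = vec.astype(np.float32)
        for max_gap in (0, 5, 50):
            units = call_transcript_units(
                cov, 1e6, min_rpkm=0, min_length_bp=1, max_gap_bp=max_gap
            )
            # oracle: explicit scan merging zero-gaps of <= max_gap
            runs = []
            start = None
            last_nz = None
            for i, v in enumerate(vec):
                if v:
                    if start is None:
                        start = i
                    elif i - last_nz - 1 > max_gap:
                        runs.append((start, last_nz + 1))
                        start = i
                    last_nz = i
            if start is not None:
                runs.append((start, last_nz + 1))
            assert [(u.interval.start, u.interval.end) for u in units] == runs


def test_rpkm_homogeneity():
    """Doubling every base and the library size leaves RPKM unchanged."""
    rng = np.random.default_rng(3)
    cov = make_cov(length=5000)
    cov.data["chr1"]["+"] = (rng.random(5000) < 0.2).astype(np.float32) * 2.0
    u1 = call_transcript_units(cov, 1e6, min_rpkm=0)
    cov2 = make_cov(length=5000)
    cov2.data["chr1"]["+"] = cov.data["chr1"]["+"] * 2
    u2 = call_transcript_units(cov2, 2e6, min_rpkm=0)
    assert [u.rpkm for u in u1] == pytest.approx([u.rpkm for u in u2])


def test_nonpositive_library_rejected():
    with pytest.raises(ValidationError):
        call_transcript_units(make_cov(), 0)


# ----------------------------------------------------- transcribed fraction


def test_transcribed_fraction_basics():
    sizes = {"chr1": 1000}
    assert transcribed_fraction([], sizes) == 0.0
    assert transcribed_fraction([unit("+", 0, 500)], sizes) == pytest.approx(0.5)
    # opposite strands over the same bases count once
    both = [unit("+", 0, 500), unit("-", 250, 750)]
    assert transcribed_fraction(both, sizes) == pytest.approx(0.75)


def test_transcribed_fraction_rejects_out_of_genome():
    with pytest.raises(ValidationError):
        transcribed_fraction([unit("+", 0, 2000)], {"chr1": 1000})


# ------------------------------------------------------- divergent sites --


def test_divergent_pair_direct_example():
    plus = [unit("+", 1000, 1500)]
    minus = [unit("-", 600, 901)]  # 5' end at 900, pointing left
    (site,) = detect_divergent_sites(plus, minus)
    assert site.gap == 100
    assert (site.interval.start, site.interval.end) == (900, 1001)
    assert site.max_rpkm == 1.0


def test_gap_at_threshold_is_excluded():
    minus = [unit("-", 600, 901)]
    assert detect_divergent_sites([unit("+", 1200, 1700)], minus) == []  # gap 300
    assert len(detect_divergent_sites([unit("+", 1199, 1700)], minus)) == 1  # 299


def test_convergent_pairs_are_never_sites():
    # transcripts pointing toward each other: plus 5' left of minus 5'
    plus = [unit("+", 100, 400)]
    minus = [unit("-", 200, 501)]
    assert detect_divergent_sites(plus, minus) == []


def test_rpkm_floor_and_strict_both_switch():
    plus = [unit("+", 1000, 1500, rpkm=1.0)]
    minus = [unit("-", 600, 901, rpkm=0.1)]
    assert len(detect_divergent_sites(plus, minus, min_rpkm=0.2)) == 1
    assert detect_divergent_sites(plus, minus, min_rpkm=0.2, require_both=True) == []
    weak = [unit("+", 1000, 1500, rpkm=0.2)]
    assert detect_divergent_sites(weak, minus, min_rpkm=0.2) == []  # strict >


def test_degenerate_coincident_five_primes():
    (site,) = detect_divergent_sites([unit("+", 900, 1400)], [unit("-", 500, 901)])
    assert site.gap == 0 and site.interval.length == 1


def test_unsorted_input_rejected():
    plus = [unit("+", 1000, 1500), unit("+", 10, 20)]
    with pytest.raises(ValidationError):
        detect_divergent_sites(plus, [])


def _oracle_sites(plus, minus, max_gap=300, min_rpkm=0.2):
    """Independent all-pairs enumeration with the same pairing rules."""
    cands = []
    for mi, mu in enumerate(minus):
        for pi, pu in enumerate(plus):
            if mu.interval.chrom != pu.interval.chrom:
                continue
            gap = pu.five_prime - mu.five_prime
            if 0 <= gap < max_gap and max(pu.rpkm, mu.rpkm) > min_rpkm:
                cands.append((gap, mu.five_prime, mi, pi))
    cands.sort()
    used_m, used_p, out = set(), set(), []
    for gap, m5, mi, pi in cands:
        if mi in used_m or pi in used_p:
            continue
        used_m.add(mi)
        used_p.add(pi)
        out.append((minus[mi].five_prime, plus[pi].five_prime))
    return sorted(out)


def test_matching_is_a_matching_and_equals_oracle():
    rng = np.random.default_rng(23)
    for trial in range(50):
        plus, minus = [], []
        pos = 100
        for _ in range(rng.integers(3, 25)):
            pos += int(rng.integers(50, 600))
            length = int(rng.integers(60, 400))
            if rng.random() < 0.5:
                plus.append(unit("+", pos, pos + length, rpkm=float(rng.uniform(0, 2))))
            else:
                minus.append(unit("-", max(0, pos - length), pos + 1,
                                  rpkm=float(rng.uniform(0, 2))))
        key = lambda u: (u.interval.chrom, u.interval.start)
        plus.sort(key=key)
        minus.sort(key=key)
        sites = detect_divergent_sites(plus, minus)
        got = sorted((s.minus_unit.five_prime, s.plus_unit.five_prime) for s in sites)
        assert got == _oracle_sites(plus, minus)
        # matching property: each unit participates at most once
        assert len({id(s.plus_unit) for s in sites}) == len(sites)
        assert len({id(s.minus_unit) for s in sites}) == len(sites)
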