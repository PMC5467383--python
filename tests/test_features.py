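"""Feature extraction: classifiers, depth, the 49-vector, normalization."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from delfilter.candidates import CandidateDeletion
from delfilter.features import (FAMILY_SIZES, FEATURE_NAMES, N_FEATURES,
                                DEPTH_OFFSET, PAIR_OFFSET, SPLIT_OFFSET,
                                STAT_OFFSET, FeatureConfig, Normalizer,
                                classify_pair, classify_split_read,
                                estimate_insert_model, extract_features,
                                mean_depth)
from conftest import brute_force_mean_depth, make_bam, make_view

INSERT = (425.0, 50.0)


def _cand(start=10_000, end=12_000):
    return CandidateDeletion("chrT", start, end, source="x")


# ---------------------------------------------------------------------------
# pair classification

def test_concordant_clean_unique_pair():
    r1 = make_view(ref_start=425 - 79, template_length=-425, is_reverse=True,
                   mate_ref_start=0)
    r2 = make_view(ref_start=0, template_length=425, mate_ref_start=425 - 79)
    pc = classify_pair(r2, r1, INSERT)
    assert (pc.concordance, pc.error, pc.uniqueness) == \
        ("concordant", "error_free", "unique")


def test_three_sigma_insert_rule():
    # outer insert 925 vs mean 425, sd 50: |500| > 150 -> discordant
    r1 = make_view(ref_start=0)
    r2 = make_view(ref_start=925 - 79, is_reverse=True)
    assert classify_pair(r1, r2, INSERT).concordance == "discordant"
    # 570 is within 3 sigma (145 <= 150)
    r3 = make_view(ref_start=570 - 79, is_reverse=True)
    assert classify_pair(r1, r3, INSERT).concordance == "concordant"


def test_orientation_discordance():
    r1 = make_view(ref_start=0)               # forward
    r2 = make_view(ref_start=346)             # forward too -> not FR
    assert classify_pair(r1, r2, INSERT).concordance == "discordant"


def test_mismatch_and_uniqueness_flags():
    r1 = make_view(ref_start=0, n_mismatches=2)
    r2 = make_view(ref_start=346, is_reverse=True)
    pc = classify_pair(r1, r2, INSERT)
    assert pc.error == "with_mismatch"
    r3 = make_view(ref_start=346, is_reverse=True, mapq=5)
    assert classify_pair(r1, r3, INSERT).uniqueness == "multi"
    r4 = make_view(ref_start=346, is_reverse=True, has_alt_hits=True)
    assert classify_pair(r1, r4, INSERT).uniqueness == "multi"


def test_pair_must_span_the_candidate():
    cand = _cand(10_000, 12_000)
    left = make_view(ref_start=9_800)
    right = make_view(ref_start=12_100, is_reverse=True)
    assert classify_pair(left, right, INSERT, cand) is not None
    inside = make_view(ref_start=10_100)
    inside2 = make_view(ref_start=10_400, is_reverse=True)
    assert classify_pair(inside, inside2, INSERT, cand) is None


# ---------------------------------------------------------------------------
# split-read classification

def test_soft_clip_at_left_breakpoint():
    cand = _cand(10_000, 12_000)
    # 40M39S ending exactly at the left breakpoint, anchored upstream
    r = make_view(ref_start=10_000 - 40, cigar=((0, 40), (4, 39)))
    sc = classify_split_read(r, None, cand, INSERT)
    assert (sc.sort, sc.breakpoint_side, sc.anchor_side, sc.uniqueness) == \
        ("soft_clip", "left", "upstream", "unique")


def test_soft_clip_at_right_breakpoint_downstream_anchor():
    cand = _cand(10_000, 12_000)
    r = make_view(ref_start=12_000, cigar=((4, 30), (0, 49)))
    sc = classify_split_read(r, None, cand, INSERT)
    assert (sc.sort, sc.breakpoint_side, sc.anchor_side) == \
        ("soft_clip", "right", "downstream")


def test_clip_outside_tolerance_is_not_a_split():
    cand = _cand(10_000, 12_000)
    r = make_view(ref_start=10_000 - 40 - 25, cigar=((0, 40), (4, 39)))
    sc = classify_split_read(r, None, cand, INSERT)
    assert sc is None or sc.sort != "soft_clip"


def test_one_end_anchored_near_right_breakpoint():
    cand = _cand(10_000, 12_000)
    mate = make_view(ref_start=12_200)  # 200 bp after the end breakpoint
    r = make_view(is_mapped=False, ref_start=12_200, ref_end=12_200)
    sc = classify_split_read(r, mate, cand, INSERT)
    assert (sc.sort, sc.breakpoint_side, sc.anchor_side) == \
        ("one_end_anchored", "right", "downstream")


def test_fully_mapped_read_spanning_a_breakpoint():
    cand = _cand(10_000, 12_000)
    r = make_view(ref_start=10_000 - 30)  # 79M across the left breakpoint
    sc = classify_split_read(r, None, cand, INSERT)
    assert (sc.sort, sc.breakpoint_side) == ("fully_mapped", "left")


def test_read_inside_the_region_touches_no_breakpoint():
    cand = _cand(10_000, 12_000)
    r = make_view(ref_start=10_500)
    assert classify_split_read(r, None, cand, INSERT) is None


# ---------------------------------------------------------------------------
# depth

def test_mean_depth_trivial_cases(tmp_path):
    bam = make_bam(tmp_path / "d.bam",
                   [{"pos": 100, "cigar": ((0, 50),)} for _ in range(3)])
    with pysam.AlignmentFile(str(bam)) as b:
        assert mean_depth(b, "chrT", 5000, 6000) == 0.0
        assert mean_depth(b, "chrT", 100, 150) == 3.0
        with pytest.raises(ValueError):
            mean_depth(b, "chrT", 200, 200)


def test_mean_depth_matches_interval_arithmetic_oracle(tmp_path):
    rng = np.random.default_rng(0)
    for trial in range(20):
        reads = [{"pos": int(rng.integers(0, 1900)),
                  "cigar": ((0, int(rng.integers(30, 100))),)}
                 for _ in range(int(rng.integers(5, 60)))]
        bam = make_bam(tmp_path / f"d{trial}.bam", reads, contig_length=2_100)
        s = int(rng.integers(0, 1000))
        e = s + int(rng.integers(50, 800))
        with pysam.AlignmentFile(str(bam)) as b:
            got = mean_depth(b, "chrT", s, e)
        assert got == pytest.approx(brute_force_mean_depth(bam, "chrT", s, e))


# ---------------------------------------------------------------------------
# the 49-vector

def test_feature_family_partition():
    assert FAMILY_SIZES == (1, 8, 24, 4, 12)
    assert sum(FAMILY_SIZES) == N_FEATURES == 49
    assert len(FEATURE_NAMES) == 49
    assert (PAIR_OFFSET, SPLIT_OFFSET, DEPTH_OFFSET, STAT_OFFSET) == (1, 9, 33, 37)


def test_empty_bam_gives_length_and_zeros(tmp_path):
    bam_path = make_bam(tmp_path / "e.bam", [], contig_length=50_000)
    cfg = FeatureConfig(insert_mean=425.0, insert_sd=50.0)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        v = extract_features(bam, _cand(10_000, 12_000), cfg)
    assert v.shape == (49,)
    assert v[0] == 2_000
    assert np.all(v[1:] == 0)


def test_unknown_contig_rejected(tmp_path):
    bam_path = make_bam(tmp_path / "e2.bam", [], contig_length=50_000)
    cfg = FeatureConfig(insert_mean=425.0, insert_sd=50.0)
    cand = CandidateDeletion("chrZ", 100, 600)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        with pytest.raises(ValueError, match="chrZ"):
            extract_features(bam, cand, cfg)


def test_extraction_is_deterministic(small_sim):
    d = small_sim["deletions"][0]
    cand = CandidateDeletion(d.chrom, d.start, d.end)
    with pysam.AlignmentFile(str(small_sim["bam"])) as bam:
        v1 = extract_features(bam, cand)
        v2 = extract_features(bam, cand)
    assert np.array_equal(v1, v2)


def test_depth_features_on_simulated_deletions(small_sim):
    cfg = small_sim["config"]
    with pysam.AlignmentFile(str(small_sim["bam"])) as bam:
        for d in small_sim["deletions"]:
            if d.length < 400:
                continue
            v = extract_features(bam, CandidateDeletion(d.chrom, d.start, d.end))
            region, up, dn = v[DEPTH_OFFSET:DEPTH_OFFSET + 3]
            if d.zygosity == "homozygous":
                assert region < 1.0
            else:
                # heterozygous: roughly half the flanking depth
                assert region == pytest.approx((up + dn) / 4, rel=0.35)
            assert up == pytest.approx(cfg.target_depth, rel=0.3)
            assert dn == pytest.approx(cfg.target_depth, rel=0.3)


def test_pair_and_region_counts_match_brute_force_scan(small_sim):
    """The pair-consistency counts partition the classified spanning pairs,
    and the region read-count cells partition the reads overlapping the
    region -- both re-derived here by an independent whole-BAM scan."""
    cfg = small_sim["config"]
    with pysam.AlignmentFile(str(small_sim["bam"])) as bam:
        mean, sd = estimate_insert_model(bam)
        fcfg = FeatureConfig(insert_mean=mean, insert_sd=sd)
        pad = int(mean + 3 * sd + 100)
        dels = [d for d in small_sim["deletions"] if d.length >= 200][:6]
        for d in dels:
            cand = CandidateDeletion(d.chrom, d.start, d.end)
            v = extract_features(bam, cand, fcfg)

            # oracle: pair up primary records in the same fetch window
            by_name = {}
            for r in bam.fetch(cfg.chrom, max(0, d.start - pad),
                               min(cfg.genome_length, d.end + pad)):
                if r.is_secondary or r.is_supplementary:
                    continue
                by_name.setdefault(r.query_name, []).append(r)
            n_spanning = 0
            n_discordant = 0
            for recs in by_name.values():
                if len(recs) != 2:
                    continue
                a, b = recs
                if a.is_unmapped or b.is_unmapped:
                    continue
                os_ = min(a.reference_start, b.reference_start)
                oe = max(a.reference_end, b.reference_end)
                if not (os_ < d.start and oe > d.end):
                    continue
                n_spanning += 1
                left, right = (a, b) if a.reference_start <= b.reference_start else (b, a)
                fr = (not left.is_reverse) and right.is_reverse
                if abs((oe - os_) - mean) > 3 * sd or not fr:
                    n_discordant += 1
            assert v[PAIR_OFFSET:PAIR_OFFSET + 8].sum() == n_spanning
            assert v[PAIR_OFFSET:PAIR_OFFSET + 4].sum() == n_discordant

            # oracle: reads overlapping the region itself
            n_region = sum(
                1 for r in bam.fetch(cfg.chrom, d.start, d.end)
                if not (r.is_unmapped or r.is_secondary or r.is_supplementary))
            assert v[STAT_OFFSET:STAT_OFFSET + 4].sum() == n_region


# ---------------------------------------------------------------------------
# normalization

def test_minmax_scaling_basic():
    X = np.array([[0.0], [5.0], [10.0]])
    norm = Normalizer().fit(X)
    assert norm.transform(X).ravel().tolist() == [0.0, 0.5, 1.0]
    # unseen values clip into [0, 1]
    assert norm.transform(np.array([[12.0]]))[0, 0] == 1.0
    assert norm.transform(np.array([[-3.0]]))[0, 0] == 0.0


def test_constant_feature_maps_to_zero():
    X = np.full((4, 2), 7.0)
    X[:, 1] = [1, 2, 3, 4]
    out = Normalizer().fit(X).transform(X)
    assert np.all(out[:, 0] == 0.0)


def test_unfitted_normalizer_rejected():
    with pytest.raises(RuntimeError):
        Normalizer().transform(np.zeros((1, 2)))


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=3),
                min_size=2, max_size=20))
def test_normalized_output_always_in_unit_interval(rows):
    X = np.asarray(rows)
    out = Normalizer().fit(X).transform(X)
    assert np.all(out >= 0.0) and np.all(out <= 1.0)
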