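"""Site algebra: BED I/O, filters, replicate/nearby merging, exon overlap,
border distances and pair detection."""

import numpy as np
import pytest

from txcontext.annotation import merged_exon_union
from txcontext.core import GenomeInterval, TranscriptModel
from txcontext.sites import (
    Thresholds,
    border_distance,
    classify_exonic,
    detect_pairs,
    filter_sites,
    merge_nearby,
    merge_replicates,
    read_bed,
    write_bed,
)


def gi(start, end, score=1.0, strand="+", sid=None, chrom="chr1", pvalue=None):
    return GenomeInterval(chrom, start, end, strand,
                          sid or f"s{start}_{end}", score, pvalue)


# ---------------------------------------------------------------- BED I/O

def test_read_bed_parses_six_columns(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t20\ts1\t2.5\t+\n")
    (s,) = read_bed(str(p))
    assert (s.chrom, s.start, s.end, s.strand, s.id, s.score) == (
        "chr1", 10, 20, "+", "s1", 2.5
    )


def test_read_bed_empty_file(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("")
    assert read_bed(str(p)) == []


def test_read_bed_errors_name_line_numbers(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t20\ts\t1\t+\nchr1\t30\tnope\n")
    with pytest.raises(ValueError, match=":2"):
        read_bed(str(p))
    p.write_text("chr1\t20\t10\n")
    with pytest.raises(ValueError, match=":1"):
        read_bed(str(p))


def test_write_read_round_trip_is_byte_stable(tmp_path):
    sites = [gi(10, 20, 2.5), gi(30, 40, 3.0, "-", pvalue=0.001)]
    p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(sites, str(p1))
    write_bed(read_bed(str(p1), pvalue_col=6), str(p2))
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------- filtering

@pytest.mark.parametrize(
    "length, lfc, pvalue, kept",
    [
        (81, 5.0, 0.001, False),   # too long
        (80, 3.0, 0.01, True),     # all bounds inclusive
        (40, 2.9, 0.001, False),   # LFC below minimum
        (40, 3.0, 0.02, False),    # p-value above maximum
    ],
)
def test_context_preset_filter(length, lfc, pvalue, kept):
    thr = Thresholds.context_preset()  # max_len 80, min LFC 3, max p 0.01
    site = gi(0, length, lfc, pvalue=pvalue)
    assert (filter_sites([site], thr) == [site]) is kept


def test_lfc_only_filter_drops_exactly_sub_threshold_sites():
    thr = Thresholds(min_lfc=1.0)
    sites = [gi(0, 10, 0.99), gi(20, 30, 1.0), gi(40, 50, 4.0)]
    assert [s.score for s in filter_sites(sites, thr)] == [1.0, 4.0]


# ---------------------------------------------------------------- merging

def test_merge_replicates_keeps_highest_lfc_of_overlap():
    a, b = gi(10, 20, 2.0), gi(15, 25, 3.0)
    merged = merge_replicates([a], [b])
    assert merged == [b]


def test_merge_replicates_passes_disjoint_sites_through():
    a, b = gi(10, 20, 2.0), gi(30, 40, 1.0)
    assert sorted(merge_replicates([a], [b]), key=lambda s: s.start) == [a, b]


def test_merge_replicates_transitive_chain_single_winner():
    chain = [gi(10, 20, 1.0), gi(18, 28, 5.0), gi(26, 36, 2.0)]
    merged = merge_replicates(chain[:1], chain[1:])
    assert [(m.start, m.end) for m in merged] == [(18, 28)]


def test_merge_replicates_strand_separated():
    a, b = gi(10, 20, 2.0, "+"), gi(15, 25, 3.0, "-")
    assert len(merge_replicates([a], [b])) == 2


def test_merge_nearby_gap_below_threshold_merges():
    merged = merge_nearby([gi(10, 20, 2.0), gi(25, 35, 4.0)], merge_dist=10)
    assert [(m.start, m.end) for m in merged] == [(25, 35)]


def test_merge_nearby_gap_exactly_threshold_keeps_both():
    merged = merge_nearby([gi(10, 20, 2.0), gi(30, 40, 4.0)], merge_dist=10)
    assert len(merged) == 2


def test_merge_single_site_unchanged():
    s = gi(10, 20)
    assert merge_nearby([s], 10) == [s]


def test_merges_are_idempotent_order_invariant_and_conservative():
    rng = np.random.default_rng(3)
    sites = []
    for i in range(60):
        start = int(rng.integers(0, 500))
        sites.append(gi(start, start + int(rng.integers(5, 30)),
                        float(rng.uniform(0, 5)), sid=f"r{i}"))
    once = merge_nearby(sites, 10)
    assert merge_nearby(once, 10) == once          # idempotent
    shuffled = [sites[i] for i in rng.permutation(len(sites))]
    assert merge_nearby(shuffled, 10) == once      # order-invariant
    ids = {s.id for s in sites}
    assert all(s.id in ids for s in once)          # coordinates never altered
    assert len(once) <= len(sites)


# ------------------------------------------------------- exon classification

def _union(*exon_lists, strand="+"):
    models = [
        TranscriptModel(transcript_id=f"t{i}", gene_id=f"g{i}", chrom="chr1",
                        strand=strand, exons=tuple(exons))
        for i, exons in enumerate(exon_lists)
    ]
    return merged_exon_union(models)


def test_site_fully_inside_exon_is_exonic():
    [(flag, frac)] = classify_exonic([gi(120, 150)], _union([(100, 200)]))
    assert flag and frac == 1.0


def test_overlap_fraction_just_below_threshold_is_not_exonic():
    # 89 of 100 bases exonic
    [(flag, frac)] = classify_exonic([gi(11, 111)], _union([(0, 100)]), 0.90)
    assert not flag and frac == pytest.approx(0.89)


def test_site_spanning_two_exons_uses_union_overlap():
    union = _union([(100, 150), (155, 300)])
    [(flag, frac)] = classify_exonic([gi(110, 210)], union, 0.90)
    assert flag and frac == pytest.approx(0.95)


def test_strand_mismatch_gives_zero_overlap_and_dot_matches_both():
    union = _union([(100, 200)], strand="+")
    [(flag, _)] = classify_exonic([gi(120, 150, strand="-")], union)
    assert not flag
    [(flag, frac)] = classify_exonic([gi(120, 150, strand=".")], union)
    assert flag and frac == 1.0


def test_classify_agrees_with_per_base_oracle(dataset):
    union = merged_exon_union(dataset.transcriptome.values())
    exonic_bases = {
        strand: {
            (chrom, g)
            for (chrom, st), ivs in union.items() if st == strand
            for s, e in ivs for g in range(s, e)
        }
        for strand in "+-"
    }
    rng = np.random.default_rng(2)
    chroms = list(dataset.chroms)
    sites = []
    for i in range(300):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, len(dataset.chroms[chrom]) - 80))
        strand = "+-."[int(rng.integers(3))]
        sites.append(gi(start, start + int(rng.integers(10, 60)),
                        strand=strand, chrom=chrom, sid=f"x{i}"))
    results = classify_exonic(sites, union, 0.90)
    for s, (flag, frac) in zip(sites, results):
        strands = "+-" if s.strand == "." else s.strand
        n = sum(
            1 for g in range(s.start, s.end)
            if any((s.chrom, g) in exonic_bases[st] for st in strands)
        )
        assert frac == pytest.approx(n / len(s))
        assert flag == (n / len(s) >= 0.90)


# ------------------------------------------------------- border distances

def _two_exon_model(strand="+"):
    return TranscriptModel(transcript_id="t1", gene_id="g1", chrom="chr1",
                           strand=strand, exons=((100, 200), (300, 400)))


def test_border_distance_flush_start():
    bd = border_distance(gi(100, 120), _two_exon_model())
    assert (bd.dist_five, bd.dist_three) == (0, 80)
    assert bd.min_dist == 0 and bd.near_border(0)


def test_border_distance_interior_site():
    bd = border_distance(gi(140, 160), _two_exon_model())
    assert bd.min_dist == 40
    assert bd.near_border(50) and not bd.near_border(10)


def test_border_distance_flush_both_borders():
    m = TranscriptModel(transcript_id="t", gene_id="g", chrom="chr1",
                        strand="+", exons=((100, 130),))
    bd = border_distance(gi(100, 130), m)
    assert (bd.dist_five, bd.dist_three) == (0, 0)


def test_border_distance_minus_strand_swaps_ends():
    bd = border_distance(gi(300, 320, strand="-"), _two_exon_model("-"))
    # on the minus strand exon (300,400) is the 5'-most exon (index 1)
    assert (bd.dist_five, bd.dist_three) == (80, 0)
    assert bd.exon_index_five == 1


def test_border_distance_intronic_end_raises():
    with pytest.raises(ValueError, match="intron"):
        border_distance(gi(190, 210), _two_exon_model())


# ------------------------------------------------------- pair detection

def _assign(sites, model):
    return {s.id: model for s in sites}


def test_pair_detected_at_adjacent_borders():
    m = _two_exon_model()
    s1, s2 = gi(180, 197, 2.0, sid="a"), gi(303, 330, 2.0, sid="b")
    assert detect_pairs([s1, s2], _assign([s1, s2], m), 10) == [("a", "b")]


def test_no_pair_when_distance_reaches_threshold():
    m = _two_exon_model()
    s1, s2 = gi(180, 197, 2.0, sid="a"), gi(315, 330, 2.0, sid="b")
    assert detect_pairs([s1, s2], _assign([s1, s2], m), 10) == []


def test_no_pair_across_non_adjacent_exons():
    m = TranscriptModel(transcript_id="t1", gene_id="g1", chrom="chr1", strand="+",
                        exons=((100, 200), (300, 400), (500, 600)))
    s1, s2 = gi(190, 199, 2.0, sid="a"), gi(501, 520, 2.0, sid="b")
    assert detect_pairs([s1, s2], _assign([s1, s2], m), 10) == []


def test_each_site_joins_at_most_one_pair_highest_lfc_wins():
    m = _two_exon_model()
    s1a = gi(180, 197, 1.0, sid="low")
    s1b = gi(175, 195, 4.0, sid="high")
    s2 = gi(303, 330, 2.0, sid="right")
    pairs = detect_pairs([s1a, s1b, s2], _assign([s1a, s1b, s2], m), 10)
    assert pairs == [("high", "right")]


def test_planted_pairs_recovered_from_fixture(dataset):
    from txcontext.coordmap import assign_to_transcriptome

    exonic_ids = {
        s["id"] for s in dataset.truth["sites"]
        if s["category"] in ("exonic_far", "near_border", "pair_member")
    }
    exonic = [s for s in dataset.sites if s.id in exonic_ids]
    assignment = assign_to_transcriptome(exonic, dataset.transcriptome)
    pairs = detect_pairs(exonic, assignment, 10)
    assert sorted(pairs) == sorted(tuple(p) for p in dataset.truth["pairs"])
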