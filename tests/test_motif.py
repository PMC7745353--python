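"""Motif grammar parsing, gapped scanning vs exhaustive enumeration,
hit deduplication, split mapping and frequency comparison."""

import itertools

import numpy as np
import pytest

from txcontext.core import TranscriptModel
from txcontext.motif import (
    IGF2BP3_COMPOUND,
    IUPAC,
    PUM2_PRE,
    Motif,
    MotifElement,
    MotifHit,
    compare_frequencies,
    dedupe_hits,
    map_hit_to_genome,
    parse_motif,
    scan,
)

# ------------------------------------------------------------- parsing

def test_parse_plain_iupac_single_block():
    m = parse_motif("ACGT")
    assert m.elements == (MotifElement("ACGT", 0, 0),)


def test_parse_pre_normalises_rna_alphabet():
    m = parse_motif(PUM2_PRE)
    assert m.elements == (MotifElement("TGTANATA", 0, 0),)


def test_parse_compound_motif_blocks_and_gaps():
    m = parse_motif(IGF2BP3_COMPOUND)
    assert [e.block for e in m.elements] == ["GGC", "CA", "CA", "GGC", "CACACACA"]
    assert [(e.gap_min, e.gap_max) for e in m.elements[1:]] == [
        (15, 25), (7, 20), (15, 25), (2, 8)
    ]
    assert m.min_length == 3 + 15 + 2 + 7 + 2 + 15 + 3 + 2 + 8


@pytest.mark.parametrize(
    "bad", ["", "ACXGT", "GGC-N{25-15}-CA", "ACG-N{2-4}", "N{1-2}-ACG"]
)
def test_parse_errors(bad):
    with pytest.raises(ValueError):
        parse_motif(bad)


# ------------------------------------------------------------- scanning

def test_scan_pre_iupac_n_matches_any_base():
    hits = scan("TGTACATA", parse_motif(PUM2_PRE))
    assert len(hits) == 1 and hits[0].start == 0 and hits[0].matched == "TGTACATA"


def test_scan_no_hit():
    assert scan("AAAA", parse_motif("ACGT")) == []


def test_sequence_n_matches_only_motif_n():
    assert scan("ANGT", parse_motif("ACGT")) == []
    assert scan("ANGT", parse_motif("ANGT")) != []
    assert scan("AAGT", parse_motif("ANGT")) != []


def test_overlapping_hits_at_different_starts_all_reported():
    hits = scan("AAAA", parse_motif("AA"))
    assert [h.start for h in hits] == [0, 1, 2]


def test_gapped_scan_reports_minimal_gap_assignment():
    motif = parse_motif("AC-N{1-5}-GT")
    hits = scan("ACTTGTAGT", motif)
    # start 0 admits gaps of 2 (end 8? no: AC..GT at pos 4) — minimal is gap 2
    assert hits[0].start == 0
    assert hits[0].matched == "ACTTGT"


def brute_force_starts(seq, motif):
    """Oracle: exhaustive enumeration over all gap-length combinations."""
    starts = set()
    ranges = [range(e.gap_min, e.gap_max + 1) for e in motif.elements[1:]]
    for start in range(len(seq)):
        for gaps in itertools.product(*ranges):
            pos = start
            ok = True
            for elem, gap in zip(motif.elements, (0,) + tuple(gaps)):
                pos += gap
                block = elem.block
                if pos + len(block) > len(seq) or any(
                    seq[pos + i] not in IUPAC[c] for i, c in enumerate(block)
                ):
                    ok = False
                    break
                pos += len(block)
            if ok:
                starts.add(start)
                break
    return starts


def random_motif(rng):
    n_blocks = int(rng.integers(1, 4))
    elements = []
    letters = "ACGTRYN"
    for i in range(n_blocks):
        block = "".join(
            letters[int(rng.integers(len(letters)))]
            for _ in range(int(rng.integers(2, 5)))
        )
        if i == 0:
            elements.append(MotifElement(block, 0, 0))
        else:
            a = int(rng.integers(0, 4))
            b = a + int(rng.integers(0, 4))
            elements.append(MotifElement(block, a, b))
    return Motif("rand", tuple(elements))


def test_scan_equals_exhaustive_enumeration_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(60):
        seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(50, 300)),
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        motif = random_motif(rng)
        assert {h.start for h in scan(seq, motif)} == brute_force_starts(seq, motif)


# ------------------------------------------------------------- dedup

def _hit(start, end, motif_id="m", target="chr1"):
    return MotifHit(motif_id, target, "genomic", start, end, "X" * (end - start))


def test_dedupe_same_absolute_position_counted_once():
    assert len(dedupe_hits([_hit(5, 10), _hit(5, 10)])) == 1


def test_dedupe_different_motifs_kept():
    assert len(dedupe_hits([_hit(5, 10, "m1"), _hit(5, 10, "m2")])) == 2


def test_dedupe_empty():
    assert dedupe_hits([]) == []


def test_dedupe_invariant_to_window_tiling():
    """Hits from windows shifted by 10 nt resolve to the same absolute keys."""
    hits_a = [_hit(30, 38)]  # window at offset 0
    hits_b = [_hit(20, 28)]  # same genomic match seen from a window 10 nt right
    deduped = dedupe_hits(
        hits_a + hits_b,
        resolver=lambda h: ("chr1", "+", h.start + (0 if h in hits_a else 10),
                            h.end + (0 if h in hits_a else 10)),
    )
    assert len(deduped) == 1


# ------------------------------------------------------------- split mapping

def _model(exons, strand="+"):
    return TranscriptModel(transcript_id="t1", gene_id="g1", chrom="chr1",
                           strand=strand, exons=exons)


def test_hit_straddling_junction_maps_to_two_blocks():
    m = _model(((100, 150), (200, 250)))
    hit = MotifHit("m", "t1", "transcript", 45, 53, "TGTANATA")
    map_hit_to_genome(hit, m)
    assert [(b.start, b.end) for b in hit.genome_blocks] == [(145, 150), (200, 203)]
    assert hit.is_split


def test_hit_within_one_exon_is_not_split():
    m = _model(((100, 150), (200, 250)))
    hit = MotifHit("m", "t1", "transcript", 10, 18, "X" * 8)
    map_hit_to_genome(hit, m)
    assert len(hit.genome_blocks) == 1 and not hit.is_split


def test_multi_junction_hit_block_lengths_conserve_match_length():
    m = _model(((0, 10), (20, 30), (40, 50), (60, 70), (80, 90)))
    hit = MotifHit("m", "t1", "transcript", 5, 45, "X" * 40)
    map_hit_to_genome(hit, m)
    assert len(hit.genome_blocks) == 5
    assert sum(len(b) for b in hit.genome_blocks) == 40


# ------------------------------------------------------------- frequencies

@pytest.mark.parametrize(
    "ht, lt, hg, lg, expected",
    [
        (10, 1000, 5, 1000, 100.0),
        (5, 500, 10, 2000, 100.0),
        (5, 1000, 5, 1000, 0.0),
    ],
)
def test_compare_frequencies_percent_change(ht, lt, hg, lg, expected):
    _, _, change = compare_frequencies(ht, lt, hg, lg)
    assert change == pytest.approx(expected)


def test_compare_frequencies_zero_genomic_hits_flagged_undefined():
    dt, dg, change = compare_frequencies(3, 1000, 0, 1000)
    assert change is None and dg == 0


def test_compare_frequencies_zero_length_errors():
    with pytest.raises(ValueError):
        compare_frequencies(1, 0, 1, 10)
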