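"""IUPAC motif parsing, scanning with bounded gaps, and split-motif mapping.

Motifs are written in a small grammar: IUPAC blocks (RNA ``U`` accepted and
normalised to ``T``), bounded unspecified spacers ``N{a-b}`` between blocks,
and repeat shorthand ``[XY]k``. Examples:

* the Pumilio response element (PRE): ``UGUANAUA``
* a multi-block compound motif: ``GGC-N{15-25}-CA-N{7-20}-CA-N{15-25}-GGC-N{2-8}-[CA]4``

Scanning reports one hit per admissible start position (minimal total gap
assignment) so that gap-assignment multiplicity never inflates positional hit
counts. Hits found in spliced-transcript space can be mapped back to the
genome, where a hit crossing splice junctions splits into several blocks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core import GenomeInterval, TranscriptInterval, TranscriptModel
from .coordmap import transcript_to_genome

IUPAC: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    # Sequence N matches only motif N: masked genome regions must not produce
    # phantom hits under degenerate motif letters.
    "N": frozenset("ACGTN"),
}


@dataclass(frozen=True)
class MotifElement:
    """One IUPAC block preceded by a bounded gap (first block has gap 0,0)."""

    block: str
    gap_min: int = 0
    gap_max: int = 0


@dataclass
class Motif:
    motif_id: str
    elements: Tuple[MotifElement, ...]
    source: str = ""

    @property
    def min_length(self) -> int:
        return sum(len(e.block) + e.gap_min for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(len(e.block) + e.gap_max for e in self.elements)


@dataclass
class MotifHit:
    """A motif match within a target sequence.

    Coordinates are 0-based half-open within ``target_id`` (a context-window
    id, transcript id or chromosome). ``genome_blocks`` is filled by
    :func:`map_hit_to_genome`; a hit is junction-split iff it has >= 2 blocks.
    """

    motif_id: str
    target_id: str
    space: str  # "genomic" | "transcript"
    start: int
    end: int
    matched: str
    genome_blocks: Optional[List[GenomeInterval]] = None

    @property
    def is_split(self) -> bool:
        return self.genome_blocks is not None and len(self.genome_blocks) >= 2


_TOKEN = re.compile(
    r"""
    \[(?P<rep_block>[ACGUTRYSWKMBDHVN]+)\](?P<rep_count>\d+)   # [XY]k repeat
    | N\{(?P<gap_min>\d+)[-−–](?P<gap_max>\d+)\}     # N{a-b} gap
    | (?P<block>[ACGUTRYSWKMBDHVN]+)                           # IUPAC block
    | (?P<sep>[-\s]+)                                          # separators
    """,
    re.VERBOSE,
)


def parse_motif(spec: str, motif_id: Optional[str] = None) -> Motif:
    """Parse a motif grammar string into a canonical :class:`Motif`.

    RNA ``U`` is normalised to ``T``. A plain IUPAC string yields a single
    block with zero gap. Raises ValueError (naming the character position)
    for unknown letters, inverted gap bounds or zero-length blocks.
    """
    upper = spec.strip().upper()
    if not upper:
        raise ValueError("empty motif string")
    elements: List[MotifElement] = []
    pending_gap: Optional[Tuple[int, int]] = None
    pos = 0
    while pos < len(upper):
        m = _TOKEN.match(upper, pos)
        if not m:
            raise ValueError(f"motif {spec!r}: unrecognised token at position {pos}")
        if m.group("sep"):
            pos = m.end()
            continue
        if m.group("gap_min") is not None:
            a, b = int(m.group("gap_min")), int(m.group("gap_max"))
            if a > b:
                raise ValueError(
                    f"motif {spec!r}: gap bounds {a}-{b} inverted at position {pos}"
                )
            if pending_gap is not None:
                raise ValueError(
                    f"motif {spec!r}: two consecutive gaps at position {pos}"
                )
            if not elements:
                raise ValueError(f"motif {spec!r}: gap before first block")
            pending_gap = (a, b)
        else:
            if m.group("rep_block") is not None:
                block = m.group("rep_block") * int(m.group("rep_count"))
            else:
                block = m.group("block")
            block = block.replace("U", "T")
            if not block:
                raise ValueError(f"motif {spec!r}: zero-length block at position {pos}")
            gap = pending_gap or (0, 0)
            if elements and pending_gap is None:
                # adjacent blocks without an explicit gap concatenate
                prev = elements.pop()
                elements.append(MotifElement(prev.block + block, prev.gap_min, prev.gap_max))
            else:
                elements.append(MotifElement(block, gap[0], gap[1]))
            pending_gap = None
        pos = m.end()
    if pending_gap is not None:
        raise ValueError(f"motif {spec!r}: trailing gap without a following block")
    if not elements:
        raise ValueError(f"motif {spec!r}: no IUPAC blocks found")
    return Motif(motif_id or upper, tuple(elements), source=spec)


def _block_matches(seq: str, pos: int, block: str) -> bool:
    if pos + len(block) > len(seq):
        return False
    for i, letter in enumerate(block):
        if seq[pos + i] not in IUPAC[letter]:
            return False
    return True


def _match_from(
    seq: str, pos: int, elements: Sequence[MotifElement], idx: int
) -> Optional[List[Tuple[int, str]]]:
    """Block placements of a match of elements[idx:] anchored at ``pos``,
    trying shorter gaps first (minimal total gap, leftmost-greedy); None if
    no gap assignment fits."""
    if idx == len(elements):
        return []
    elem = elements[idx]
    for gap in range(elem.gap_min, elem.gap_max + 1):
        p = pos + gap
        if _block_matches(seq, p, elem.block):
            rest = _match_from(seq, p + len(elem.block), elements, idx + 1)
            if rest is not None:
                return [(p, elem.block)] + rest
    return None


def match_at(seq: str, start: int, motif: Motif) -> Optional[List[Tuple[int, str]]]:
    """Block placements [(block_start, block), ...] of the minimal-total-gap
    match of ``motif`` anchored at ``start``, or None when no assignment
    fits."""
    first = motif.elements[0]
    if not _block_matches(seq, start, first.block):
        return None
    rest = _match_from(seq, start + len(first.block), motif.elements, 1)
    if rest is None:
        return None
    return [(start, first.block)] + rest


def scan(
    sequence: str,
    motif: Motif,
    target_id: str = "",
    space: str = "genomic",
) -> List[MotifHit]:
    """Scan a sequence (A/C/G/T/N, sense strand) for motif matches.

    Every start position admitting at least one gap-length assignment yields
    exactly one hit (the minimal-total-gap assignment); overlapping hits at
    different starts are all reported. Sequence ``N`` matches only motif
    ``N``.
    """
    seq = sequence.upper()
    hits: List[MotifHit] = []
    last_start = len(seq) - motif.min_length
    for start in range(0, last_start + 1):
        placements = match_at(seq, start, motif)
        if placements is not None:
            last_pos, last_block = placements[-1]
            end = last_pos + len(last_block)
            hits.append(
                MotifHit(motif.motif_id, target_id, space, start, end, seq[start:end])
            )
    return hits


def dedupe_hits(
    hits: Iterable[MotifHit],
    resolver=None,
) -> List[MotifHit]:
    """Drop hits at identical absolute positions, keeping first occurrences.

    Overlapping context windows can contain the same match; a hit is counted
    once per (space, absolute target, strand, start, end, motif). ``resolver``
    maps a hit to its absolute key ``(target, strand, start, end)``; by
    default the hit's own target/coordinates are used with strand '+'.
    """
    if resolver is None:
        resolver = lambda h: (h.target_id, "+", h.start, h.end)
    seen: Set[tuple] = set()
    out: List[MotifHit] = []
    for h in hits:
        target, strand, start, end = resolver(h)
        key = (h.space, target, strand, start, end, h.motif_id)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def hit_absolute_interval(
    hit: MotifHit, center: int, strand: str, viewpoint_start: int
) -> Tuple[int, int]:
    """Absolute coordinates of a context-window hit.

    ``center`` is the absolute coordinate (genomic or spliced) of the window's
    center base and ``viewpoint_start`` its offset within the window sequence.
    For genomic minus-strand windows the sequence is reverse-complemented, so
    window offsets run against genomic coordinates.
    """
    if strand == "-":
        return (
            center + viewpoint_start - hit.end + 1,
            center + viewpoint_start - hit.start + 1,
        )
    return (
        center - viewpoint_start + hit.start,
        center - viewpoint_start + hit.end,
    )


def map_hit_to_genome(hit: MotifHit, model: TranscriptModel) -> MotifHit:
    """Resolve a transcript-space hit to its genomic block structure.

    ``hit.start``/``hit.end`` must already be absolute spliced-transcript
    coordinates. The hit is junction-split iff it maps to >= 2 blocks.
    """
    if hit.space != "transcript":
        raise ValueError(f"hit {hit.motif_id}@{hit.start} is not in transcript space")
    tiv = TranscriptInterval(model.transcript_id, hit.start, hit.end, id=hit.motif_id)
    hit.genome_blocks = transcript_to_genome(tiv, model)
    return hit


def compare_frequencies(
    hits_t: int, len_t: int, hits_g: int, len_g: int
) -> Tuple[float, float, Optional[float]]:
    """Length-normalised motif densities and their percent change.

    Densities are hits per nt of total context-set length; percent change is
    ``100 * (density_t / density_g - 1)``, or None (undefined) when the
    genomic context has zero hits.
    """
    if len_t <= 0 or len_g <= 0:
        raise ValueError("context set lengths must be positive")
    density_t = hits_t / len_t
    density_g = hits_g / len_g
    if hits_g == 0:
        return density_t, density_g, None
    return density_t, density_g, 100.0 * (density_t / density_g - 1.0)


# Motifs printed in the study this toolkit reproduces, usable as defaults.
PUM2_PRE = "UGUANAUA"
IGF2BP3_COMPOUND = "GGC-N{15-25}-CA-N{7-20}-CA-N{15-25}-GGC-N{2-8}-[CA]4"
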