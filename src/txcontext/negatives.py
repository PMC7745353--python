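"""Negative (non-bound) site sampling for classifier training sets.

Negatives are drawn uniformly from the spans of genes that carry at least one
positive site, with zero base overlap with any positive and (to avoid
duplicate training examples) no overlap among the negatives themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .core import GenomeInterval, TranscriptModel


@dataclass
class NegativeSet:
    sites: List[GenomeInterval]
    requested: int
    exhausted: bool  # True when fewer eligible positions than requested

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)


def _subtract(intervals: List[Tuple[int, int]], cut: Tuple[int, int]) -> List[Tuple[int, int]]:
    """Remove ``cut`` from a sorted disjoint interval list."""
    out = []
    cs, ce = cut
    for s, e in intervals:
        if e <= cs or s >= ce:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs))
        if ce < e:
            out.append((ce, e))
    return out


def sample_negatives(
    transcriptome: Dict[str, TranscriptModel],
    positives: Sequence[GenomeInterval],
    n: int,
    site_len: int = 161,
    seed: int = 0,
) -> NegativeSet:
    """Sample ``n`` negative sites of length ``site_len``.

    Eligible genes are those (gene span = first to last exon of the retained
    isoform) with >= 1 nt overlap with a positive on a compatible strand.
    Start positions are sampled uniformly over all positions whose site would
    lie fully inside a covered gene span and overlap no positive on that
    chromosome; accepted negatives additionally exclude each other's
    neighbourhood so the output is mutually non-overlapping. Deterministic
    for a fixed seed. If the eligible space is exhausted before ``n`` sites,
    all that could be drawn are returned with ``exhausted=True``.

    Raises ValueError when no gene is covered by any positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if site_len < 1:
        raise ValueError("site_len must be >= 1")

    by_chrom_pos: Dict[str, List[GenomeInterval]] = {}
    for p in positives:
        by_chrom_pos.setdefault(p.chrom, []).append(p)

    covered: List[TranscriptModel] = []
    for gene_id in sorted(transcriptome):
        m = transcriptome[gene_id]
        span_s, span_e = m.span
        for p in by_chrom_pos.get(m.chrom, []):
            if p.strands_compatible(m.strand) and p.start < span_e and p.end > span_s:
                covered.append(m)
                break
    if not covered:
        raise ValueError("no gene is covered by any positive site")

    # Allowed start positions per covered gene: inside the span, not touching
    # any positive on the chromosome.
    allowed: List[Tuple[str, str, List[Tuple[int, int]]]] = []
    for m in covered:
        span_s, span_e = m.span
        if span_e - span_s < site_len:
            continue
        starts = [(span_s, span_e - site_len + 1)]
        for p in by_chrom_pos.get(m.chrom, []):
            # a start s collides with positive p iff [s, s+L) overlaps p
            starts_new = []
            for iv in starts:
                starts_new.extend(_subtract([iv], (p.start - site_len + 1, p.end)))
            starts = starts_new
        if starts:
            allowed.append((m.chrom, m.strand, starts))

    rng = np.random.default_rng(seed)
    negatives: List[GenomeInterval] = []
    idx = 0
    while len(negatives) < n:
        total = sum(e - s for _, _, ivs in allowed for s, e in ivs)
        if total == 0:
            return NegativeSet(negatives, n, exhausted=True)
        pick = int(rng.integers(total))
        for gi, (chrom, strand, ivs) in enumerate(allowed):
            for s, e in ivs:
                if pick < e - s:
                    start = s + pick
                    idx += 1
                    negatives.append(
                        GenomeInterval(
                            chrom, start, start + site_len, strand, f"neg_{idx}"
                        )
                    )
                    # forbid overlap with this negative from now on
                    allowed[gi] = (
                        chrom,
                        strand,
                        _subtract(ivs, (start - site_len + 1, start + site_len)),
                    )
                    break
                pick -= e - s
            else:
                continue
            break
    return NegativeSet(negatives, n, exhausted=False)
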