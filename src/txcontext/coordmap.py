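"""Bidirectional mapping between genomic and spliced-transcript coordinates.

Transcript coordinates run 5'->3' of the mRNA: on a minus-strand model the
genomic base ``end - 1`` of the 3'-most genomic exon maps to transcript
position 0. Intervals mapped back to the genome may split into several blocks
separated exactly by whole introns of the model.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from pyfaidx import Fasta

from .core import GenomeInterval, TranscriptInterval, TranscriptModel, reverse_complement


@dataclass
class MappingReport:
    """Result of mapping a genomic interval that is not fully exonic.

    ``interval`` is the spliced image of the exonic bases (None when there is
    no exonic overlap at all); ``exonic_bases``/``total_bases`` give the
    overlap breakdown so callers can apply their own overlap-fraction policy.
    """

    transcript_id: str
    exonic_bases: int
    total_bases: int
    interval: Optional[TranscriptInterval] = None

    @property
    def exonic_fraction(self) -> float:
        return self.exonic_bases / self.total_bases

    @property
    def no_exonic_overlap(self) -> bool:
        return self.exonic_bases == 0


def _cumulative_starts(model: TranscriptModel) -> List[int]:
    """Spliced offset (in genomic 5'->3' i.e. plus-strand order) of each exon start."""
    offsets = []
    total = 0
    for s, e in model.exons:
        offsets.append(total)
        total += e - s
    return offsets


def genomic_to_spliced_pos(pos: int, model: TranscriptModel) -> Optional[int]:
    """Spliced coordinate of a single genomic base, or None if intronic/outside."""
    offsets = _cumulative_starts(model)
    idx = bisect.bisect_right([s for s, _ in model.exons], pos) - 1
    if idx < 0:
        return None
    s, e = model.exons[idx]
    if pos >= e:
        return None
    plus_pos = offsets[idx] + (pos - s)
    if model.strand == "+":
        return plus_pos
    return model.spliced_length - 1 - plus_pos


def spliced_to_genomic_pos(tpos: int, model: TranscriptModel) -> int:
    """Genomic coordinate of a single spliced base."""
    if not (0 <= tpos < model.spliced_length):
        raise ValueError(
            f"transcript {model.transcript_id}: spliced position {tpos} outside "
            f"[0, {model.spliced_length})"
        )
    plus_pos = tpos if model.strand == "+" else model.spliced_length - 1 - tpos
    for (s, e), off in zip(model.exons, _cumulative_starts(model)):
        if plus_pos < off + (e - s):
            return s + (plus_pos - off)
    raise AssertionError("unreachable")


def genome_to_transcript(
    iv: GenomeInterval, model: TranscriptModel
) -> TranscriptInterval | MappingReport:
    """Map a genomic interval into spliced-transcript coordinates.

    Returns a :class:`~txcontext.core.TranscriptInterval` when ``iv`` lies
    entirely within the model's exon union; otherwise a
    :class:`MappingReport` carrying the exonic fraction (and the spliced
    image of the exonic bases, when any). The caller decides how to treat
    partial overlaps — e.g. the >=90% exon-overlap rule of the site layer.
    """
    if iv.chrom != model.chrom:
        raise ValueError(
            f"interval on {iv.chrom} mapped against transcript "
            f"{model.transcript_id} on {model.chrom}"
        )
    exonic = 0
    lo: Optional[int] = None
    hi: Optional[int] = None
    for s, e in model.exons:
        ov_s, ov_e = max(iv.start, s), min(iv.end, e)
        if ov_s < ov_e:
            exonic += ov_e - ov_s
            a = genomic_to_spliced_pos(ov_s, model)
            b = genomic_to_spliced_pos(ov_e - 1, model)
            assert a is not None and b is not None
            lo_e, hi_e = min(a, b), max(a, b) + 1
            lo = lo_e if lo is None else min(lo, lo_e)
            hi = hi_e if hi is None else max(hi, hi_e)
    total = len(iv)
    if exonic == total:
        return TranscriptInterval(
            model.transcript_id, lo, hi, id=iv.id, score=iv.score, pvalue=iv.pvalue
        )
    interval = (
        TranscriptInterval(model.transcript_id, lo, hi, id=iv.id,
                           score=iv.score, pvalue=iv.pvalue)
        if exonic > 0
        else None
    )
    return MappingReport(model.transcript_id, exonic, total, interval)


def transcript_to_genome(
    tiv: TranscriptInterval, model: TranscriptModel
) -> List[GenomeInterval]:
    """Map a spliced interval back to genomic blocks (genomic order).

    The exact inverse of :func:`genome_to_transcript` on exonic bases: an
    interval crossing k splice junctions yields k+1 blocks separated exactly
    by whole introns of the model.
    """
    if tiv.end > model.spliced_length:
        raise ValueError(
            f"transcript {model.transcript_id}: interval end {tiv.end} exceeds "
            f"spliced length {model.spliced_length}"
        )
    # Convert the 5'->3' interval to plus-strand spliced orientation.
    if model.strand == "+":
        plo, phi = tiv.start, tiv.end
    else:
        plo = model.spliced_length - tiv.end
        phi = model.spliced_length - tiv.start
    blocks: List[GenomeInterval] = []
    for (s, e), off in zip(model.exons, _cumulative_starts(model)):
        exon_len = e - s
        ov_lo, ov_hi = max(plo, off), min(phi, off + exon_len)
        if ov_lo < ov_hi:
            blocks.append(
                GenomeInterval(
                    model.chrom,
                    s + (ov_lo - off),
                    s + (ov_hi - off),
                    model.strand,
                    id=tiv.id,
                    score=tiv.score,
                    pvalue=tiv.pvalue,
                )
            )
    return blocks


def spliced_sequence(model: TranscriptModel, genome: Fasta) -> str:
    """Spliced (mRNA, 5'->3') sequence of a transcript from an indexed FASTA.

    Exon substrings are concatenated in genomic order and reverse-complemented
    for minus-strand models; output is uppercased.
    """
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom} not in FASTA")
    chrom_len = len(genome[model.chrom])
    if model.exons[-1][1] > chrom_len:
        raise ValueError(
            f"transcript {model.transcript_id}: exon end {model.exons[-1][1]} "
            f"exceeds chromosome length {chrom_len}"
        )
    seq = "".join(str(genome[model.chrom][s:e]) for s, e in model.exons).upper()
    return reverse_complement(seq) if model.strand == "-" else seq


def assign_to_transcriptome(
    sites: Iterable[GenomeInterval],
    transcriptome: Dict[str, TranscriptModel],
) -> Dict[str, TranscriptModel]:
    """Assign each site to the retained isoform whose exons it overlaps most.

    ``transcriptome`` maps gene_id -> most prominent model. Ties are broken by
    lexicographic transcript id; sites overlapping no exon (on a compatible
    strand) are absent from the result. Returns site id -> model.
    """
    models = sorted(transcriptome.values(), key=lambda m: m.transcript_id)
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    assignment: Dict[str, TranscriptModel] = {}
    for site in sites:
        best: Tuple[int, str] | None = None
        best_model = None
        for m in by_chrom.get(site.chrom, []):
            if not site.strands_compatible(m.strand):
                continue
            ov = sum(
                max(0, min(site.end, e) - max(site.start, s)) for s, e in m.exons
            )
            if ov > 0 and (best is None or (-ov, m.transcript_id) < best):
                best = (-ov, m.transcript_id)
                best_model = m
        if best_model is not None:
            assignment[site.id] = best_model
    return assignment
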