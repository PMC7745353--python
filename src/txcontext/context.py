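"""Centered, fixed-extension sequence context around binding sites.

A site is reduced to its center base, then extended ``ext`` nt up- and
downstream (default 80, i.e. 161 nt total). The genomic context extends in
raw genomic coordinates (reading into introns); the transcript context
extends in spliced coordinates (reading through splice junctions). At
chromosome or transcript ends the window is truncated, never padded, and the
lost lengths are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

from pyfaidx import Fasta

from .core import (
    GenomeInterval,
    TranscriptInterval,
    TranscriptModel,
    reverse_complement,
)
from .coordmap import spliced_sequence


@dataclass
class ContextSequence:
    """A context window around one site center.

    ``sequence`` reads 5'->3' on the site's strand. ``viewpoint`` gives the
    (start, end) offsets of the original site center base within the
    sequence. ``up_truncated``/``dn_truncated`` count bases lost at the 5'
    and 3' window edges to chromosome or transcript ends, so that
    ``len(sequence) == 2*ext + 1 - up_truncated - dn_truncated``.
    """

    site_id: str
    space: str  # "genomic" | "transcript"
    sequence: str
    viewpoint: Tuple[int, int]
    up_truncated: int = 0
    dn_truncated: int = 0

    def fasta_header(self) -> str:
        vs, ve = self.viewpoint
        return (
            f"{self.site_id} space={self.space} vp={vs}-{ve} "
            f"up_trunc={self.up_truncated} dn_trunc={self.dn_truncated}"
        )


Site = Union[GenomeInterval, TranscriptInterval]


def center_site(site: Site) -> Site:
    """Reduce a site to its single center base.

    Odd length keeps the middle base; even length keeps the more 5' (on the
    site's strand) of the two central bases, so reverse-complementing the
    input flips the choice consistently.
    """
    n = len(site)
    if isinstance(site, TranscriptInterval):
        off = (n - 1) // 2  # transcript coordinates are already 5'->3'
        return TranscriptInterval(
            site.transcript_id, site.start + off, site.start + off + 1,
            id=site.id, score=site.score, pvalue=site.pvalue,
        )
    off = n // 2 if site.strand == "-" else (n - 1) // 2
    return GenomeInterval(
        site.chrom, site.start + off, site.start + off + 1,
        site.strand, site.id, site.score, site.pvalue,
    )


def extract_genomic_context(
    site: GenomeInterval, genome: Fasta, ext: int = 80
) -> ContextSequence:
    """Genomic context: ext nt either side of the site center on the genome.

    The window covers [center-ext, center+ext+1) and is truncated only at
    chromosome ends; minus-strand sites yield the reverse complement so the
    sequence reads 5'->3' on the site strand.
    """
    center = center_site(site)
    if center.chrom not in genome:
        raise KeyError(f"chromosome {center.chrom} not in FASTA")
    chrom_len = len(genome[center.chrom])
    c = center.start
    lo, hi = c - ext, c + ext + 1
    clip_lo, clip_hi = max(0, lo), min(chrom_len, hi)
    seq = str(genome[center.chrom][clip_lo:clip_hi]).upper()
    left_lost, right_lost = clip_lo - lo, hi - clip_hi
    if site.strand == "-":
        seq = reverse_complement(seq)
        up, dn = right_lost, left_lost
    else:
        up, dn = left_lost, right_lost
    vp = ext - up
    return ContextSequence(site.id, "genomic", seq, (vp, vp + 1), up, dn)


def extract_transcript_context(
    site: TranscriptInterval,
    model: TranscriptModel,
    genome: Fasta,
    ext: int = 80,
) -> ContextSequence:
    """Transcript context: ext nt either side of the center in spliced
    coordinates, reading through splice junctions; truncated at transcript
    5'/3' ends."""
    if site.transcript_id != model.transcript_id:
        raise ValueError(
            f"site {site.id} is on {site.transcript_id}, not {model.transcript_id}"
        )
    center = center_site(site)
    c = center.start
    if not (0 <= c < model.spliced_length):
        raise ValueError(
            f"site {site.id}: center {c} outside transcript "
            f"{model.transcript_id} (length {model.spliced_length})"
        )
    lo, hi = c - ext, c + ext + 1
    clip_lo, clip_hi = max(0, lo), min(model.spliced_length, hi)
    tx_seq = spliced_sequence(model, genome)
    seq = tx_seq[clip_lo:clip_hi]
    up, dn = clip_lo - lo, hi - clip_hi
    vp = ext - up
    return ContextSequence(site.id, "transcript", seq, (vp, vp + 1), up, dn)


def write_context_fasta(contexts: Sequence[ContextSequence], path: str) -> None:
    """One FASTA record per context; header carries id, space, viewpoint and
    truncation bookkeeping."""
    with open(path, "w") as fh:
        for ctx in contexts:
            fh.write(f">{ctx.fasta_header()}\n{ctx.sequence}\n")


def write_truncation_table(contexts: Sequence[ContextSequence], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tspace\tlength\tup_truncated\tdn_truncated\n")
        for ctx in contexts:
            fh.write(
                f"{ctx.site_id}\t{ctx.space}\t{len(ctx.sequence)}\t"
                f"{ctx.up_truncated}\t{ctx.dn_truncated}\n"
            )
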