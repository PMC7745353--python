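"""Core domain types shared by all modules.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based closed) is converted at the reader boundary in :mod:`txcontext.annotation`.
Transcript (spliced) coordinates always run 5'->3' of the mRNA, i.e. position 0
is the transcript 5' end regardless of genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeInterval:
    """A stranded genomic region with a score (log2 fold change) and optional p-value.

    The unit of peak/site algebra. ``start``/``end`` are 0-based half-open.
    ``score`` carries the peak caller's log2 fold change (LFC); ``pvalue`` is
    optional and, when present, must lie in [0, 1].
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    score: float = 0.0
    pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def strands_compatible(self, strand: str) -> bool:
        """Stranded overlap rule: '.' matches both strands."""
        return self.strand == "." or strand == "." or self.strand == strand


# APPRIS labels in priority order (best first). The ``alternative`` labels rank
# below every ``principal`` label; ``none`` means unannotated.
APPRIS_ORDER = (
    "principal1",
    "principal2",
    "principal3",
    "principal4",
    "principal5",
    "alternative1",
    "alternative2",
)


@dataclass
class TranscriptModel:
    """Ordered exon structure of one isoform plus isoform-selection metadata.

    ``exons`` are genomic (start, end) pairs, 0-based half-open, sorted by
    genomic start, non-overlapping, all on one chromosome/strand. Selection
    metadata mirrors Ensembl transcript-quality annotation: APPRIS principal
    isoform label, transcript support level (TSL) and GENCODE basic membership.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    gene_name: str = ""
    appris: str = "none"
    tsl: Optional[int] = None
    basic: bool = False
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: invalid exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({s}, {e})"
                )
            prev_end = e
        if self.appris not in APPRIS_ORDER and self.appris != "none":
            raise ValueError(f"{self.transcript_id}: unknown APPRIS label {self.appris!r}")
        if self.tsl is not None and self.tsl not in (1, 2, 3, 4, 5):
            raise ValueError(f"{self.transcript_id}: invalid TSL {self.tsl!r}")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class TranscriptInterval:
    """A region in spliced-transcript coordinates (0-based half-open, 5'->3')."""

    transcript_id: str
    start: int
    end: int
    id: str = ""
    score: float = 0.0
    pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid transcript interval {self.transcript_id}:"
                f"{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start
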