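"""GTF annotation reading, most-prominent-isoform selection, exon/intron regions.

The annotation layer turns an Ensembl-dialect GTF into
:class:`~txcontext.core.TranscriptModel` objects, selects one representative
("most prominent") isoform per gene by hierarchical quality filtering
(GENCODE basic membership, then APPRIS label, then transcript support level),
and emits exon/intron regions as stranded BED intervals.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gffutils

from .core import APPRIS_ORDER, GenomeInterval, TranscriptModel

# Ensembl writes APPRIS as tags like "appris_principal_1"; some dialects use
# the bare label. Both are accepted.
_APPRIS_TAG = re.compile(r"^(?:appris_)?(principal|alternative)_?([1-5])$")


def _parse_appris(tags: Iterable[str]) -> str:
    for tag in tags:
        m = _APPRIS_TAG.match(tag)
        if m:
            label = f"{m.group(1)}{m.group(2)}"
            if label in APPRIS_ORDER:
                return label
    return "none"


def _parse_tsl(value: Optional[str]) -> Optional[int]:
    """Leading integer of a TSL attribute; 'NA' (any suffix) means missing."""
    if value is None:
        return None
    m = re.match(r"\s*([1-5])", value)
    return int(m.group(1)) if m else None


def read_gtf(
    path: str,
    chrom_filter: Optional[Set[str]] = None,
) -> List[TranscriptModel]:
    """Read exon features of an Ensembl-dialect GTF into transcript models.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Transcript-level quality tags (APPRIS, TSL, GENCODE basic) are taken from
    the exon lines' attributes; missing tags map to APPRIS ``none``, TSL
    missing and ``basic=False``.

    Parameters
    ----------
    path
        GTF file with ``exon`` features carrying ``transcript_id`` and
        ``gene_id`` attributes.
    chrom_filter
        If given, only transcripts on these chromosomes are returned.

    Raises
    ------
    ValueError
        On a malformed GTF line (naming the line number) or when exons of one
        transcript disagree on chromosome or strand (naming the transcript).
    """
    _validate_gtf_lines(path)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # surface the offending line number if we can
        raise ValueError(_locate_bad_line(path, exc)) from exc

    per_tx: Dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if chrom_filter is not None and feat.seqid not in chrom_filter:
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"exon feature at {feat.seqid}:{feat.start} lacks {exc} attribute"
            ) from None
        rec = per_tx.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "gene_name": _first(feat.attributes, "gene_name", ""),
                "biotype": _first(feat.attributes, "gene_biotype", ""),
                "tags": list(feat.attributes.get("tag", [])),
                "tsl": _first(feat.attributes, "transcript_support_level", None)
                or _first(feat.attributes, "tsl", None),
            },
        )
        if rec["chrom"] != feat.seqid or rec["strand"] != feat.strand:
            raise ValueError(
                f"transcript {tid}: exons on conflicting chrom/strand "
                f"({rec['chrom']}{rec['strand']} vs {feat.seqid}{feat.strand})"
            )
        # GTF is 1-based closed; internal convention is 0-based half-open.
        rec["exons"].append((feat.start - 1, feat.end))

    models = []
    for tid, rec in per_tx.items():
        exons = sorted(rec["exons"])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                gene_name=rec["gene_name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(exons),
                appris=_parse_appris(rec["tags"]),
                tsl=_parse_tsl(rec["tsl"]),
                basic="basic" in rec["tags"],
                biotype=rec["biotype"],
            )
        )
    return models


def _first(attributes, key: str, default):
    vals = attributes.get(key)
    return vals[0] if vals else default


def _validate_gtf_lines(path: str) -> None:
    """Cheap structural validation so parse errors name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from None
            if start > end or start < 1:
                raise ValueError(
                    f"malformed GTF line {lineno}: invalid coordinates {start}-{end}"
                )


def _locate_bad_line(path: str, exc: Exception) -> str:
    return f"failed to parse GTF {path}: {exc}"


def _selection_key(model: TranscriptModel) -> tuple:
    """Sort key implementing the isoform-prominence hierarchy (best sorts first)."""
    return (
        APPRIS_ORDER.index(model.appris),  # principal1 best ... alternative2 worst
        model.tsl,                         # TSL 1 best
        -model.spliced_length,             # longer isoform wins remaining ties
        model.transcript_id,               # final deterministic tie-break
    )


def select_most_prominent(
    models: Iterable[TranscriptModel],
) -> Dict[str, TranscriptModel]:
    """Select one most prominent isoform per gene.

    Only transcripts that are GENCODE-basic AND carry both an APPRIS label and
    a TSL are candidates; genes with no such isoform are absent from the
    output. Among candidates the APPRIS label dominates (principal1 best),
    ties broken by TSL (1 best), then longer spliced length, then
    lexicographic transcript id. The result is invariant to input order.
    """
    per_gene: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        if m.basic and m.appris != "none" and m.tsl is not None:
            per_gene.setdefault(m.gene_id, []).append(m)
    return {
        gene: min(candidates, key=_selection_key)
        for gene, candidates in per_gene.items()
    }


def exon_intron_regions(
    model: TranscriptModel,
) -> Tuple[List[GenomeInterval], List[GenomeInterval]]:
    """Exon and intron regions of a transcript as stranded genomic intervals.

    Interval ids encode the transcript id and the 5'->3' index on the
    transcript strand (``<tid>_e1`` is the 5'-most exon; on the minus strand
    that is the exon with the highest genomic coordinates). Introns are the
    gaps between consecutive exons, numbered the same way.
    """
    n = len(model.exons)
    exon_order = range(n) if model.strand == "+" else range(n - 1, -1, -1)
    exons = []
    for rank, idx in enumerate(exon_order, start=1):
        s, e = model.exons[idx]
        exons.append(
            GenomeInterval(model.chrom, s, e, model.strand,
                           id=f"{model.transcript_id}_e{rank}")
        )
    intron_pairs = model.introns
    k = len(intron_pairs)
    intron_order = range(k) if model.strand == "+" else range(k - 1, -1, -1)
    introns = []
    for rank, idx in enumerate(intron_order, start=1):
        s, e = intron_pairs[idx]
        introns.append(
            GenomeInterval(model.chrom, s, e, model.strand,
                           id=f"{model.transcript_id}_i{rank}")
        )
    return exons, introns


def merged_exon_union(
    models: Iterable[TranscriptModel],
) -> Dict[Tuple[str, str], List[Tuple[int, int]]]:
    """Merged exon intervals per (chrom, strand), sorted; the substrate for
    exon-overlap classification of sites."""
    raw: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for m in models:
        raw.setdefault((m.chrom, m.strand), []).extend(m.exons)
    union: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for key, ivs in raw.items():
        ivs.sort()
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        union[key] = merged
    return union


def write_transcript_list(models: Iterable[TranscriptModel], path: str) -> None:
    """One transcript_id per line (the most-prominent-transcript list format)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(m.transcript_id + "\n")


def write_regions_bed(regions: Sequence[GenomeInterval], path: str) -> None:
    from .sites import write_bed

    write_bed(regions, path)
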