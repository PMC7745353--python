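"""Deterministic synthetic-data generator with machine-readable ground truth.

Builds a toy genome (uniform random bases), a multi-isoform Ensembl-dialect
GTF with APPRIS/TSL/basic labels, BED site sets planted per category
(exonic far from borders, near-border, adjacent-exon-border pairs,
non-exonic, transcript-end) and motif instances written into the genome at
chosen spliced positions — including instances straddling splice junctions,
whose spliced image lands on the two flanking exon ends. Every planted
object is recorded in a truth table so pipeline operations can be tested
closed-loop against construction.

The generator emulates the geometry of peak-called CLIP data (site/exon
arrangements, scores, splice structure) but not read-level signal: no
crosslink profiles, no coverage, and background sequence is i.i.d. uniform
rather than a natural genome composition.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pyfaidx import Faidx

from .core import GenomeInterval, TranscriptModel, reverse_complement
from .motif import IUPAC, Motif, match_at, parse_motif, scan, PUM2_PRE, IGF2BP3_COMPOUND

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_SITE_COUNTS = {
    # 100 sites: 40 exonic of which 20 near-border of which 8 pair members.
    "exonic_far": 20,
    "near_border": 12,
    "pairs": 4,  # pairs, i.e. 8 pair-member sites
    "non_exonic": 60,
}

DEFAULT_MOTIF_PLANTS = (
    ("PUM2_PRE", PUM2_PRE, 3),
    ("IGF2BP3_compound", IGF2BP3_COMPOUND, 2),
)


@dataclass
class SyntheticDataset:
    """In-memory handle on a generated fixture plus its emitted files."""

    outdir: str
    fasta: str
    gtf: str
    sites_bed: str
    end_sites_bed: str
    motif_sites_bed: str
    truth_json: str
    truth: dict
    models: List[TranscriptModel]
    expected_mpt: Dict[str, str]  # gene_id -> transcript_id
    sites: List[GenomeInterval]
    end_sites: List[GenomeInterval]
    motif_sites: List[GenomeInterval]
    chroms: Dict[str, str]

    @property
    def transcriptome(self) -> Dict[str, TranscriptModel]:
        by_id = {m.transcript_id: m for m in self.models}
        return {g: by_id[t] for g, t in self.expected_mpt.items()}


# ---------------------------------------------------------------------------
# independent per-base spliced <-> genomic walkers (used for planting; they
# deliberately do not go through txcontext.coordmap)

def _spliced_len(exons) -> int:
    return sum(e - s for s, e in exons)


def _spliced_to_genomic(t: int, exons, strand: str) -> int:
    total = _spliced_len(exons)
    plus = t if strand == "+" else total - 1 - t
    for s, e in exons:
        if plus < e - s:
            return s + plus
        plus -= e - s
    raise IndexError(t)


def _exon_cum_starts(exons) -> List[int]:
    out, acc = [], 0
    for s, e in exons:
        out.append(acc)
        acc += e - s
    return out


def _junction_spliced_pos(exons, strand: str, junction_idx: int) -> int:
    """Spliced coordinate of the first base after junction ``junction_idx``
    (junction i lies between genomic exons i and i+1), on the transcript
    strand."""
    cum = _exon_cum_starts(exons)
    total = _spliced_len(exons)
    plus_boundary = cum[junction_idx + 1]  # first base of exon i+1, plus-orientation
    if strand == "+":
        return plus_boundary
    return total - plus_boundary


def _instantiate_block(block: str, rng) -> str:
    """A concrete A/C/G/T string matching an IUPAC block."""
    out = []
    for letter in block:
        choices = sorted(IUPAC[letter] - {"N"})
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def make_fixture(
    outdir: str,
    n_genes: int = 16,
    exons_per_gene: Tuple[int, int] = (3, 6),
    exon_len: Tuple[int, int] = (150, 300),
    intron_len: Tuple[int, int] = (80, 200),
    site_counts: Optional[Dict[str, int]] = None,
    end_offsets: Sequence[int] = (5, 20, 50, 79),
    motif_plants: Sequence[Tuple[str, str, int]] = DEFAULT_MOTIF_PLANTS,
    ext: int = 80,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete fixture under ``outdir``.

    Writes genome.fa (+ .fai), annotation.gtf, sites.bed (the planted
    statistics site set), end_sites.bed (single-base sites k nt from
    transcript 5' ends), motif_sites.bed (one centered site per planted
    motif instance) and truth.json. Identical arguments and seed produce
    byte-identical files.

    The last three genes are isoform-selection scenarios (an APPRIS-dominates
    case, a TSL tie-break case, and a gene lacking labels that must be
    excluded); sites and motifs are planted only in the remaining genes.
    Junction-split motif instances are planted with minimal gap lengths so
    the scanner's minimal-total-gap match reproduces the planted span
    exactly, and any chance occurrence of a planted motif inside the genomic
    context window of a split instance is mutated away so genomic-context
    scans of those windows are clean by construction.
    """
    if n_genes < 6:
        raise ValueError("need at least 6 genes (3 are selection scenarios)")
    counts = dict(DEFAULT_SITE_COUNTS, **(site_counts or {}))
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)

    # ---- gene structures -------------------------------------------------
    genes: List[dict] = []
    chrom_cursor = {"chrA": 300, "chrB": 300}
    for g in range(n_genes):
        chrom = "chrA" if g % 2 == 0 else "chrB"
        strand = "+" if g % 3 != 1 else "-"  # ~1/3 minus-strand genes
        n_ex = 1 if g == 0 else int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        pos = chrom_cursor[chrom]
        exons = []
        for i in range(n_ex):
            elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_ex - 1:
                pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
        chrom_cursor[chrom] = pos + 300  # intergenic gap
        genes.append(
            {
                "gene_id": f"g{g + 1}",
                "tid": f"t{g + 1}",
                "chrom": chrom,
                "strand": strand,
                "exons": exons,
            }
        )
    chrom_len = {c: cur + 200 for c, cur in chrom_cursor.items()}

    # ---- isoform labels and selection scenarios --------------------------
    transcripts: List[dict] = []  # GTF rows
    expected_mpt: Dict[str, str] = {}
    plantable = genes[:-3]
    g_appris, g_tsl, g_nolabel = genes[-3], genes[-2], genes[-1]
    for gene in plantable:
        transcripts.append(
            dict(gene, appris="principal1", tsl=1, basic=True)
        )
        expected_mpt[gene["gene_id"]] = gene["tid"]
    # APPRIS dominates TSL: principal1/TSL2 beats principal2/TSL1.
    transcripts.append(dict(g_appris, appris="principal1", tsl=2, basic=True))
    transcripts.append(
        dict(g_appris, tid=g_appris["tid"] + "d", exons=g_appris["exons"][:2],
             appris="principal2", tsl=1, basic=True)
    )
    expected_mpt[g_appris["gene_id"]] = g_appris["tid"]
    # Equal APPRIS: TSL 1 beats TSL 2 (shorter isoform wins here).
    transcripts.append(dict(g_tsl, appris="principal1", tsl=2, basic=True))
    transcripts.append(
        dict(g_tsl, tid=g_tsl["tid"] + "d", exons=g_tsl["exons"][:2],
             appris="principal1", tsl=1, basic=True)
    )
    expected_mpt[g_tsl["gene_id"]] = g_tsl["tid"] + "d"
    # No TSL label: the gene must be excluded from the prominent set.
    transcripts.append(dict(g_nolabel, appris="principal1", tsl=None, basic=True))

    # ---- slot allocation for planted sites -------------------------------
    multi = [g for g in plantable if len(g["exons"]) >= 2]
    junctions = [(g, j) for g in multi for j in range(len(g["exons"]) - 1)]
    order = rng.permutation(len(junctions))
    junctions = [junctions[i] for i in order]
    n_pairs = counts["pairs"]
    n_motifs = sum(n for _, _, n in motif_plants)
    if len(junctions) < n_pairs + n_motifs:
        raise ValueError("not enough splice junctions for requested pairs/motifs")
    pair_junctions = junctions[:n_pairs]
    motif_junctions = junctions[n_pairs : n_pairs + n_motifs]

    pair_exons = {
        (g["gene_id"], e) for g, j in pair_junctions for e in (j, j + 1)
    }
    exon_slots = [
        (g, i)
        for g in plantable
        for i in range(len(g["exons"]))
        if (g["gene_id"], i) not in pair_exons
    ]
    order = rng.permutation(len(exon_slots))
    exon_slots = [exon_slots[i] for i in order]
    if len(exon_slots) < counts["near_border"] + counts["exonic_far"]:
        raise ValueError("not enough exons for requested site categories")
    near_slots = exon_slots[: counts["near_border"]]
    far_slots = exon_slots[
        counts["near_border"] : counts["near_border"] + counts["exonic_far"]
    ]

    sites: List[GenomeInterval] = []
    truth_sites: List[dict] = []
    site_no = 0

    def add_site(chrom, start, end, strand, category, gene_id, score=None, extra=None):
        nonlocal site_no
        site_no += 1
        sid = f"site_{site_no}"
        lfc = float(score) if score is not None else round(float(rng.uniform(1.0, 5.0)), 2)
        pv = round(float(rng.uniform(0.0, 0.009)), 6)
        iv = GenomeInterval(chrom, int(start), int(end), strand, sid, lfc, pv)
        sites.append(iv)
        rec = {
            "id": sid, "chrom": chrom, "start": int(start), "end": int(end),
            "strand": strand, "score": lfc, "pvalue": pv,
            "category": category, "gene_id": gene_id,
        }
        if extra:
            rec.update(extra)
        truth_sites.append(rec)
        return iv

    # exonic, far from borders (min end distance > 50)
    for g, i in far_slots:
        es, ee = g["exons"][i]
        sl = int(rng.integers(15, 41))
        lo, hi = es + 51, ee - 51 - sl
        start = int(rng.integers(lo, hi + 1))
        add_site(g["chrom"], start, start + sl, g["strand"], "exonic_far",
                 g["gene_id"], extra={"exon_genomic_index": i})

    # exonic near-border, non-pair (min end distance in [10, 50])
    for g, i in near_slots:
        es, ee = g["exons"][i]
        sl = int(rng.integers(15, 41))
        d = int(rng.integers(10, 51))
        side = "start" if rng.integers(2) == 0 else "end"
        if side == "start":
            start = es + d
        else:
            start = ee - d - sl
        add_site(g["chrom"], start, start + sl, g["strand"], "near_border",
                 g["gene_id"], extra={"exon_genomic_index": i, "border_dist": d})

    # pair sites at adjacent exon borders (both inner ends < 10 nt away)
    truth_pairs: List[Tuple[str, str]] = []
    for g, j in pair_junctions:
        es1, ee1 = g["exons"][j]
        es2, ee2 = g["exons"][j + 1]
        sl1, sl2 = int(rng.integers(15, 41)), int(rng.integers(15, 41))
        d1, d2 = int(rng.integers(0, 10)), int(rng.integers(0, 10))
        s1 = add_site(g["chrom"], ee1 - d1 - sl1, ee1 - d1, g["strand"],
                      "pair_member", g["gene_id"],
                      score=round(float(rng.uniform(2.0, 5.0)), 2),
                      extra={"junction_genomic_index": j, "border_dist": d1})
        s2 = add_site(g["chrom"], es2 + d2, es2 + d2 + sl2, g["strand"],
                      "pair_member", g["gene_id"],
                      score=round(float(rng.uniform(2.0, 5.0)), 2),
                      extra={"junction_genomic_index": j, "border_dist": d2})
        truth_pairs.append([s1.id, s2.id])

    # non-exonic sites: intronic (and every sixth intergenic)
    introns = [
        (g, (g["exons"][i][1], g["exons"][i + 1][0]))
        for g in plantable
        for i in range(len(g["exons"]) - 1)
    ]
    for k in range(counts["non_exonic"]):
        sl = int(rng.integers(15, 41))
        if k % 6 == 5:
            chrom = "chrA" if k % 2 == 0 else "chrB"
            start = int(rng.integers(50, 250 - sl))  # upstream pad, intergenic
            add_site(chrom, start, start + sl,
                     "+" if rng.integers(2) == 0 else "-",
                     "non_exonic", "", extra={"placement": "intergenic"})
        else:
            g, (is_, ie) = introns[int(rng.integers(len(introns)))]
            start = int(rng.integers(is_ + 2, ie - sl - 2))
            add_site(g["chrom"], start, start + sl, g["strand"], "non_exonic",
                     g["gene_id"], extra={"placement": "intronic"})

    # transcript-end sites: one single-base site k nt from a transcript 5' end
    end_sites: List[GenomeInterval] = []
    truth_end: List[dict] = []
    for n, k in enumerate(end_offsets, start=1):
        g = multi[n % len(multi)]
        gpos = _spliced_to_genomic(int(k), g["exons"], g["strand"])
        iv = GenomeInterval(g["chrom"], gpos, gpos + 1, g["strand"], f"end_{n}",
                            round(float(rng.uniform(1.0, 5.0)), 2))
        end_sites.append(iv)
        truth_end.append(
            {"id": iv.id, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "strand": iv.strand, "transcript_id": g["tid"],
             "offset_from_5p": int(k)}
        )

    # ---- genome sequence and motif planting ------------------------------
    arrays = {
        c: rng.choice(np.array(list("ACGT")), size=n)
        for c, n in sorted(chrom_len.items())
    }

    def write_spliced_base(g: dict, t: int, base: str) -> int:
        gpos = _spliced_to_genomic(t, g["exons"], g["strand"])
        arrays[g["chrom"]][gpos] = base if g["strand"] == "+" else _COMP[base]
        return gpos

    motif_defs: Dict[str, Motif] = {}
    motif_sites: List[GenomeInterval] = []
    truth_motifs: List[dict] = []
    protected: set = set()  # (chrom, genomic position) of planted block bases
    mi_no = 0
    jidx = 0
    for motif_id, spec, n_inst in motif_plants:
        motif = parse_motif(spec, motif_id)
        motif_defs[motif_id] = motif
        min_len = motif.min_length
        if min_len > 2 * ext + 1:
            raise ValueError(f"motif {motif_id} longer than the context window")
        for _ in range(n_inst):
            g, j = motif_junctions[jidx]
            jidx += 1
            spliced_total = _spliced_len(g["exons"])
            J = _junction_spliced_pos(g["exons"], g["strand"],
                                      j if g["strand"] == "+" else j)
            # split offset: at least 1 planted base on each side of the junction
            split = int(rng.integers(1, min_len))
            t_start = J - split
            if t_start < 0 or t_start + min_len > spliced_total:
                # junction too close to a transcript end for this motif; recenter
                t_start = max(0, min(J - 1, spliced_total - min_len))
            t_end = t_start + min_len
            # write blocks with minimal gaps; record their genomic bases
            blocks_t: List[Tuple[int, str]] = []
            off = t_start
            for elem in motif.elements:
                off += elem.gap_min
                concrete = _instantiate_block(elem.block, rng)
                blocks_t.append((off, concrete))
                off += len(elem.block)
            block_genomic: List[List[int]] = []
            for bstart, concrete in blocks_t:
                gps = []
                for i, base in enumerate(concrete):
                    gps.append(write_spliced_base(g, bstart + i, base))
                block_genomic.append(gps)
                protected.update((g["chrom"], p) for p in gps)
            # associated single-base site at the spliced center of the instance
            mi_no += 1
            t_center = t_start + (min_len - 1) // 2
            g_center = _spliced_to_genomic(t_center, g["exons"], g["strand"])
            site = GenomeInterval(g["chrom"], g_center, g_center + 1,
                                  g["strand"], f"mi_{mi_no}", 1.0)
            motif_sites.append(site)
            truth_motifs.append(
                {
                    "id": site.id, "motif_id": motif_id, "spec": spec,
                    "transcript_id": g["tid"], "gene_id": g["gene_id"],
                    "t_start": int(t_start), "t_end": int(t_end),
                    "junction_spliced_pos": int(J), "split": True,
                    "chrom": g["chrom"], "strand": g["strand"],
                    "center_genomic": int(g_center),
                    "center_spliced": int(t_center),
                }
            )

    # ---- scrub chance motif matches from genomic windows of split sites ---
    genes_by_tid = {t["tid"]: t for t in transcripts}

    def genomic_window(rec: dict) -> Tuple[str, int, int]:
        c = rec["center_genomic"]
        return rec["chrom"], max(0, c - ext), min(chrom_len[rec["chrom"]], c + ext + 1)

    def oriented_seq(chrom: str, lo: int, hi: int, strand: str) -> str:
        s = "".join(arrays[chrom][lo:hi].tolist())
        return reverse_complement(s) if strand == "-" else s

    for _ in range(200):
        dirty = False
        for rec in truth_motifs:
            motif = motif_defs[rec["motif_id"]]
            chrom, lo, hi = genomic_window(rec)
            seq = oriented_seq(chrom, lo, hi, rec["strand"])
            for hit in scan(seq, motif):
                placements = match_at(seq, hit.start, motif)
                mutated = False
                for bstart, block in placements:
                    for i, letter in enumerate(block):
                        if letter == "N":
                            continue
                        p = bstart + i
                        gpos = lo + p if rec["strand"] == "+" else hi - 1 - p
                        if (chrom, gpos) in protected:
                            continue
                        cur = seq[p]
                        repl = next(b for b in "ACGT" if b not in IUPAC[letter])
                        arrays[chrom][gpos] = repl if rec["strand"] == "+" else _COMP[repl]
                        mutated = True
                        break
                    if mutated:
                        break
                if not mutated:
                    raise RuntimeError(
                        "cannot scrub a chance genomic motif match without "
                        "touching planted bases"
                    )
                dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("genomic-window scrubbing did not converge")

    chroms = {c: "".join(a.tolist()) for c, a in arrays.items()}

    # ---- emit files -------------------------------------------------------
    fasta = os.path.join(outdir, "genome.fa")
    with open(fasta, "w") as fh:
        for c in sorted(chroms):
            fh.write(f">{c}\n")
            s = chroms[c]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    Faidx(fasta)

    gtf = os.path.join(outdir, "annotation.gtf")
    _write_gtf(transcripts, gtf)

    from .sites import write_bed

    sites_bed = os.path.join(outdir, "sites.bed")
    write_bed(sites, sites_bed)
    end_bed = os.path.join(outdir, "end_sites.bed")
    write_bed(end_sites, end_bed)
    motif_bed = os.path.join(outdir, "motif_sites.bed")
    write_bed(motif_sites, motif_bed)

    n_exonic = counts["exonic_far"] + counts["near_border"] + 2 * counts["pairs"]
    truth = {
        "seed": int(seed),
        "params": {
            "n_genes": n_genes, "exons_per_gene": list(exons_per_gene),
            "exon_len": list(exon_len), "intron_len": list(intron_len),
            "site_counts": counts, "end_offsets": list(end_offsets),
            "ext": ext,
        },
        "transcripts": {
            t["tid"]: {
                "gene_id": t["gene_id"], "chrom": t["chrom"],
                "strand": t["strand"],
                "exons": [list(e) for e in t["exons"]],
                "appris": t.get("appris", "none"),
                "tsl": t.get("tsl"), "basic": t.get("basic", False),
            }
            for t in transcripts
        },
        "expected_mpt": expected_mpt,
        "excluded_genes": [g_nolabel["gene_id"]],
        "sites": truth_sites,
        "pairs": truth_pairs,
        "end_sites": truth_end,
        "motif_instances": truth_motifs,
        "motifs": {mid: spec for mid, spec, _ in motif_plants},
        "expected_stats": {
            "n_sites": len(sites),
            "n_exonic": n_exonic,
            "n_near_border": counts["near_border"] + 2 * counts["pairs"],
            "n_pair_sites": 2 * counts["pairs"],
        },
    }
    truth_json = os.path.join(outdir, "truth.json")
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    models = [
        TranscriptModel(
            transcript_id=t["tid"], gene_id=t["gene_id"], chrom=t["chrom"],
            strand=t["strand"], exons=tuple(t["exons"]),
            appris=t.get("appris", "none"), tsl=t.get("tsl"),
            basic=t.get("basic", False),
        )
        for t in transcripts
    ]
    return SyntheticDataset(
        outdir=outdir, fasta=fasta, gtf=gtf, sites_bed=sites_bed,
        end_sites_bed=end_bed, motif_sites_bed=motif_bed,
        truth_json=truth_json, truth=truth, models=models,
        expected_mpt=expected_mpt, sites=sites, end_sites=end_sites,
        motif_sites=motif_sites, chroms=chroms,
    )


def _write_gtf(transcripts: Sequence[dict], path: str) -> None:
    """Ensembl-dialect GTF: transcript + exon rows, tags on every row."""
    rows = []
    for t in transcripts:
        attrs = (
            f'gene_id "{t["gene_id"]}"; transcript_id "{t["tid"]}"; '
            f'gene_name "{t["gene_id"].upper()}"; gene_biotype "protein_coding"; '
        )
        tsl = t.get("tsl")
        attrs += f'transcript_support_level "{tsl if tsl is not None else "NA"}"; '
        if t.get("basic", False):
            attrs += 'tag "basic"; '
        appris = t.get("appris", "none")
        if appris != "none":
            label = appris.replace("principal", "principal_").replace(
                "alternative", "alternative_"
            )
            attrs += f'tag "appris_{label}"; '
        span_s = t["exons"][0][0] + 1
        span_e = t["exons"][-1][1]
        rows.append(
            (t["chrom"], span_s,
             f'{t["chrom"]}\ttxcontext\ttranscript\t{span_s}\t{span_e}\t.\t'
             f'{t["strand"]}\t.\t{attrs.strip()}')
        )
        n = len(t["exons"])
        for i, (s, e) in enumerate(t["exons"]):
            number = i + 1 if t["strand"] == "+" else n - i
            ex_attrs = attrs + f'exon_number "{number}"; '
            rows.append(
                (t["chrom"], s + 1,
                 f'{t["chrom"]}\ttxcontext\texon\t{s + 1}\t{e}\t.\t'
                 f'{t["strand"]}\t.\t{ex_attrs.strip()}')
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for _, _, line in rows:
            fh.write(line + "\n")
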