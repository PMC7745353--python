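"""BED site algebra: I/O, filtering, merging, exon-overlap classification,
exon-border distances and adjacent-exon pair-site detection.

Peak callers operating on genomic read profiles split binding sites that span
splice junctions into two peaks, one at each adjacent exon end. The
operations here quantify that signature: which sites are exonic (>=90% exon
overlap by default), how close their ends lie to exon borders, and which
exonic sites form pairs at adjacent borders of consecutive exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import GenomeInterval, TranscriptModel


@dataclass
class Thresholds:
    """All numeric parameters of the site-processing pipeline.

    Defaults follow the published processing choices: sites count as exonic
    at >=90% exon overlap; "near border" means a site end within <=50 nt of
    an exon border; pair sites require <10 nt (strict) from both inner site
    ends to the adjacent exon borders; nearby sites closer than 10 nt are
    merged; context extension is 80 nt each side (161 nt total). The context
    construction preset additionally filters by length <=80, LFC >=3 and
    p-value <=0.01.
    """

    min_lfc: Optional[float] = 1.0
    max_len: Optional[int] = None
    max_pvalue: Optional[float] = None
    exon_overlap_frac: float = 0.90
    border_dist: int = 50
    pair_dist: int = 10
    merge_dist: int = 10
    ext: int = 80

    def __post_init__(self) -> None:
        if not (0 < self.exon_overlap_frac <= 1):
            raise ValueError("exon_overlap_frac must be in (0, 1]")
        for name in ("border_dist", "pair_dist", "merge_dist", "ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def context_preset(cls) -> "Thresholds":
        """Filter settings used when building classifier context sets."""
        return cls(min_lfc=3.0, max_len=80, max_pvalue=0.01)


def read_bed(
    path: str,
    score_col: int = 4,
    pvalue_col: Optional[int] = None,
) -> List[GenomeInterval]:
    """Read a BED6(+) file of sites.

    ``score_col``/``pvalue_col`` are 0-based column indices; the score column
    carries the log2 fold change. Sites without a name get a unique generated
    id. Raises ValueError naming the line number for non-integer coordinates
    or start >= end.
    """
    sites: List[GenomeInterval] = []
    seen_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 and f[3] not in ("", ".") else f"site_{lineno}"
            if name in seen_ids:
                name = f"{name}_{lineno}"
            seen_ids.add(name)
            strand = f[5] if len(f) > 5 else "."
            score = float(f[score_col]) if len(f) > score_col else 0.0
            pvalue = None
            if pvalue_col is not None and len(f) > pvalue_col:
                raw = f[pvalue_col]
                pvalue = None if raw in ("NA", ".", "") else float(raw)
            sites.append(
                GenomeInterval(f[0], start, end, strand, name, score, pvalue)
            )
    return sites


def write_bed(sites: Sequence[GenomeInterval], path: str) -> None:
    """Write sites as BED6 (+ p-value column when any site carries one)."""
    with_p = any(s.pvalue is not None for s in sites)
    with open(path, "w") as fh:
        for s in sites:
            row = [s.chrom, str(s.start), str(s.end), s.id or ".",
                   _fmt_score(s.score), s.strand]
            if with_p:
                row.append("NA" if s.pvalue is None else repr(s.pvalue))
            fh.write("\t".join(row) + "\n")


def _fmt_score(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def filter_sites(sites: Iterable[GenomeInterval], thr: Thresholds) -> List[GenomeInterval]:
    """Keep sites passing length / LFC / p-value bounds (all inclusive).

    Each criterion is disabled when the corresponding threshold is None; the
    p-value bound only applies to sites that carry a p-value.
    """
    out = []
    for s in sites:
        if thr.max_len is not None and len(s) > thr.max_len:
            continue
        if thr.min_lfc is not None and s.score < thr.min_lfc:
            continue
        if (
            thr.max_pvalue is not None
            and s.pvalue is not None
            and s.pvalue > thr.max_pvalue
        ):
            continue
        out.append(s)
    return out


def _component_merge(
    sites: Sequence[GenomeInterval], link_dist: int
) -> List[GenomeInterval]:
    """Single-winner merge: in every connected component of same-strand sites
    whose gap is < link_dist (overlap = gap < 0 <= any link_dist), only the
    highest-LFC site survives with its original coordinates. Ties go to the
    longer site, then the lower start, then lexicographic id."""
    groups: Dict[Tuple[str, str], List[GenomeInterval]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    out: List[GenomeInterval] = []
    for group in groups.values():
        group.sort(key=lambda s: (s.start, s.end, s.id))
        component: List[GenomeInterval] = []
        comp_end = None
        for s in group:
            if comp_end is not None and s.start - comp_end < link_dist:
                component.append(s)
                comp_end = max(comp_end, s.end)
            else:
                if component:
                    out.append(_component_winner(component))
                component = [s]
                comp_end = s.end
        if component:
            out.append(_component_winner(component))
    out.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand))
    return out


def _component_winner(component: Sequence[GenomeInterval]) -> GenomeInterval:
    return max(component, key=lambda s: (s.score, len(s), -s.start, s.id))


def merge_replicates(
    a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]
) -> List[GenomeInterval]:
    """Merge two replicate site sets by keeping, per connected component of
    (transitively) overlapping same-strand sites, only the site with the
    highest log2 fold change. Non-overlapping sites pass through unchanged."""
    return _component_merge(list(a) + list(b), link_dist=0)


def merge_nearby(
    sites: Sequence[GenomeInterval], merge_dist: int = 10
) -> List[GenomeInterval]:
    """Merge nearby sites: sites that overlap or whose end-to-start gap is
    strictly below ``merge_dist`` form components; the highest-LFC site per
    component survives with its original coordinates."""
    return _component_merge(list(sites), link_dist=merge_dist)


def classify_exonic(
    sites: Sequence[GenomeInterval],
    exon_union: Dict[Tuple[str, str], List[Tuple[int, int]]],
    frac: float = 0.90,
) -> List[Tuple[bool, float]]:
    """Per-site exon-overlap classification against a merged exon union.

    ``exon_union`` maps (chrom, strand) to sorted merged exon intervals (see
    :func:`txcontext.annotation.merged_exon_union`); overlap fraction uses the
    site length as denominator (intersect fraction-of-A semantics). A site on
    strand '.' counts exons of both strands. Returns (is_exonic, fraction)
    per site, exonic iff fraction >= frac.
    """
    results = []
    for s in sites:
        strands = ("+", "-") if s.strand == "." else (s.strand,)
        covered: List[Tuple[int, int]] = []
        for strand in strands:
            for es, ee in exon_union.get((s.chrom, strand), []):
                ov_s, ov_e = max(s.start, es), min(s.end, ee)
                if ov_s < ov_e:
                    covered.append((ov_s, ov_e))
        covered.sort()
        exonic_bases = 0
        cur_e = None
        for ov_s, ov_e in covered:  # re-merge: '.' sites may double-count strands
            if cur_e is not None and ov_s < cur_e:
                ov_s = cur_e
            if ov_s < ov_e:
                exonic_bases += ov_e - ov_s
                cur_e = ov_e if cur_e is None else max(cur_e, ov_e)
        fraction = exonic_bases / len(s)
        results.append((fraction >= frac, fraction))
    return results


@dataclass
class BorderDistances:
    """Distances of a site's ends to the borders of their containing exons.

    ``dist_five``/``dist_three`` are the distances of the site's 5' and 3'
    ends (on the site's transcript strand) to the corresponding exon borders;
    0 means flush. Exon indices are 5'->3' on the transcript strand (1-based).
    """

    dist_five: int
    dist_three: int
    exon_index_five: int
    exon_index_three: int

    @property
    def min_dist(self) -> int:
        return min(self.dist_five, self.dist_three)

    def near_border(self, d: int) -> bool:
        """Near-border at threshold d iff the minimum end distance is <= d."""
        return self.min_dist <= d


def _containing_exon(pos: int, model: TranscriptModel) -> int:
    """Genomic-order index of the exon containing genomic base ``pos``."""
    for i, (s, e) in enumerate(model.exons):
        if s <= pos < e:
            return i
    raise ValueError(
        f"position {pos} lies in an intron / outside transcript "
        f"{model.transcript_id}; sites must be pre-classified as exonic"
    )


def border_distance(site: GenomeInterval, model: TranscriptModel) -> BorderDistances:
    """Distances of both site ends to the borders of their containing exons.

    Requires both site ends to fall inside exons of ``model`` (raise
    otherwise). A site spanning a junction may have its two ends in different
    exons; each end is measured against its own exon's border.
    """
    i_left = _containing_exon(site.start, model)
    i_right = _containing_exon(site.end - 1, model)
    dist_left = site.start - model.exons[i_left][0]
    dist_right = model.exons[i_right][1] - site.end
    n = len(model.exons)
    if model.strand == "+":
        return BorderDistances(dist_left, dist_right, i_left + 1, i_right + 1)
    return BorderDistances(dist_right, dist_left, n - i_right, n - i_left)


def detect_pairs(
    sites: Sequence[GenomeInterval],
    assignment: Dict[str, TranscriptModel],
    pair_dist: int = 10,
) -> List[Tuple[str, str]]:
    """Detect pair sites: two sites at adjacent exon borders of one model.

    (s1, s2) is a pair iff s1's inner end lies strictly within ``pair_dist``
    nt of the 3' border of exon i (genomic order) and s2's inner end strictly
    within ``pair_dist`` nt of the 5' border of exon i+1 of the same
    transcript model. Each site joins at most one pair: junctions are
    processed in order and the highest-LFC candidate on each side wins.
    Returns (upstream-exon site id, downstream-exon site id) pairs in genomic
    orientation.
    """
    by_model: Dict[str, List[GenomeInterval]] = {}
    models: Dict[str, TranscriptModel] = {}
    for s in sites:
        m = assignment.get(s.id)
        if m is None:
            continue
        by_model.setdefault(m.transcript_id, []).append(s)
        models[m.transcript_id] = m

    pairs: List[Tuple[str, str]] = []
    for tid in sorted(by_model):
        m = models[tid]
        used: set = set()
        for i in range(len(m.exons) - 1):
            junction_end = m.exons[i][1]      # 3' border of exon i (genomic)
            junction_start = m.exons[i + 1][0]  # 5' border of exon i+1
            left = [
                s
                for s in by_model[tid]
                if s.id not in used
                and s.end <= junction_end
                and s.end > m.exons[i][0]
                and junction_end - s.end < pair_dist
            ]
            right = [
                s
                for s in by_model[tid]
                if s.id not in used
                and s.start >= junction_start
                and s.start < m.exons[i + 1][1]
                and s.start - junction_start < pair_dist
            ]
            if left and right:
                s1 = max(left, key=lambda s: (s.score, -s.start, s.id))
                s2 = max(right, key=lambda s: (s.score, -s.start, s.id))
                pairs.append((s1.id, s2.id))
                used.update((s1.id, s2.id))
    return pairs
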