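"""Dataset-level binding-site statistics.

For a merged, filtered site set and a transcriptome of retained isoforms:
how many sites are exonic (>=90% exon overlap), how many exonic sites lie
near exon borders, how many form adjacent-exon-border pairs, and how their
scores compare. Near-border and pair ratios use the number of EXONIC sites
as denominator. Also provides the exonic-ratio histogram binning and the
cross-cell-line ratio correlation used for multi-dataset summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .annotation import merged_exon_union
from .core import GenomeInterval, TranscriptModel
from .coordmap import assign_to_transcriptome
from .sites import Thresholds, border_distance, classify_exonic, detect_pairs


@dataclass
class DatasetStats:
    n_sites: int
    n_exonic: int
    n_near_border: int
    n_pair_sites: int
    mean_score_exonic: Optional[float]
    mean_score_pairs: Optional[float]
    exonic_site_ids: List[str]
    near_border_site_ids: List[str]
    pairs: List[Tuple[str, str]]

    @property
    def exonic_ratio(self) -> float:
        return self.n_exonic / self.n_sites if self.n_sites else 0.0

    @property
    def near_border_ratio(self) -> Optional[float]:
        """Fraction of exonic sites near a border; None when no exonic sites."""
        return self.n_near_border / self.n_exonic if self.n_exonic else None

    @property
    def pair_ratio(self) -> Optional[float]:
        """Fraction of exonic sites that are pair members; None when no exonic sites."""
        return self.n_pair_sites / self.n_exonic if self.n_exonic else None


def dataset_stats(
    sites: Sequence[GenomeInterval],
    transcriptome: Dict[str, TranscriptModel],
    thr: Thresholds = Thresholds(),
) -> DatasetStats:
    """Compose exon classification, border distances and pair detection.

    ``sites`` are assumed already replicate-merged and filtered;
    ``transcriptome`` maps gene -> most prominent isoform. A site is
    near-border when the minimum distance of its ends to the containing-exon
    borders is <= ``thr.border_dist``; pairs use the strict < ``thr.pair_dist``
    rule on both inner ends.
    """
    union = merged_exon_union(transcriptome.values())
    flags = classify_exonic(sites, union, thr.exon_overlap_frac)
    exonic = [s for s, (is_ex, _) in zip(sites, flags) if is_ex]
    assignment = assign_to_transcriptome(exonic, transcriptome)

    near: List[str] = []
    for s in exonic:
        m = assignment.get(s.id)
        if m is None:
            continue
        try:
            bd = border_distance(s, m)
        except ValueError:
            continue  # an end outside the assigned model's exons
        if bd.near_border(thr.border_dist):
            near.append(s.id)

    pairs = detect_pairs(exonic, assignment, thr.pair_dist)
    pair_ids = {sid for pair in pairs for sid in pair}
    scores = {s.id: s.score for s in exonic}
    return DatasetStats(
        n_sites=len(sites),
        n_exonic=len(exonic),
        n_near_border=len(near),
        n_pair_sites=len(pair_ids),
        mean_score_exonic=float(np.mean([s.score for s in exonic])) if exonic else None,
        mean_score_pairs=float(np.mean([scores[i] for i in pair_ids])) if pair_ids else None,
        exonic_site_ids=[s.id for s in exonic],
        near_border_site_ids=near,
        pairs=pairs,
    )


#: Quartile percentage bins with a right-closed top bin:
#: [0,25), [25,50), [50,75), [75,100].
DEFAULT_BIN_EDGES = (0.0, 25.0, 50.0, 75.0, 100.0)


def ratio_binning(
    ratios: Sequence[float],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> List[Tuple[Tuple[float, float], int, float]]:
    """Histogram of exonic-site percentage ratios over percentage ranges.

    ``ratios`` are fractions in [0, 1]; bins are left-closed with a
    right-closed top bin. Returns (bin edges, count, percentage of datasets)
    per bin.
    """
    pct = np.asarray(ratios, dtype=float) * 100.0
    counts, _ = np.histogram(pct, bins=np.asarray(edges))  # numpy: top bin closed
    total = len(pct)
    return [
        ((edges[i], edges[i + 1]), int(c), 100.0 * c / total if total else 0.0)
        for i, c in enumerate(counts)
    ]


def exon_ratio_correlation(
    pairs: Sequence[Tuple[float, float]]
) -> Optional[float]:
    """Squared Pearson correlation of exonic-site ratios between two cell lines.

    Returns None (undefined) when either vector has zero variance.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two ratio pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = sps.pearsonr(a, b).statistic
    return float(r * r)


def write_stats_tsv(stats: DatasetStats, path: str, dataset_id: str = "dataset") -> None:
    with open(path, "w") as fh:
        fh.write(
            "dataset\tn_sites\tn_exonic\texonic_ratio\tn_near_border\t"
            "near_border_ratio\tn_pair_sites\tpair_ratio\t"
            "mean_score_exonic\tmean_score_pairs\n"
        )
        fmt = lambda x: "NA" if x is None else f"{x:.6g}"
        fh.write(
            f"{dataset_id}\t{stats.n_sites}\t{stats.n_exonic}\t"
            f"{fmt(stats.exonic_ratio)}\t{stats.n_near_border}\t"
            f"{fmt(stats.near_border_ratio)}\t{stats.n_pair_sites}\t"
            f"{fmt(stats.pair_ratio)}\t{fmt(stats.mean_score_exonic)}\t"
            f"{fmt(stats.mean_score_pairs)}\n"
        )
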