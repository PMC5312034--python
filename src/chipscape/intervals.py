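"""Interval algebra: exact and gap-tolerant overlap, nearest-TSS queries,
TSS-proximal/distal classification, and cross-condition peak-set comparison.

Distances follow the nearest-bp convention: the distance from a peak to a
TSS point is 0 when the TSS falls inside (or on the last base of) the peak,
otherwise the distance from the closer peak edge. "Within 1 kb of a TSS" is
inclusive (distance <= 1000) and strand-ignored.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, PeakSet, TSSRecord

INF = math.inf


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff the two intervals share at least ``min_overlap`` bp.

    Half-open convention: [0,100) and [100,200) are adjacent, not
    overlapping. Different chromosomes never overlap. Symmetric.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


def gap_overlap(a: GenomicInterval, b: GenomicInterval, max_gap: int = 0) -> bool:
    """True iff the intervals overlap by >= 1 bp or are separated by a gap
    of at most ``max_gap`` bp. Symmetric; max_gap=0 reduces to overlaps."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if a.chrom != b.chrom:
        return False
    # overlap length when positive; -(gap) when disjoint
    span = min(a.end, b.end) - max(a.start, b.start)
    return span >= 1 or -span <= max_gap


def intersect_sets(
    a: PeakSet,
    b: PeakSet,
    min_overlap: int = 1,
    max_gap: int = 0,
) -> list[tuple[int, int]]:
    """All index pairs (i, j) with a[i] and b[j] co-located.

    When ``max_gap`` > 0 the criterion is gap_overlap; when ``max_gap`` = 0
    the pair must additionally share >= ``min_overlap`` bp. Indices refer to
    the sorted order of each PeakSet. Uses a per-chromosome interval tree
    over B with exact post-filtering.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        # widen the query so candidates at exactly max_gap are returned
        hits = tree.overlap(iv.start - max_gap - 1, iv.end + max_gap + 1)
        for hit in hits:
            j = hit.data
            other = b[j]
            if max_gap > 0:
                if gap_overlap(iv, other, max_gap):
                    pairs.append((i, j))
            elif overlaps(iv, other, min_overlap):
                pairs.append((i, j))
    pairs.sort()
    return pairs


class TSSIndex:
    """Per-chromosome sorted index of TSS positions for nearest queries.

    Records are ordered by (position, gene_id) so that the documented tie
    break — lower position first, then lexicographic gene_id — falls out of
    index order.
    """

    def __init__(self, records: Iterable[TSSRecord]):
        by_chrom: dict[str, list[TSSRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._positions: dict[str, np.ndarray] = {}
        self._genes: dict[str, list[str]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.position, r.gene_id))
            self._positions[chrom] = np.array(
                [r.position for r in recs], dtype=np.int64
            )
            self._genes[chrom] = [r.gene_id for r in recs]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._positions

    def chroms(self) -> list[str]:
        return list(self._positions)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions[chrom]

    def nearest(self, chrom: str, start: int, end: int) -> tuple[str | None, float]:
        """Nearest TSS to the closed position span [start, end]; returns
        (gene_id, distance). No TSS on the chromosome -> (None, inf)."""
        pos = self._positions.get(chrom)
        if pos is None or len(pos) == 0:
            return None, INF
        genes = self._genes[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        # a TSS inside [start, end] has distance 0; the first such index is
        # the lowest position (gene_id ties resolved by index order)
        if lo < len(pos) and pos[lo] <= end:
            return genes[lo], 0.0
        best_gene, best_dist = None, INF
        if lo < len(pos):  # nearest on the right
            best_gene, best_dist = genes[lo], float(pos[lo] - end)
        if lo > 0:  # nearest on the left; ties prefer the lower position
            d = float(start - pos[lo - 1])
            if d <= best_dist:
                # leftmost record sharing this position wins the gene_id tie
                first = int(np.searchsorted(pos, pos[lo - 1], side="left"))
                best_gene, best_dist = genes[first], d
        return best_gene, best_dist


def nearest_tss(
    peak: GenomicInterval, tss: TSSIndex, use_summit: bool = False
) -> tuple[str | None, float]:
    """Nearest TSS to a peak under the nearest-bp convention (default) or
    measured from the peak anchor point (``use_summit``)."""
    if use_summit:
        p = peak.anchor
        return tss.nearest(peak.chrom, p, p)
    return tss.nearest(peak.chrom, peak.start, peak.end - 1)


@dataclass(frozen=True)
class PeakClassification:
    peak: GenomicInterval
    klass: str  # "tss_proximal" | "distal"
    distance_to_tss: float
    nearest_gene: str | None


def classify_peaks(
    peaks: PeakSet,
    tss: TSSIndex,
    tss_threshold: int = 1000,
    use_summit: bool = False,
) -> list[PeakClassification]:
    """Label every peak tss_proximal (nearest-TSS distance <= threshold,
    inclusive) or distal. Peaks on chromosomes absent from the annotation
    are classified distal with distance +inf and retained."""
    if tss_threshold < 0:
        raise ValueError("tss_threshold must be >= 0")
    out = []
    for peak in peaks:
        gene, dist = nearest_tss(peak, tss, use_summit=use_summit)
        klass = "tss_proximal" if dist <= tss_threshold else "distal"
        out.append(PeakClassification(peak, klass, dist, gene))
    return out


def classifications_to_frame(
    classifications: Sequence[PeakClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.peak.chrom for c in classifications],
            "start": [c.peak.start for c in classifications],
            "end": [c.peak.end for c in classifications],
            "peak_id": [c.peak.id for c in classifications],
            "klass": [c.klass for c in classifications],
            "distance_to_tss": [c.distance_to_tss for c in classifications],
            "nearest_gene": [c.nearest_gene for c in classifications],
        }
    )


@dataclass
class ComparisonResult:
    """Peak- and gene-level comparison of condition A against condition B."""

    label_a: str
    label_b: str
    shared_a: list[int]  # indices into A overlapping >= 1 peak of B
    specific_a: list[int]
    shared_b: list[int]
    specific_b: list[int]
    shared_genes: set[str]
    specific_genes_a: set[str]
    specific_genes_b: set[str]
    frac_distal_specific_a: float
    frac_distal_specific_b: float

    def summary(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_a": len(self.shared_a) + len(self.specific_a),
            "n_b": len(self.shared_b) + len(self.specific_b),
            "n_shared_a": len(self.shared_a),
            "n_specific_a": len(self.specific_a),
            "n_shared_b": len(self.shared_b),
            "n_specific_b": len(self.specific_b),
            "n_shared_genes": len(self.shared_genes),
            "n_specific_genes_a": len(self.specific_genes_a),
            "n_specific_genes_b": len(self.specific_genes_b),
            "frac_distal_specific_a": self.frac_distal_specific_a,
            "frac_distal_specific_b": self.frac_distal_specific_b,
        }


def compare_conditions(
    a: PeakSet,
    b: PeakSet,
    tss: TSSIndex,
    min_overlap: int = 1,
    tss_threshold: int = 1000,
) -> ComparisonResult:
    """Partition each condition's peaks into shared (>= min_overlap bp with
    at least one peak of the other condition) and condition-specific, and
    intersect the nearest-gene label sets of the two conditions.

    Also reports, among each condition's specific peaks, the fraction
    classified distal under ``tss_threshold`` — the redistribution readout.
    """
    pairs = intersect_sets(a, b, min_overlap=min_overlap, max_gap=0)
    hit_a = {i for i, _ in pairs}
    hit_b = {j for _, j in pairs}
    shared_a = sorted(hit_a)
    specific_a = [i for i in range(len(a)) if i not in hit_a]
    shared_b = sorted(hit_b)
    specific_b = [j for j in range(len(b)) if j not in hit_b]

    cls_a = classify_peaks(a, tss, tss_threshold)
    cls_b = classify_peaks(b, tss, tss_threshold)
    genes_a = {c.nearest_gene for c in cls_a if c.nearest_gene is not None}
    genes_b = {c.nearest_gene for c in cls_b if c.nearest_gene is not None}

    def frac_distal(cls, idx):
        if not idx:
            return 0.0
        return sum(cls[i].klass == "distal" for i in idx) / len(idx)

    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        shared_a=shared_a,
        specific_a=specific_a,
        shared_b=shared_b,
        specific_b=specific_b,
        shared_genes=genes_a & genes_b,
        specific_genes_a=genes_a - genes_b,
        specific_genes_b=genes_b - genes_a,
        frac_distal_specific_a=frac_distal(cls_a, specific_a),
        frac_distal_specific_b=frac_distal(cls_b, specific_b),
    )
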