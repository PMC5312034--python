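"""Active vs poised enhancer calling by 1-D k-means on H3K27ac signal.

Distal peaks are split into an H3K27ac-high (active) and an H3K27ac-low
(poised) class by k-means with k=2 on the per-peak input-normalised
acetylation level. "Low or no" acetylation is a single class: peaks with
absent signal are not separated from weakly marked ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import CoverageTrack, PeakSet
from .signal import SignalMatrix, normalized_peak_summaries, peak_summaries


class DegenerateInputError(ValueError):
    """Clustering input has fewer distinct values than clusters."""


def kmeans_1d(
    values: Sequence[float],
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster scalar values with k-means (k-means++ init, best of
    ``n_init`` restarts by within-cluster sum of squares).

    Returns (labels, centroids) with centroids sorted ascending and labels
    renumbered to match, so label 0 is always the lowest-signal cluster.
    Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(x) < k:
        raise ValueError(f"need at least {k} values")
    if len(np.unique(x)) < k:
        raise DegenerateInputError(
            f"only {len(np.unique(x))} distinct values for k={k}"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    ).fit(x.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids, kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    return relabel[km.labels_], centroids[order]


@dataclass(frozen=True)
class EnhancerClassLabel:
    peak_id: str
    cluster: str  # "high" | "low"
    h3k27ac_value: float


@dataclass
class EnhancerClassification:
    labels: list[EnhancerClassLabel]
    fraction_low: float
    centroids: np.ndarray  # ascending: [low, high]
    seed: int

    @property
    def fraction_high(self) -> float:
        return 1.0 - self.fraction_low

    def summary(self) -> dict:
        n_low = sum(1 for lab in self.labels if lab.cluster == "low")
        return {
            "n_peaks": len(self.labels),
            "n_low": n_low,
            "n_high": len(self.labels) - n_low,
            "fraction_low": self.fraction_low,
            "centroid_low": float(self.centroids[0]),
            "centroid_high": float(self.centroids[1]),
            "seed": self.seed,
        }


def classify_enhancers(
    distal_peaks: PeakSet,
    h3k27ac_ip: CoverageTrack,
    h3k27ac_input: CoverageTrack | None = None,
    seed: int = 0,
    pseudocount: float = 1.0,
    n_init: int = 10,
) -> EnhancerClassification:
    """Split distal peaks into H3K27ac-high and -low classes.

    The clustered quantity is the per-peak mean log2(IP/input) after depth
    adjustment when an input track is supplied, otherwise the raw per-peak
    mean IP density. The cluster with the larger centroid is "high";
    fraction_low = |low| / |peaks|.
    """
    if h3k27ac_input is not None:
        values = normalized_peak_summaries(
            h3k27ac_ip, h3k27ac_input, distal_peaks, pseudocount
        )
    else:
        values = peak_summaries(h3k27ac_ip, distal_peaks)
    labels_num, centroids = kmeans_1d(values, k=2, seed=seed, n_init=n_init)
    names = {0: "low", 1: "high"}
    labels = [
        EnhancerClassLabel(peak.id, names[int(lab)], float(val))
        for peak, lab, val in zip(distal_peaks, labels_num, values)
    ]
    fraction_low = float(np.mean(labels_num == 0))
    return EnhancerClassification(labels, fraction_low, centroids, seed)


def sort_rows(
    matrix: SignalMatrix, labels: Sequence[EnhancerClassLabel]
) -> SignalMatrix:
    """Reorder matrix rows for display: high cluster first, then descending
    H3K27ac value within each cluster; stable for ties, so equal-value rows
    keep their original relative order regardless of input permutation."""
    by_id = {lab.peak_id: lab for lab in labels}
    missing = [pid for pid in matrix.peak_ids if pid not in by_id]
    if missing:
        raise ValueError(f"no enhancer label for rows: {missing[:5]}")
    keyed = [
        (0 if by_id[pid].cluster == "high" else 1, -by_id[pid].h3k27ac_value)
        for pid in matrix.peak_ids
    ]
    order = sorted(range(len(keyed)), key=keyed.__getitem__)  # stable
    return matrix.reordered(order)
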