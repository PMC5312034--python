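"""Coverage normalisation and binned signal matrices.

The normalisation pipeline mirrors standard ChIP-seq practice: each track is
scaled to a common sequencing depth (counts per million: every run value is
multiplied by 1e6 / total_signal), both IP and matched input are binned over
windows centred on peak anchors, and enrichment is the bin-wise
log2((ip + c) / (input + c)) ratio with pseudocount c guarding zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CoverageTrack, GenomicInterval, PeakSet


def depth_adjust(track: CoverageTrack) -> CoverageTrack:
    """Scale a track to 1e6 total signal (counts-per-million). Idempotent
    after the first application; an empty track cannot be scaled."""
    if track.total_signal <= 0:
        raise ValueError("cannot depth-adjust a track with zero total signal")
    return track.scaled(1e6 / track.total_signal)


def input_normalize(ip_value, input_value, pseudocount: float = 1.0):
    """log2((ip + pseudocount) / (input + pseudocount)), element-wise.

    Accepts scalars or arrays; antisymmetric under swapping ip and input,
    and exactly 0 wherever the two agree.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ip = np.asarray(ip_value, dtype=np.float64)
    inp = np.asarray(input_value, dtype=np.float64)
    if np.any(ip < 0) or np.any(inp < 0):
        raise ValueError("densities must be >= 0")
    out = np.log2((ip + pseudocount) / (inp + pseudocount))
    return float(out) if out.ndim == 0 else out


@dataclass
class SignalMatrix:
    """Peaks x bins matrix of signal over fixed windows centred on peaks."""

    peak_ids: list[str]
    window_size: int
    bin_size: int
    values: np.ndarray  # shape (n_peaks, n_bins)
    track_label: str = ""
    # rows whose window ran past the chromosome start (out-of-range spans
    # contributed 0 rather than being dropped)
    clipped_rows: list[int] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.window_size // self.bin_size

    @property
    def bin_offsets(self) -> np.ndarray:
        """Offset of each bin centre from the window centre, in bp."""
        half = self.window_size // 2
        return (
            -half + self.bin_size * np.arange(self.n_bins) + self.bin_size / 2
        )

    def reordered(self, order) -> "SignalMatrix":
        order = list(order)
        return SignalMatrix(
            peak_ids=[self.peak_ids[i] for i in order],
            window_size=self.window_size,
            bin_size=self.bin_size,
            values=self.values[order],
            track_label=self.track_label,
            clipped_rows=sorted(order.index(r) for r in self.clipped_rows if r in order),
        )


def compute_matrix(
    track: CoverageTrack,
    peaks: PeakSet,
    window_size: int = 10000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Binned mean signal over a ``window_size`` bp window centred at each
    peak's anchor (summit when called, midpoint otherwise).

    Bin j of row i covers [anchor_i - window/2 + j*bin, ... + (j+1)*bin);
    spans falling before position 0 or past the end of the track contribute
    value 0, so every row stays rectangular.
    """
    if window_size % bin_size != 0:
        raise ValueError("window_size must be divisible by bin_size")
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    n_bins = window_size // bin_size
    half = window_size // 2
    values = np.zeros((len(peaks), n_bins), dtype=np.float64)
    clipped = []
    for i, peak in enumerate(peaks):
        w0 = peak.anchor - half
        edges = w0 + bin_size * np.arange(n_bins + 1)
        if edges[0] < 0:
            clipped.append(i)
        integrals = track.integral(peak.chrom, np.maximum(edges, 0))
        values[i] = np.diff(integrals) / bin_size
    return SignalMatrix(
        peak_ids=[p.id for p in peaks],
        window_size=window_size,
        bin_size=bin_size,
        values=values,
        track_label=track_label_of(track),
        clipped_rows=clipped,
    )


def track_label_of(track: CoverageTrack) -> str:
    return getattr(track, "label", "")


def normalized_matrix(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    peaks: PeakSet,
    window_size: int = 10000,
    bin_size: int = 50,
    pseudocount: float = 1.0,
    label: str = "",
) -> SignalMatrix:
    """Depth-adjust IP and input, bin both over the same windows, and return
    the bin-wise log2 ratio matrix."""
    m_ip = compute_matrix(depth_adjust(ip), peaks, window_size, bin_size)
    m_in = compute_matrix(depth_adjust(input_track), peaks, window_size, bin_size)
    out = SignalMatrix(
        peak_ids=m_ip.peak_ids,
        window_size=window_size,
        bin_size=bin_size,
        values=input_normalize(m_ip.values, m_in.values, pseudocount),
        track_label=label,
        clipped_rows=m_ip.clipped_rows,
    )
    return out


def average_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin mean over all rows (the metagene/average-density profile)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("matrix is empty")
    return matrix.values.mean(axis=0)


def peak_summary(track: CoverageTrack, peak: GenomicInterval) -> float:
    """Mean signal density over the peak interval itself (not the window);
    gap regions count as 0."""
    return track.mean_over(peak.chrom, peak.start, peak.end)


def peak_summaries(track: CoverageTrack, peaks: PeakSet) -> np.ndarray:
    return np.array([peak_summary(track, p) for p in peaks], dtype=np.float64)


def normalized_peak_summaries(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    peaks: PeakSet,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-peak log2(IP/input) after depth adjustment of both tracks."""
    s_ip = peak_summaries(depth_adjust(ip), peaks)
    s_in = peak_summaries(depth_adjust(input_track), peaks)
    return input_normalize(s_ip, s_in, pseudocount)


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, NaN where undefined (zero variance)


def correlation_matrix(summaries: dict[str, np.ndarray]) -> CorrelationMatrix:
    """Pairwise Pearson correlation of per-peak occupancy vectors.

    All vectors must cover the same peaks (equal length >= 3). A vector with
    zero variance yields NaN entries in its row/column (flagged missing,
    never silently 0); its diagonal entry is NaN too.
    """
    labels = list(summaries)
    if len(labels) < 2:
        raise ValueError("need at least two factors")
    vectors = [np.asarray(summaries[k], dtype=np.float64) for k in labels]
    n = len(vectors[0])
    if n < 3:
        raise ValueError("need vectors of length >= 3")
    if any(len(v) != n for v in vectors):
        raise ValueError("summary vectors differ in length")
    k = len(labels)
    out = np.full((k, k), np.nan)
    sds = [float(np.std(v)) for v in vectors]
    for i in range(k):
        if sds[i] == 0:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, k):
            if sds[j] == 0:
                continue
            r = float(np.corrcoef(vectors[i], vectors[j])[0, 1])
            out[i, j] = out[j, i] = r
    return CorrelationMatrix(labels, out)
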