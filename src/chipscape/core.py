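"""Core genomic data types and plain-text format I/O.

All coordinates are 0-based half-open throughout the package; GTF input
(1-based inclusive) is converted on read. Chromosome names are compared as
exact strings — ``chr1`` and ``1`` are different sequences unless a rename
map is applied at read time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed record in a genomic text file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome.

    ``summit``, when present, is a 0-based offset from ``start`` marking the
    position of maximum signal within the peak (narrowPeak convention).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length "
                f"{self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Absolute bp used to centre signal windows: the summit when known,
        otherwise the interval midpoint floor((start+end)/2)."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2

    @property
    def id(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: the strand-resolved 0-based position where
    transcription of ``gene_id`` begins."""

    gene_id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")


class PeakSet:
    """A labelled, sorted collection of intervals for one factor in one
    condition. Sorting is by (chrom, start, end) and is enforced on
    construction."""

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        if not label:
            raise ValueError("PeakSet label must be non-empty")
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def subset(self, indices: Sequence[int], label: str | None = None) -> "PeakSet":
        return PeakSet(label or self.label, [self.intervals[i] for i in indices])


class CoverageTrack:
    """Run-length encoded genome-wide signal.

    Runs are stored per chromosome as parallel numpy arrays (starts, ends,
    values), sorted and non-overlapping; positions not covered by any run
    have value 0. ``total_signal`` is the integral sum(value * run length)
    over the whole track, used for sequencing-depth scaling.
    """

    def __init__(
        self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ):
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("run arrays must have equal length")
            if len(starts) == 0:
                continue
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: empty or inverted run")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping runs")
            if not np.all(np.isfinite(values)):
                raise FormatError(f"{chrom}: non-finite value")
            self.runs[chrom] = (starts, ends, values)
            total += float(np.sum(values * (ends - starts)))
        self.total_signal = total
        # cumulative integral per chromosome, built lazily for window queries
        self._cum: dict[str, np.ndarray] = {}

    def chroms(self) -> list[str]:
        return list(self.runs)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal value at a single position; 0 in gaps and off-track."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, values = self.runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def _cumulative(self, chrom: str) -> np.ndarray:
        cum = self._cum.get(chrom)
        if cum is None:
            starts, ends, values = self.runs[chrom]
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._cum[chrom] = cum
        return cum

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, x) for each x, vectorised."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self.runs:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self.runs[chrom]
        cum = self._cumulative(chrom)
        idx = np.searchsorted(starts, positions, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        valid = idx >= 0
        iv = np.maximum(idx, 0)
        partial = values[iv] * np.clip(positions - starts[iv], 0, ends[iv] - starts[iv])
        return out + np.where(valid, partial, 0.0)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end); gaps count as 0."""
        if end <= start:
            raise ValueError("end must exceed start")
        lo, hi = self.integral(chrom, np.array([max(start, 0), max(end, 0)]))
        return float(hi - lo) / (end - start)

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.runs.items()}
        )


# ---------------------------------------------------------------------------
# file I/O


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bed(
    path: str | Path,
    label: str | None = None,
    rename: Mapping[str, str] | None = None,
) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a sorted PeakSet.

    The optional 10th (narrowPeak summit) column populates ``summit`` when
    non-negative; -1 means "no summit called". ``rename`` maps chromosome
    names on read (e.g. {"1": "chr1"}).
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 fields")
            chrom = fields[0]
            if rename:
                chrom = rename.get(chrom, chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score") from exc
            strand = "."
            if len(fields) > 5:
                strand = fields[5]
                if strand not in VALID_STRANDS:
                    raise FormatError(
                        f"{path}:{lineno}: unknown strand {strand!r}"
                    )
            summit = None
            if len(fields) >= 10:
                try:
                    summit_val = int(fields[9])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad summit") from exc
                if summit_val >= 0:
                    summit = summit_val
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label or Path(path).stem, intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED; emits exactly the columns that are populated
    (BED6 when any name/score/strand is set, BED3 otherwise)."""
    want6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in peaks
    )
    with open(path, "wt") as fh:
        for iv in peaks:
            if want6:
                score = "0" if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tss(
    path: str | Path,
    format: str = "tsv",
    feature: str = "gene",
    rename: Mapping[str, str] | None = None,
) -> list[TSSRecord]:
    """Read TSS positions from a GTF (``format="gtf"``) or a 4-column TSV
    (gene_id, chrom, position, strand; ``format="tsv"``).

    GTF coordinates are 1-based inclusive: a '+' gene's TSS is start-1 in
    0-based coordinates, a '-' gene's TSS is end-1. Records missing a strand
    are skipped with a warning; duplicate gene_ids keep the first occurrence.
    """
    if format not in ("gtf", "tsv"):
        raise ValueError(f"unknown TSS format {format!r}")
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gtf":
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: GTF needs 9 fields")
                if fields[2] != feature:
                    continue
                chrom, strand = fields[0], fields[6]
                gene_id = _gtf_attribute(fields[8], "gene_id")
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: missing gene_id")
                try:
                    gstart, gend = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                if strand == "+":
                    position = gstart - 1
                elif strand == "-":
                    position = gend - 1
                else:
                    logger.warning(
                        "%s:%d: gene %s has no strand; skipped",
                        path, lineno, gene_id,
                    )
                    continue
            else:
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: TSV needs 4 fields")
                gene_id, chrom, strand = fields[0], fields[1], fields[3]
                try:
                    position = int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad position") from exc
                if strand not in ("+", "-"):
                    logger.warning(
                        "%s:%d: gene %s has no strand; skipped",
                        path, lineno, gene_id,
                    )
                    continue
            if rename:
                chrom = rename.get(chrom, chrom)
            if gene_id in seen:
                logger.warning("duplicate gene_id %s: keeping first", gene_id)
                continue
            seen.add(gene_id)
            records.append(TSSRecord(gene_id, chrom, position, strand))
    return records


def _gtf_attribute(attr_field: str, key: str) -> str | None:
    for part in attr_field.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def write_tss(records: Sequence[TSSRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.position}\t{r.strand}\n")


def read_bedgraph(
    path: str | Path, rename: Mapping[str, str] | None = None
) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack.

    Intervals are 0-based half-open. Overlapping runs and negative values
    are format errors; gaps imply value 0.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: fewer than 4 fields")
            chrom = fields[0]
            if rename:
                chrom = rename.get(chrom, chrom)
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates/value") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted run")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    runs = {}
    for chrom, triples in per_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        values = np.array([t[2] for t in triples], dtype=np.float64)
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"{path}: overlapping runs on {chrom}")
        runs[chrom] = (starts, ends, values)
    return CoverageTrack(runs)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as 4-column bedGraph; zero-valued runs are
    dropped (gaps imply 0 on read)."""
    with open(path, "wt") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
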