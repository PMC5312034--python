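"""Synthetic two-condition ChIP-seq landscapes with full ground truth.

The generator emulates the statistical structure of a naive-to-primed
embryonic stem cell priming experiment:

* a toy genome with uniformly spaced genes,
* a "naive" condition whose main-factor peaks are mostly TSS-proximal
  (70% by default) and a "primed" condition containing every naive peak
  plus additional distal peaks, most of them placed near genes already
  targeted in the naive state — the promoter-to-enhancer redistribution,
* a bimodal H3K27ac state over distal peaks (85% low/poised by default),
* partner factors planted within a fixed 150 bp gap of source peaks with a
  configurable probability (detectable under the 200 bp analysis gap),
* piecewise-constant coverage tracks: Poisson background per 50 bp step
  plus a triangular signal bump at each peak anchor, with a matched
  background-only input track.

Planted class counts are exact (round(proportion x n) by construction),
so recovery tolerances measure the pipeline, not generator sampling noise.
All outputs are pure functions of (config, seed); the global seed expands
into per-stage substreams by stable hashing of stage names, so adding a
stage never perturbs earlier streams.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    GenomicInterval,
    PeakSet,
    TSSRecord,
    write_bed,
    write_bedgraph,
    write_tss,
)

MIN_TSS_SPACING = 20_000
DISTAL_BUFFER = 5_000  # planted distal peaks keep >= 5 kb edge distance to any TSS
# planted distal peaks keep two bump widths between centres so each peak's
# signal (and hence its planted H3K27ac state) is unambiguous — peak callers
# emit disjoint peaks, so colliding planted peaks would be unrealistic anyway
DISTAL_SEPARATION_FACTOR = 2
SHARED_GENE_RANGE = (5_500, 50_000)  # centre offset for "near an A gene" placement
PARTNER_GAP = 150
COVERAGE_STEP = 50


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape (defaults are the study-like
    conditions, scaled to a 20 Mb toy genome)."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 8_000_000}
    )
    n_genes: int = 200
    n_peaks_a: int = 1000  # naive condition
    n_peaks_b: int = 2700  # primed condition: all naive peaks + extra distal
    frac_tss_a: float = 0.7
    frac_shared_genes: float = 0.8
    frac_low_h3k27ac: float = 0.85
    # ordered: each partner is planted near the peaks of an already
    # generated source, chaining med1 onto the main factor and the
    # remaining enhancer factors onto med1 (the tested pairs)
    cooccupancy_probs: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("jmjd2c", "med1"): 0.6,
            ("med1", "p300"): 0.6,
            ("med1", "oct4"): 0.6,
            ("med1", "smc1a"): 0.6,
        }
    )
    background_rate: float = 0.01  # Poisson intensity per bp
    peak_height: float = 10.0  # bump height; low-state bumps get height/10
    peak_width: int = 1000  # bump full width and emitted peak width
    main_factor: str = "jmjd2c"
    condition_a: str = "naive"
    condition_b: str = "primed"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("frac_tss_a", self.frac_tss_a),
            ("frac_shared_genes", self.frac_shared_genes),
            ("frac_low_h3k27ac", self.frac_low_h3k27ac),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for p in self.cooccupancy_probs.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("cooccupancy probabilities must be in [0, 1]")
        if any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        if self.n_peaks_b < self.n_peaks_a:
            raise ValueError("n_peaks_b must be >= n_peaks_a (superset design)")
        if self.peak_width <= 0 or self.peak_width % 2:
            raise ValueError("peak_width must be positive and even")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream of the global seed."""
        tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, tag])
        )


@dataclass
class SyntheticTruth:
    """Per-peak planted ground truth plus the generating config."""

    records: pd.DataFrame  # condition, factor, peak_id, chrom, start, end,
    #                        klass, state, gene
    config: SyntheticConfig

    def subset(self, **where) -> pd.DataFrame:
        df = self.records
        for col, val in where.items():
            df = df[df[col] == val]
        return df


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[dict[str, int], list[TSSRecord]]:
    """Place n_genes TSS uniformly with pairwise spacing >= 20 kb.

    Genes are apportioned to chromosomes by size; within a chromosome,
    positions are drawn by the exact uniform-with-minimum-spacing
    construction (sorted uniforms in the shrunk domain plus i*spacing).
    Strands alternate. Deterministic given the config seed.
    """
    rng = config.rng("annotation")
    chroms = sorted(config.chrom_sizes)
    total = sum(config.chrom_sizes.values())
    counts = {c: int(config.n_genes * config.chrom_sizes[c] / total) for c in chroms}
    leftover = config.n_genes - sum(counts.values())
    for c in chroms[:leftover]:
        counts[c] += 1
    records: list[TSSRecord] = []
    gene_no = 0
    for chrom in chroms:
        n = counts[chrom]
        if n == 0:
            continue
        size = config.chrom_sizes[chrom]
        shrunk = size - (n - 1) * MIN_TSS_SPACING
        if shrunk <= 0:
            raise ValueError(
                f"{chrom} ({size} bp) cannot host {n} genes at "
                f"{MIN_TSS_SPACING} bp spacing"
            )
        u = np.sort(rng.integers(0, shrunk, size=n))
        positions = u + MIN_TSS_SPACING * np.arange(n)
        for pos in positions:
            strand = "+" if gene_no % 2 == 0 else "-"
            records.append(
                TSSRecord(f"gene{gene_no:04d}", chrom, int(pos), strand)
            )
            gene_no += 1
    return dict(config.chrom_sizes), records


def _tss_arrays(records: Sequence[TSSRecord]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for r in records:
        out.setdefault(r.chrom, []).append(r.position)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


def _min_tss_distance(chrom: str, centre: int, tss_pos: dict[str, np.ndarray]) -> int:
    pos = tss_pos.get(chrom)
    if pos is None or len(pos) == 0:
        return np.iinfo(np.int64).max
    i = int(np.searchsorted(pos, centre))
    best = np.iinfo(np.int64).max
    if i < len(pos):
        best = min(best, int(pos[i] - centre))
    if i > 0:
        best = min(best, int(centre - pos[i - 1]))
    return best


# ---------------------------------------------------------------------------
# peaks


def _interval_at(
    chrom: str, centre: int, width: int, name: str, sizes: Mapping[str, int]
) -> GenomicInterval:
    half = width // 2
    start = max(0, min(centre - half, sizes[chrom] - width))
    return GenomicInterval(chrom, start, start + width, name=name)


def generate_peaks(
    config: SyntheticConfig,
    annotation: tuple[dict[str, int], list[TSSRecord]],
) -> tuple[dict[str, dict[str, PeakSet]], SyntheticTruth]:
    """Plant the two-condition, multi-factor peak landscape.

    Condition A gets exactly round(frac_tss_a * n_peaks_a) peaks centred
    within 1 kb of a TSS and the remainder distal (>= 5 kb edge distance
    from every TSS). Condition B contains every A peak plus extra distal
    peaks, round(frac_shared_genes * extra) of them 5.5-50 kb from genes
    already targeted in A. Enhancer states (high/low H3K27ac) are assigned
    to distal main-factor peaks with an exact low-state count. Partner
    factor peaks are planted at a fixed 150 bp gap from distal source
    peaks with the configured probability, else placed uniformly.
    """
    rng = config.rng("peaks")
    sizes, tss_records = annotation
    tss_pos = _tss_arrays(tss_records)
    genes_by_chrom: dict[str, list[TSSRecord]] = {}
    for r in tss_records:
        genes_by_chrom.setdefault(r.chrom, []).append(r)
    for recs in genes_by_chrom.values():
        recs.sort(key=lambda r: r.position)
    all_genes = [r for c in sorted(genes_by_chrom) for r in genes_by_chrom[c]]
    chrom_names = sorted(sizes)
    chrom_p = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    width = config.peak_width
    max_attempts = 1000
    min_sep = DISTAL_SEPARATION_FACTOR * width
    placed_distal: dict[str, list[int]] = {c: [] for c in chrom_names}

    def distal_clear(chrom: str, centre: int) -> bool:
        from bisect import bisect_left

        centres = placed_distal[chrom]
        i = bisect_left(centres, centre)
        if i < len(centres) and centres[i] - centre < min_sep:
            return False
        if i > 0 and centre - centres[i - 1] < min_sep:
            return False
        return True

    def register_distal(chrom: str, centre: int) -> None:
        from bisect import insort

        insort(placed_distal[chrom], centre)

    def sample_proximal(tag: str, count: int) -> list[tuple[GenomicInterval, str]]:
        out = []
        for i in range(count):
            for _ in range(max_attempts):
                gene = all_genes[int(rng.integers(len(all_genes)))]
                offset = int(rng.integers(-1000, 1001))
                centre = gene.position + offset
                if width // 2 <= centre <= sizes[gene.chrom] - width // 2:
                    out.append(
                        (
                            _interval_at(
                                gene.chrom, centre, width, f"{tag}{i:05d}", sizes
                            ),
                            gene.gene_id,
                        )
                    )
                    break
            else:
                raise RuntimeError("proximal placement failed")
        return out

    def nearest_gene_id(chrom: str, centre: int) -> str:
        recs = genes_by_chrom.get(chrom)
        if not recs:
            return ""
        pos = tss_pos[chrom]
        i = int(np.searchsorted(pos, centre))
        cands = []
        if i < len(pos):
            cands.append(recs[i])
        if i > 0:
            cands.append(recs[i - 1])
        return min(cands, key=lambda r: abs(r.position - centre)).gene_id

    def sample_distal_uniform(tag: str, count: int) -> list[tuple[GenomicInterval, str]]:
        out = []
        for i in range(count):
            for _ in range(max_attempts):
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                centre = int(rng.integers(width // 2, sizes[chrom] - width // 2))
                if (
                    _min_tss_distance(chrom, centre, tss_pos)
                    >= DISTAL_BUFFER + width // 2
                    and distal_clear(chrom, centre)
                ):
                    register_distal(chrom, centre)
                    out.append(
                        (
                            _interval_at(chrom, centre, width, f"{tag}{i:05d}", sizes),
                            nearest_gene_id(chrom, centre),
                        )
                    )
                    break
            else:
                raise RuntimeError("distal placement failed; genome too dense")
        return out

    def sample_distal_near(
        tag: str, count: int, genes: Sequence[TSSRecord]
    ) -> list[tuple[GenomicInterval, str]]:
        lo, hi = SHARED_GENE_RANGE
        out = []
        for i in range(count):
            for _ in range(max_attempts):
                gene = genes[int(rng.integers(len(genes)))]
                offset = int(rng.integers(lo, hi + 1)) * (
                    1 if rng.random() < 0.5 else -1
                )
                centre = gene.position + offset
                if not (width // 2 <= centre <= sizes[gene.chrom] - width // 2):
                    continue
                if (
                    _min_tss_distance(gene.chrom, centre, tss_pos)
                    >= DISTAL_BUFFER + width // 2
                    and distal_clear(gene.chrom, centre)
                ):
                    register_distal(gene.chrom, centre)
                    out.append(
                        (
                            _interval_at(gene.chrom, centre, width, f"{tag}{i:05d}", sizes),
                            nearest_gene_id(gene.chrom, centre),
                        )
                    )
                    break
            else:
                raise RuntimeError("shared-gene distal placement failed")
        return out

    # condition A (naive): exact TSS-proximal count
    n_prox = round(config.frac_tss_a * config.n_peaks_a)
    n_dist_a = config.n_peaks_a - n_prox
    prox_a = sample_proximal("naive_tss_", n_prox)
    dist_a = sample_distal_uniform("naive_dist_", n_dist_a)

    # condition B (primed): superset of A plus extra distal
    extra = config.n_peaks_b - config.n_peaks_a
    n_near = round(config.frac_shared_genes * extra)
    a_gene_ids = {g for _, g in prox_a} | {g for _, g in dist_a}
    a_genes = [r for r in all_genes if r.gene_id in a_gene_ids]
    near_b = sample_distal_near("primed_near_", n_near, a_genes or all_genes)
    far_b = sample_distal_uniform("primed_far_", extra - n_near)

    # enhancer states over primed distal peaks: exact low count
    primed_distal = dist_a + near_b + far_b
    n_low = round(config.frac_low_h3k27ac * len(primed_distal))
    state_order = rng.permutation(len(primed_distal))
    states = np.array(["high"] * len(primed_distal), dtype=object)
    states[state_order[:n_low]] = "low"
    state_by_id = {
        iv.name: states[i] for i, (iv, _) in enumerate(primed_distal)
    }

    main = config.main_factor
    cond_a, cond_b = config.condition_a, config.condition_b
    landscape: dict[str, dict[str, PeakSet]] = {cond_a: {}, cond_b: {}}
    landscape[cond_a][main] = PeakSet(
        f"{main}_{cond_a}", [iv for iv, _ in prox_a + dist_a]
    )
    landscape[cond_b][main] = PeakSet(
        f"{main}_{cond_b}", [iv for iv, _ in prox_a + primed_distal]
    )

    rows = []

    def record(condition, factor, iv, klass, state, gene):
        rows.append(
            {
                "condition": condition,
                "factor": factor,
                "peak_id": iv.name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "klass": klass,
                "state": state,
                "gene": gene,
            }
        )

    for iv, gene in prox_a:
        record(cond_a, main, iv, "tss_proximal", "", gene)
        record(cond_b, main, iv, "tss_proximal", "", gene)
    for iv, gene in dist_a:
        record(cond_a, main, iv, "distal", state_by_id[iv.name], gene)
        record(cond_b, main, iv, "distal", state_by_id[iv.name], gene)
    for iv, gene in near_b + far_b:
        record(cond_b, main, iv, "distal", state_by_id[iv.name], gene)

    # partner factors planted against primed distal source peaks; chained
    # partners are placed on the side of their source facing the original
    # site, so co-occupied factors cluster at the same enhancer
    source_sets = {main: [iv for iv, _ in primed_distal]}
    origin_of: dict[str, GenomicInterval] = {}
    for (src, partner), prob in config.cooccupancy_probs.items():
        sources = source_sets.get(src)
        if sources is None:
            raise ValueError(f"co-occupancy source factor {src!r} not generated")
        planted = rng.random(len(sources)) < prob
        intervals = []
        for i, (src_iv, is_planted) in enumerate(zip(sources, planted)):
            name = f"{partner}_{i:05d}"
            if is_planted:
                origin = origin_of.get(src_iv.name)
                side = None
                if origin is not None:
                    side = "left" if origin.start < src_iv.start else "right"
                iv = partner_interval(
                    src_iv, sizes, width, PARTNER_GAP, rng, name, side=side
                )
                origin_of[name] = src_iv
            else:
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                centre = int(rng.integers(width // 2, sizes[chrom] - width // 2))
                iv = _interval_at(chrom, centre, width, name, sizes)
            intervals.append(iv)
            record(
                cond_b,
                partner,
                iv,
                "",
                "",
                "",
            )
            rows[-1]["planted_near"] = src_iv.name if is_planted else ""
        landscape[cond_b][partner] = PeakSet(f"{partner}_{cond_b}", intervals)
        source_sets[partner] = intervals  # later pairs may chain onto this

    truth = SyntheticTruth(pd.DataFrame(rows), config)
    return landscape, truth


def partner_interval(
    src: GenomicInterval,
    sizes: Mapping[str, int],
    width: int,
    gap: int,
    rng: np.random.Generator,
    name: str,
    side: str | None = None,
) -> GenomicInterval:
    """A partner peak separated from ``src`` by exactly ``gap`` bp.

    ``side`` forces left/right placement (used to keep chained partners
    clustered around the same site); None picks a random side. Either way
    the other side is the fallback at chromosome edges."""
    right_start = src.end + gap
    left_start = src.start - gap - width
    if side is None:
        prefer_right = rng.random() < 0.5
    else:
        prefer_right = side == "right"
    for start in ([right_start, left_start] if prefer_right else [left_start, right_start]):
        if 0 <= start and start + width <= sizes[src.chrom]:
            return GenomicInterval(src.chrom, start, start + width, name=name)
    raise RuntimeError("cannot place partner peak within chromosome bounds")


def plant_partner_peaks(
    universe: PeakSet,
    indices: Sequence[int],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    label: str,
    width: int = 500,
    gap: int = PARTNER_GAP,
) -> PeakSet:
    """Partner set with one peak at a fixed ``gap`` from each selected
    universe peak — the planted co-occupancy building block used by the
    calibration and power studies."""
    intervals = [
        partner_interval(universe[i], chrom_sizes, width, gap, rng, f"{label}_{j:05d}")
        for j, i in enumerate(indices)
    ]
    return PeakSet(label, intervals)


def uniform_peak_set(
    label: str,
    n: int,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    width: int = 500,
) -> PeakSet:
    """n peaks placed uniformly over the genome (no TSS constraint)."""
    chroms = sorted(chrom_sizes)
    p = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    p /= p.sum()
    intervals = []
    for i in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=p))]
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        intervals.append(
            GenomicInterval(chrom, start, start + width, name=f"{label}_{i:05d}")
        )
    return PeakSet(label, intervals)


# ---------------------------------------------------------------------------
# coverage


def _triangle_cumulative(
    x: np.ndarray, centre: int, height: float, half_width: float
) -> np.ndarray:
    """Integral from -inf to x of the triangular bump
    h * max(0, 1 - |t - centre| / half_width)."""
    y = np.clip(x - centre, -half_width, half_width).astype(np.float64)
    left = height * (y + half_width) ** 2 / (2 * half_width)
    right = (
        height * half_width / 2
        + height * (y - y**2 / (2 * half_width))
    )
    return np.where(y <= 0, left, right)


def generate_coverage(
    peaks: PeakSet,
    config: SyntheticConfig,
    states: Mapping[str, str] | None = None,
    stage: str = "coverage",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate an (IP, input) bedGraph-style track pair over the genome.

    Both tracks draw independent Poisson(background_rate * 50) counts per
    50 bp step. The IP track additionally carries a triangular bump of full
    width ``peak_width`` at each peak anchor: height ``peak_height`` for
    high-state peaks (and peaks without a state), ``peak_height / 10`` for
    low-state peaks, added as the exact per-step mean of the triangle.
    """
    rng = config.rng(stage)
    step = COVERAGE_STEP
    half_width = config.peak_width / 2
    by_chrom = peaks.by_chrom()
    ip_runs, input_runs = {}, {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        n_steps = (size + step - 1) // step
        starts = np.arange(n_steps, dtype=np.int64) * step
        ends = np.minimum(starts + step, size)
        ip_vals = rng.poisson(config.background_rate * step, n_steps).astype(
            np.float64
        )
        input_vals = rng.poisson(
            config.background_rate * step, n_steps
        ).astype(np.float64)
        for peak in by_chrom.get(chrom, []):
            state = (states or {}).get(peak.id, "high")
            height = (
                config.peak_height if state != "low" else config.peak_height / 10
            )
            anchor = peak.anchor
            i0 = max(0, int((anchor - half_width) // step))
            i1 = min(n_steps, int(np.ceil((anchor + half_width) / step)))
            if i1 <= i0:
                continue
            edges = np.arange(i0, i1 + 1, dtype=np.int64) * step
            cum = _triangle_cumulative(edges, anchor, height, half_width)
            ip_vals[i0:i1] += np.diff(cum) / step
        ip_runs[chrom] = (starts, ends, ip_vals)
        input_runs[chrom] = (starts, ends, input_vals)
    return CoverageTrack(ip_runs), CoverageTrack(input_runs)


# ---------------------------------------------------------------------------
# fixture bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["cooccupancy_probs"] = {
        f"{a}:{b}": p for (a, b), p in config.cooccupancy_probs.items()
    }
    return d


def write_fixture_bundle(outdir: str | Path, config: SyntheticConfig) -> dict:
    """Generate a complete landscape and write every file the pipeline
    consumes: BED per factor/condition, TSS table, bedGraph IP/input pairs
    for the main factor and H3K27ac, truth TSV, config snapshot, and a
    manifest of sha256 checksums. Byte-identical for identical (config,
    seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes, tss = generate_annotation(config)
    landscape, truth = generate_peaks(config, annotation=(sizes, tss))

    files: dict[str, Path] = {}

    tss_path = outdir / "tss.tsv"
    write_tss(tss, tss_path)
    files["tss"] = tss_path

    for condition, factors in landscape.items():
        for factor, peakset in factors.items():
            path = outdir / f"{factor}_{condition}.bed"
            write_bed(peakset, path)
            files[f"peaks:{factor}:{condition}"] = path

    main = config.main_factor
    primed = landscape[config.condition_b][main]
    # main-factor signal: every peak carries a full-height bump
    ip, inp = generate_coverage(primed, config, stage=f"coverage:{main}")
    for tag, track in ((f"{main}_ip", ip), (f"{main}_input", inp)):
        path = outdir / f"{tag}.bedgraph"
        write_bedgraph(track, path)
        files[f"coverage:{tag}"] = path
    # acetylation signal: bimodal over distal peaks, high at promoters
    truth_b = truth.subset(condition=config.condition_b, factor=main)
    states = {
        row.peak_id: (row.state if row.state else "high")
        for row in truth_b.itertuples()
    }
    ip, inp = generate_coverage(primed, config, states=states, stage="coverage:h3k27ac")
    for tag, track in (("h3k27ac_ip", ip), ("h3k27ac_input", inp)):
        path = outdir / f"{tag}.bedgraph"
        write_bedgraph(track, path)
        files[f"coverage:{tag}"] = path

    truth_path = outdir / "truth.tsv"
    truth.records.to_csv(truth_path, sep="\t", index=False)
    files["truth"] = truth_path

    config_path = outdir / "config.json"
    with open(config_path, "wt") as fh:
        json.dump(_config_to_jsonable(config), fh, indent=2, sort_keys=True)
    files["config"] = config_path

    manifest = {
        "files": {
            key: {"path": path.name, "sha256": _sha256(path)}
            for key, path in sorted(files.items())
        },
        "seed": config.seed,
    }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
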