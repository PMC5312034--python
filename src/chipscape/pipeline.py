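"""End-to-end pipeline: config validation, stage orchestration, reporting.

Stages run in a fixed order — peak classification, condition comparison,
signal matrices, enhancer-state calling, co-occupancy enrichment — and each
writes its tabular outputs (TSV/JSON) before the next begins, so a failing
stage leaves earlier results on disk. All tabular outputs are deterministic
functions of (config, seed); per-stage wall-clock goes to a separate
timings file so the report itself is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccupancy import pairwise_table
from .core import CoverageTrack, PeakSet, read_bed, read_bedgraph, read_tss
from .enhancers import classify_enhancers, sort_rows
from .intervals import (
    TSSIndex,
    classifications_to_frame,
    classify_peaks,
    compare_conditions,
)
from .signal import (
    average_profile,
    correlation_matrix,
    normalized_matrix,
    normalized_peak_summaries,
)

logger = logging.getLogger(__name__)

PARAM_RANGES: dict[str, tuple[float, float]] = {
    "tss_threshold": (0, 1e9),
    "min_overlap": (1, 1e9),
    "max_gap": (0, 1e9),
    "window_size": (100, 1e9),
    "bin_size": (1, 1e9),
    "pseudocount": (1e-12, 1e9),
    "k": (2, 64),
    "seed": (0, 2**31 - 1),
}

DEFAULT_PARAMS: dict[str, Any] = {
    "tss_threshold": 1000,
    "min_overlap": 1,
    "max_gap": 200,
    "window_size": 10000,
    "bin_size": 50,
    "pseudocount": 1.0,
    "k": 2,
    "seed": 0,
}

UNIVERSE_CHOICES = ("distal_all", "distal_high", "distal_low")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    tss_path: Path
    tss_format: str
    peak_paths: dict[str, dict[str, Path]]  # factor -> condition -> path
    coverage_paths: dict[str, dict[str, Path]]  # factor -> {"ip","input"} -> path
    main_factor: str
    condition_a: str
    condition_b: str
    h3k27ac_factor: str
    cooccupancy_pairs: list[tuple[str, str]]
    cooccupancy_universe: str
    params: dict[str, Any]
    outdir: Path
    raw: dict = field(default_factory=dict)


def validate_config(
    path: str | Path,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> PipelineConfig:
    """Parse and validate a YAML pipeline config.

    Every referenced file is checked; missing files are reported together
    in one error. Parameters outside their documented ranges are rejected.
    ``seed`` and ``outdir`` are the only command-line overrides.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    missing: list[str] = []

    def checked(p: Path) -> Path:
        if not p.exists():
            missing.append(str(p))
        return p

    tss_cfg = raw.get("tss") or {}
    tss_path = checked(resolve(tss_cfg.get("path", "tss.tsv")))
    tss_format = tss_cfg.get("format", "tsv")
    if tss_format not in ("tsv", "gtf"):
        raise ConfigError(f"tss.format must be tsv or gtf, got {tss_format!r}")

    peak_paths: dict[str, dict[str, Path]] = {}
    for factor, conds in (raw.get("peaks") or {}).items():
        peak_paths[factor] = {
            cond: checked(resolve(p)) for cond, p in conds.items()
        }
    coverage_paths: dict[str, dict[str, Path]] = {}
    for factor, pair in (raw.get("coverage") or {}).items():
        coverage_paths[factor] = {
            role: checked(resolve(p)) for role, p in pair.items()
        }
        for role in ("ip", "input"):
            if role not in coverage_paths[factor]:
                raise ConfigError(f"coverage.{factor} missing {role!r} path")

    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params") or {})
    if seed is not None:
        params["seed"] = seed
    for key, value in params.items():
        if key not in PARAM_RANGES:
            raise ConfigError(f"unknown parameter {key!r}")
        lo, hi = PARAM_RANGES[key]
        if not (lo <= value <= hi):
            raise ConfigError(f"parameter {key}={value} outside [{lo}, {hi}]")
    if params["window_size"] % params["bin_size"] != 0:
        raise ConfigError("window_size must be divisible by bin_size")

    main_factor = raw.get("main_factor", "jmjd2c")
    condition_a = raw.get("condition_a", "naive")
    condition_b = raw.get("condition_b", "primed")
    if main_factor not in peak_paths:
        raise ConfigError(f"no peak files for main factor {main_factor!r}")
    for cond in (condition_a, condition_b):
        if cond not in peak_paths[main_factor]:
            raise ConfigError(
                f"main factor {main_factor!r} has no peaks for condition {cond!r}"
            )

    universe = raw.get("cooccupancy_universe", "distal_high")
    if universe not in UNIVERSE_CHOICES:
        raise ConfigError(
            f"cooccupancy_universe must be one of {UNIVERSE_CHOICES}"
        )
    pairs = [tuple(p) for p in (raw.get("cooccupancy_pairs") or [])]
    for pair in pairs:
        if len(pair) != 2:
            raise ConfigError(f"co-occupancy pair must have 2 labels: {pair}")

    if missing:
        raise ConfigError("missing input files:\n  " + "\n  ".join(missing))

    out = Path(outdir) if outdir is not None else resolve(raw.get("outdir", "out"))
    return PipelineConfig(
        tss_path=tss_path,
        tss_format=tss_format,
        peak_paths=peak_paths,
        coverage_paths=coverage_paths,
        main_factor=main_factor,
        condition_a=condition_a,
        condition_b=condition_b,
        h3k27ac_factor=raw.get("h3k27ac_factor", "h3k27ac"),
        cooccupancy_pairs=pairs,
        cooccupancy_universe=universe,
        params=params,
        outdir=out,
        raw=raw,
    )


@dataclass
class RunReport:
    version: str
    config_snapshot: dict
    stages: dict[str, dict]
    timings: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config_snapshot,
            "stages": self.stages,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _write_matrix_tsv(matrix, path: Path) -> None:
    df = pd.DataFrame(matrix.values, columns=[f"bin{j}" for j in range(matrix.n_bins)])
    df.insert(0, "peak_id", matrix.peak_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_profile_tsv(matrix, path: Path) -> None:
    prof = average_profile(matrix)
    pd.DataFrame(
        {"offset_bp": matrix.bin_offsets, "mean_signal": prof}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _render_heatmap(matrix, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_prof, ax_heat) = plt.subplots(
        2, 1, figsize=(4, 7), height_ratios=[1, 4], constrained_layout=True
    )
    ax_prof.plot(matrix.bin_offsets, average_profile(matrix))
    ax_prof.set_ylabel("mean signal")
    ax_prof.set_title(title)
    vals = matrix.values
    if vals.shape[0] > 2000:  # display cap only; tabular outputs keep all rows
        idx = np.linspace(0, vals.shape[0] - 1, 2000).astype(int)
        vals = vals[idx]
    ax_heat.imshow(
        vals,
        aspect="auto",
        interpolation="nearest",
        extent=[matrix.bin_offsets[0], matrix.bin_offsets[-1], vals.shape[0], 0],
        cmap="viridis",
    )
    ax_heat.set_xlabel("distance from peak centre (bp)")
    ax_heat.set_ylabel("peaks")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write all stage outputs under
    ``config.outdir``. Deterministic for fixed (config, seed) except the
    advisory PNG images and the timings file."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    stages: dict[str, dict] = {}
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, *exc):
                timings[name] = time.perf_counter() - self_inner.t0
                logger.info("stage %s: done (%.2fs)", name, timings[name])
                return False

        return _T()

    # ---- load inputs
    with timed("load"):
        tss = TSSIndex(read_tss(config.tss_path, format=config.tss_format))
        peaks: dict[str, dict[str, PeakSet]] = {}
        for factor, conds in config.peak_paths.items():
            peaks[factor] = {
                cond: read_bed(p, label=f"{factor}_{cond}")
                for cond, p in conds.items()
            }
        coverage: dict[str, dict[str, CoverageTrack]] = {}
        for factor, pair in config.coverage_paths.items():
            coverage[factor] = {
                role: read_bedgraph(p) for role, p in pair.items()
            }
    stages["load"] = {
        "n_peaks": {
            f: {c: len(ps) for c, ps in conds.items()}
            for f, conds in peaks.items()
        }
    }

    main = config.main_factor
    cond_a, cond_b = config.condition_a, config.condition_b
    peaks_a = peaks[main][cond_a]
    peaks_b = peaks[main][cond_b]

    # ---- classification
    with timed("classify"):
        cls = {}
        for cond, ps in ((cond_a, peaks_a), (cond_b, peaks_b)):
            c = classify_peaks(ps, tss, params["tss_threshold"])
            cls[cond] = c
            frame = classifications_to_frame(c)
            frame.to_csv(
                outdir / f"classify_{main}_{cond}.tsv", sep="\t", index=False
            )
    stages["classify"] = {
        cond: {
            "n": len(c),
            "n_tss_proximal": sum(x.klass == "tss_proximal" for x in c),
            "n_distal": sum(x.klass == "distal" for x in c),
            "frac_tss_proximal": (
                sum(x.klass == "tss_proximal" for x in c) / len(c) if c else 0.0
            ),
        }
        for cond, c in cls.items()
    }
    for cond, info in stages["classify"].items():
        logger.info(
            "%s/%s: %d peaks, %d TSS-proximal, %d distal",
            main, cond, info["n"], info["n_tss_proximal"], info["n_distal"],
        )

    # ---- condition comparison (B against A: the redistribution readout)
    with timed("compare"):
        comparison = compare_conditions(
            peaks_b, peaks_a, tss,
            min_overlap=params["min_overlap"],
            tss_threshold=params["tss_threshold"],
        )
        with open(outdir / "comparison.json", "wt") as fh:
            json.dump(comparison.summary(), fh, indent=2, sort_keys=True)
    stages["compare"] = comparison.summary()

    # ---- signal matrices over the condition-B main-factor peaks
    matrices = {}
    with timed("matrix"):
        for factor, pair in coverage.items():
            m = normalized_matrix(
                pair["ip"],
                pair["input"],
                peaks_b,
                window_size=params["window_size"],
                bin_size=params["bin_size"],
                pseudocount=params["pseudocount"],
                label=factor,
            )
            matrices[factor] = m
            _write_matrix_tsv(m, outdir / f"matrix_{factor}.tsv")
            _write_profile_tsv(m, outdir / f"profile_{factor}.tsv")
            _render_heatmap(m, outdir / f"heatmap_{factor}.png", factor)
        # Pearson correlation of per-peak occupancy between factors
        if len(coverage) >= 2:
            summaries = {
                factor: normalized_peak_summaries(
                    pair["ip"], pair["input"], peaks_b,
                    pseudocount=params["pseudocount"],
                )
                for factor, pair in coverage.items()
            }
            corr = correlation_matrix(summaries)
            pd.DataFrame(
                corr.values, index=corr.labels, columns=corr.labels
            ).to_csv(outdir / "correlation.tsv", sep="\t", float_format="%.6g")
    stages["matrix"] = {
        f: {"n_rows": len(m.peak_ids), "n_bins": m.n_bins}
        for f, m in matrices.items()
    }

    # ---- enhancer-state classification on condition-B distal peaks
    enhancers = None
    distal_idx = [
        i for i, c in enumerate(cls[cond_b]) if c.klass == "distal"
    ]
    ac = config.h3k27ac_factor
    with timed("enhancers"):
        if distal_idx and ac in coverage:
            distal = peaks_b.subset(distal_idx, label=f"{main}_{cond_b}_distal")
            enhancers = classify_enhancers(
                distal,
                coverage[ac]["ip"],
                coverage[ac]["input"],
                seed=params["seed"],
                pseudocount=params["pseudocount"],
            )
            pd.DataFrame(
                {
                    "peak_id": [l.peak_id for l in enhancers.labels],
                    "cluster": [l.cluster for l in enhancers.labels],
                    "h3k27ac_value": [l.h3k27ac_value for l in enhancers.labels],
                }
            ).to_csv(
                outdir / "enhancer_labels.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
            with open(outdir / "enhancer_summary.json", "wt") as fh:
                json.dump(enhancers.summary(), fh, indent=2, sort_keys=True)
            if ac in matrices:
                row_ids = set(distal.intervals[i].id for i in range(len(distal)))
                keep = [
                    i for i, pid in enumerate(matrices[ac].peak_ids)
                    if pid in row_ids
                ]
                sorted_m = sort_rows(matrices[ac].reordered(keep), enhancers.labels)
                _render_heatmap(
                    sorted_m, outdir / f"heatmap_{ac}_sorted.png", f"{ac} (sorted)"
                )
    stages["enhancers"] = enhancers.summary() if enhancers else {"skipped": True}

    # ---- co-occupancy over the configured universe
    with timed("cooccupancy"):
        coocc_rows = []
        if config.cooccupancy_pairs:
            universe = _build_universe(
                config, peaks_b, cls[cond_b], enhancers
            )
            factor_sets = {
                f: ps[cond_b]
                for f, ps in peaks.items()
                if cond_b in ps
            }
            results = pairwise_table(
                universe,
                factor_sets,
                config.cooccupancy_pairs,
                max_gap=params["max_gap"],
            )
            coocc_rows = [r.as_dict() for r in results]
            df = pd.DataFrame(coocc_rows)
            df.to_csv(
                outdir / "cooccupancy.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            with open(outdir / "cooccupancy.json", "wt") as fh:
                json.dump(
                    {
                        "universe": config.cooccupancy_universe,
                        "n_universe": len(universe),
                        "max_gap": params["max_gap"],
                        "results": coocc_rows,
                    },
                    fh, indent=2, sort_keys=True,
                )
    stages["cooccupancy"] = {
        "universe": config.cooccupancy_universe,
        "results": coocc_rows,
    }

    report = RunReport(
        version=__version__,
        config_snapshot={
            "params": params,
            "main_factor": main,
            "condition_a": cond_a,
            "condition_b": cond_b,
            "cooccupancy_universe": config.cooccupancy_universe,
            "cooccupancy_pairs": [list(p) for p in config.cooccupancy_pairs],
        },
        stages=stages,
        timings=timings,
    )
    with open(outdir / "report.json", "wt") as fh:
        fh.write(report.to_json())
    with open(outdir / "timings.json", "wt") as fh:
        json.dump(timings, fh, indent=2, sort_keys=True)
    return report


def _build_universe(config, peaks_b, classifications, enhancers) -> PeakSet:
    """Reference population for the hypergeometric test, per config: all
    distal main-factor peaks, or the H3K27ac-high / -low subset."""
    distal_idx = [
        i for i, c in enumerate(classifications) if c.klass == "distal"
    ]
    if config.cooccupancy_universe == "distal_all" or enhancers is None:
        return peaks_b.subset(distal_idx, label="universe_distal")
    want = "high" if config.cooccupancy_universe == "distal_high" else "low"
    by_id = {l.peak_id: l.cluster for l in enhancers.labels}
    keep = [
        i for i in distal_idx
        if by_id.get(peaks_b[i].id) == want
    ]
    return peaks_b.subset(keep, label=f"universe_distal_{want}")
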