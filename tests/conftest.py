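import numpy as np
import pytest

from chipscape import (
    CoverageTrack,
    GenomicInterval,
    PeakSet,
    SyntheticConfig,
    TSSIndex,
    TSSRecord,
)
from chipscape.simulate import write_fixture_bundle


def make_track(runs):
    """Build a CoverageTrack from {chrom: [(start, end, value), ...]}."""
    out = {}
    for chrom, triples in runs.items():
        triples = sorted(triples)
        out[chrom] = (
            np.array([t[0] for t in triples], dtype=np.int64),
            np.array([t[1] for t in triples], dtype=np.int64),
            np.array([t[2] for t in triples], dtype=np.float64),
        )
    return CoverageTrack(out)


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


@pytest.fixture
def tss_index():
    return TSSIndex(
        [
            TSSRecord("geneA", "chr1", 10_000, "+"),
            TSSRecord("geneB", "chr1", 50_000, "-"),
            TSSRecord("geneC", "chr2", 5_000, "+"),
        ]
    )


def small_synthetic_config(**overrides):
    """A fast, fully planted landscape for unit and pipeline tests."""
    defaults = dict(
        chrom_sizes={"chrA": 4_000_000, "chrB": 2_000_000},
        n_genes=60,
        n_peaks_a=200,
        n_peaks_b=700,
        seed=11,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    config = small_synthetic_config()
    manifest = write_fixture_bundle(outdir, config)
    return outdir, config, manifest


PIPELINE_YAML = """\
tss:
  path: {bundle}/tss.tsv
  format: tsv
peaks:
  jmjd2c:
    naive: {bundle}/jmjd2c_naive.bed
    primed: {bundle}/jmjd2c_primed.bed
  med1:
    primed: {bundle}/med1_primed.bed
  p300:
    primed: {bundle}/p300_primed.bed
  oct4:
    primed: {bundle}/oct4_primed.bed
  smc1a:
    primed: {bundle}/smc1a_primed.bed
coverage:
  jmjd2c:
    ip: {bundle}/jmjd2c_ip.bedgraph
    input: {bundle}/jmjd2c_input.bedgraph
  h3k27ac:
    ip: {bundle}/h3k27ac_ip.bedgraph
    input: {bundle}/h3k27ac_input.bedgraph
main_factor: jmjd2c
condition_a: naive
condition_b: primed
h3k27ac_factor: h3k27ac
cooccupancy_universe: distal_high
cooccupancy_pairs:
  - [med1, p300]
  - [med1, oct4]
  - [med1, smc1a]
params:
  seed: {seed}
outdir: {outdir}
"""


def write_pipeline_yaml(path, bundle_dir, outdir, seed=11):
    path.write_text(
        PIPELINE_YAML.format(bundle=bundle_dir, outdir=outdir, seed=seed)
    )
    return path
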