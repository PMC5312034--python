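"""Depth adjustment, input normalisation, signal matrices, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipscape import (
    PeakSet,
    average_profile,
    compute_matrix,
    correlation_matrix,
    depth_adjust,
    input_normalize,
    peak_summary,
)
from conftest import iv, make_track


class TestDepthAdjust:
    def test_scales_to_counts_per_million(self):
        t = make_track({"chr1": [(0, 500_000, 4.0)]})  # total 2e6
        adj = depth_adjust(t)
        assert adj.runs["chr1"][2][0] == pytest.approx(2.0)
        assert adj.total_signal == pytest.approx(1e6, rel=1e-9)

    def test_identity_and_idempotence(self):
        t = make_track({"chr1": [(0, 1000, 1000.0)]})  # total 1e6 already
        adj = depth_adjust(t)
        assert adj.runs["chr1"][2][0] == pytest.approx(1000.0)
        twice = depth_adjust(depth_adjust(make_track({"chr1": [(0, 10, 7.0)]})))
        assert twice.total_signal == pytest.approx(1e6, rel=1e-9)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            depth_adjust(make_track({}))


class TestInputNormalize:
    def test_examples(self):
        assert input_normalize(8, 2, 1.0) == pytest.approx(np.log2(3))
        assert input_normalize(5.5, 5.5) == 0.0
        assert input_normalize(0, 0) == 0.0

    def test_pseudocount_validation(self):
        with pytest.raises(ValueError):
            input_normalize(1, 1, pseudocount=0)
        with pytest.raises(ValueError):
            input_normalize(-1, 1)

    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_zero_on_diagonal(self, a, b):
        assert input_normalize(a, a) == 0.0
        assert input_normalize(a, b) == pytest.approx(-input_normalize(b, a))


class TestComputeMatrix:
    def test_constant_field(self):
        t = make_track({"chr1": [(0, 200_000, 2.0)]})
        peaks = PeakSet("p", [iv(90_000, 91_000)])
        m = compute_matrix(t, peaks, window_size=10_000, bin_size=50)
        assert m.values.shape == (1, 200)
        assert np.allclose(m.values, 2.0)

    def test_single_run_against_bin_grid(self):
        # run [4975,5025)=10 centred on the anchor: exactly the two central
        # bins [4950,5000) and [5000,5050) each catch 25 bp of signal -> 5.0
        t = make_track({"chr1": [(4975, 5025, 10.0)]})
        peaks = PeakSet("p", [iv(4500, 5500)])  # midpoint anchor 5000
        m = compute_matrix(t, peaks, window_size=10_000, bin_size=50)
        row = m.values[0]
        assert row[99] == pytest.approx(5.0)
        assert row[100] == pytest.approx(5.0)
        assert np.count_nonzero(row) == 2

    def test_window_clipped_at_chromosome_start(self):
        t = make_track({"chr1": [(0, 1_000, 3.0)]})
        peaks = PeakSet("p", [iv(50, 150)])  # anchor 100, window [-4900, 5100)
        m = compute_matrix(t, peaks, window_size=10_000, bin_size=100)
        assert 0 in m.clipped_rows
        # bins before position 0 see only zeros
        assert np.allclose(m.values[0, :49], 0.0)
        # bin covering [0,100) sits at index 49 with value 3
        assert m.values[0, 49] == pytest.approx(3.0)

    def test_divisibility_enforced(self):
        t = make_track({"chr1": [(0, 100, 1.0)]})
        with pytest.raises(ValueError):
            compute_matrix(t, PeakSet("p", [iv(0, 10)]), 10_000, 33)

    def test_mass_conservation(self):
        # track fully inside the window: bin sums * bin_size = track integral
        t = make_track({"chr1": [(98_000, 99_000, 4.0), (99_500, 100_700, 1.5)]})
        peaks = PeakSet("p", [iv(99_000, 100_000)])  # anchor 99500
        m = compute_matrix(t, peaks, window_size=10_000, bin_size=50)
        assert m.values[0].sum() * 50 == pytest.approx(t.total_signal, rel=1e-6)

    def test_shift_covariance(self):
        # shift-covariant signal: shifting anchors by +k bins shifts rows
        rng = np.random.default_rng(5)
        vals = rng.poisson(3, 400).astype(float)
        t1 = make_track(
            {"chr1": [(50_000 + 50 * i, 50_000 + 50 * (i + 1), v) for i, v in enumerate(vals)]}
        )
        shift = 150  # 3 bins
        t2 = make_track(
            {"chr1": [(50_000 + shift + 50 * i, 50_000 + shift + 50 * (i + 1), v) for i, v in enumerate(vals)]}
        )
        peaks = PeakSet("p", [iv(59_500, 60_500)])
        m1 = compute_matrix(t1, peaks, 10_000, 50)
        m2 = compute_matrix(t2, peaks, 10_000, 50)
        # track shifted +150 bp = +3 bins: row shifts right by 3 columns
        assert np.allclose(m2.values[0, 3:], m1.values[0, :-3])


class TestProfilesAndSummaries:
    def test_average_profile_examples(self):
        t = make_track({"chr1": [(0, 200_000, 1.5)]})
        peaks = PeakSet("p", [iv(90_000, 91_000), iv(100_000, 101_000)])
        m = compute_matrix(t, peaks, 10_000, 50)
        assert np.allclose(average_profile(m), m.values[0])
        m.values = np.vstack([np.zeros(200), np.full(200, 2.0)])
        assert np.allclose(average_profile(m), 1.0)

    def test_average_profile_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        t = make_track({"chr1": [(0, 200_000, 1.0)]})
        m = compute_matrix(t, PeakSet("p", [iv(90_000, 91_000)]), 10_000, 50)
        m.values = rng.normal(size=(17, 200))
        oracle = np.array(
            [sum(m.values[i][j] for i in range(17)) / 17 for j in range(200)]
        )
        assert np.allclose(average_profile(m), oracle)

    def test_peak_summary_examples(self):
        t = make_track({"chr1": [(0, 100, 3.0)]})
        assert peak_summary(t, iv(0, 100)) == pytest.approx(3.0)
        t2 = make_track({"chr1": [(0, 50, 2.0), (50, 100, 4.0)]})
        assert peak_summary(t2, iv(0, 100)) == pytest.approx(3.0)
        assert peak_summary(t2, iv(500, 600)) == 0.0  # all-gap region


class TestCorrelationMatrix:
    def test_identity_and_antisymmetry(self):
        v = np.array([1.0, 2.0, 5.0, 3.0, 0.5])
        cm = correlation_matrix({"a": v, "b": v, "c": -v})
        i, j, k = (cm.labels.index(x) for x in ("a", "b", "c"))
        assert cm.values[i, j] == pytest.approx(1.0)
        assert cm.values[i, k] == pytest.approx(-1.0)
        assert np.allclose(cm.values, cm.values.T, equal_nan=True)

    def test_hand_oracle_five_elements(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # textbook formula by hand
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        cm = correlation_matrix({"x": x, "y": y})
        assert cm.values[0, 1] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_flagged_missing(self):
        cm = correlation_matrix(
            {"flat": np.ones(5), "var": np.arange(5.0)}
        )
        i = cm.labels.index("flat")
        assert np.isnan(cm.values[i]).all()
        assert cm.values[1 - i, 1 - i] == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            correlation_matrix({"a": np.ones(5)})
        with pytest.raises(ValueError):
            correlation_matrix({"a": np.ones(5), "b": np.ones(4)})
        with pytest.raises(ValueError):
            correlation_matrix({"a": np.ones(2), "b": np.ones(2)})

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(12)
        data = {f"f{i}": rng.normal(size=50) for i in range(6)}
        cm = correlation_matrix(data)
        eigvals = np.linalg.eigvalsh(cm.values)
        assert eigvals.min() >= -1e-10
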