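"""Intensity binning, reporting-bin selection, per-minute aggregation, LOESS, onset."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluotrack as ft
from fluotrack.fluorescence import DEFAULT_BIN_EDGES, ChannelHistogram


def component_on_frame(levels, rng=None):
    """A frame plus a component whose green pixels take the given levels."""
    n = len(levels)
    side = int(np.ceil(np.sqrt(n)))
    frame = np.zeros((side + 2, side + 2, 3), dtype=np.uint8)
    coords = []
    for i, lv in enumerate(levels):
        r, c = divmod(i, side)
        frame[r, c, 1] = lv
        coords.append((r, c))
    return frame, ft.Component(np.array(coords))


def hist_from_counts(counts, channel="green"):
    """A histogram with given counts; sums placed at each bin's lower edge."""
    counts = np.asarray(counts)
    sums = counts * np.array([0, 64, 128, 192])
    return ChannelHistogram(channel=channel, counts=counts, intensity_sums=sums)


class TestBinning:
    def test_all_zero_pixels_fill_bin1(self):
        frame, comp = component_on_frame([0] * 6)
        h = ft.bin_component_intensities(frame, comp)
        np.testing.assert_array_equal(h.counts, [6, 0, 0, 0])
        np.testing.assert_array_equal(h.intensity_sums, [0, 0, 0, 0])

    def test_one_pixel_per_bin(self):
        frame, comp = component_on_frame([10, 70, 130, 200])
        h = ft.bin_component_intensities(frame, comp)
        np.testing.assert_array_equal(h.counts, [1, 1, 1, 1])
        np.testing.assert_array_equal(h.intensity_sums, [10, 70, 130, 200])

    @pytest.mark.parametrize("level,bin_idx", [(63, 0), (64, 1), (127, 1), (128, 2), (191, 2), (192, 3), (255, 3)])
    def test_edge_levels_assigned_to_correct_bin(self, level, bin_idx):
        frame, comp = component_on_frame([level])
        h = ft.bin_component_intensities(frame, comp)
        assert h.counts[bin_idx] == 1 and h.counts.sum() == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 255), min_size=1, max_size=40))
    def test_partition_identities(self, levels):
        frame, comp = component_on_frame(levels)
        h = ft.bin_component_intensities(frame, comp)
        assert h.counts.sum() == comp.size
        assert h.intensity_sums.sum() == sum(levels)
        edges = DEFAULT_BIN_EDGES
        for k in range(4):
            assert h.intensity_sums[k] >= h.counts[k] * edges[k]
            assert h.intensity_sums[k] <= h.counts[k] * (edges[k + 1] - 1)

    def test_out_of_bounds_pixel_errors(self):
        frame = np.zeros((4, 4, 3), dtype=np.uint8)
        comp = ft.Component(np.array([[5, 1]]))
        with pytest.raises(ValueError):
            ft.bin_component_intensities(frame, comp)

    def test_dim_component_reads_zero_in_high_bins(self):
        # all pixels below 64: any top-anchored set down to G2 reads exactly 0
        frame, comp = component_on_frame([5, 20, 40, 63])
        h = ft.bin_component_intensities(frame, comp)
        assert h.sum_over_bins((4,)) == 0
        assert h.sum_over_bins((4, 3)) == 0
        assert h.sum_over_bins((4, 3, 2)) == 0
        assert h.sum_over_bins((4, 3, 2, 1)) == 128


class TestReportingBinSelection:
    def test_all_samples_populate_bin4(self):
        hists = [hist_from_counts([5, 0, 0, 3]), hist_from_counts([2, 1, 0, 7])]
        assert ft.select_reporting_bin(hists) == (4,)

    def test_extends_to_bin3_when_one_sample_lacks_bin4(self):
        hists = [hist_from_counts([5, 0, 2, 0]), hist_from_counts([2, 1, 0, 7])]
        assert ft.select_reporting_bin(hists) == (4, 3)

    def test_full_extension_for_bin1_only_samples(self):
        hists = [hist_from_counts([5, 0, 0, 0]), hist_from_counts([3, 0, 0, 0])]
        assert ft.select_reporting_bin(hists) == (4, 3, 2, 1)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ft.select_reporting_bin([hist_from_counts([0, 0, 0, 0])])

    def test_mixed_channels_rejected(self):
        with pytest.raises(ValueError):
            ft.select_reporting_bin(
                [hist_from_counts([1, 0, 0, 1], "red"), hist_from_counts([1, 0, 0, 1])]
            )


class TestPerMinuteAggregation:
    def test_constant_series(self):
        out = ft.aggregate_per_minute(np.full(120, 7.0), frame_rate=1.0)
        np.testing.assert_allclose(out, [7.0, 7.0])

    def test_linear_ramp_block_means(self):
        # two exact minutes at 2 fps: blocks of 120 frames; closed-form means
        values = np.arange(240, dtype=float)
        out = ft.aggregate_per_minute(values, frame_rate=2.0)
        np.testing.assert_allclose(out, [np.mean(np.arange(120)), np.mean(np.arange(120, 240))])

    def test_trailing_partial_minute(self):
        # 90 s at 30 fps -> one full minute and one partial
        values = np.concatenate([np.zeros(1800), np.ones(900)])
        out = ft.aggregate_per_minute(values, frame_rate=30.0)
        assert len(out) == 2
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_skip_missing_ignores_nan(self):
        values = np.array([1.0, np.nan, 3.0, np.nan])
        out = ft.aggregate_per_minute(values, frame_rate=2 / 60, skip_missing=True)
        np.testing.assert_allclose(out, [1.0, 3.0])

    def test_empty_series(self):
        assert len(ft.aggregate_per_minute(np.array([]), 30.0)) == 0


class TestLoess:
    def loess_oracle(self, y, span, degree):
        """Independent per-point tricube WLS via explicit normal equations."""
        n = len(y)
        x = np.arange(n, dtype=float)
        k = max(int(np.ceil(span * n)), degree + 2)
        out = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            order = np.argsort(d, kind="stable")[:k]
            dmax = d[order].max()
            if dmax == 0:
                out[i] = y[order].mean()
                continue
            w = (1 - (d[order] / dmax) ** 3) ** 3
            if np.count_nonzero(w) <= degree:
                w = w + 1e-9
            X = np.vander(x[order] - x[i], degree + 1, increasing=True)
            WX = X * w[:, None]
            beta = np.linalg.solve(X.T @ WX, WX.T @ y[order])
            out[i] = beta[0]
        return out

    def test_constant_series_unchanged(self):
        y = np.full(50, 3.3)
        np.testing.assert_allclose(ft.loess_smooth(y), y, atol=1e-10)

    def test_exact_on_quadratic(self):
        x = np.arange(60, dtype=float)
        y = 0.5 * x**2 - 3 * x + 2
        np.testing.assert_allclose(ft.loess_smooth(y, span=0.2, degree=2), y, atol=1e-8)

    def test_degree1_not_exact_on_quadratic(self):
        x = np.arange(60, dtype=float)
        y = 0.5 * x**2
        sm = ft.loess_smooth(y, span=0.3, degree=1)
        assert np.abs(sm - y).max() > 1e-3

    def test_matches_wls_oracle_random(self, rng):
        y = rng.normal(size=200)
        got = ft.loess_smooth(y, span=0.1, degree=2)
        np.testing.assert_allclose(got, self.loess_oracle(y, 0.1, 2), atol=1e-6)

    def test_matches_statsmodels_at_degree_one(self, rng):
        # statsmodels lowess fits local lines with the same tricube weights
        from statsmodels.nonparametric.smoothers_lowess import lowess

        y = rng.normal(size=120).cumsum()
        x = np.arange(120, dtype=float)
        span = 0.3
        ours = ft.loess_smooth(y, span=span, degree=1)
        theirs = lowess(y, x, frac=span, it=0, return_sorted=False)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_too_short_series_errors_with_minimum(self):
        with pytest.raises(ValueError, match="4"):
            ft.loess_smooth(np.array([1.0, 2.0, 3.0]), degree=2)


class TestOnsetDetection:
    def test_flat_series_has_no_onset(self):
        assert ft.detect_onset(np.full(200, 5.0), baseline_minutes=30) is None

    def test_step_function_onset_within_smoothing_lag(self):
        y = np.zeros(300)
        y[100:] = 10.0
        smooth = ft.loess_smooth(y, span=0.1, degree=2)
        onset = ft.detect_onset(smooth, baseline_minutes=50, k=3.0)
        assert onset is not None
        assert abs(onset - 100) <= int(np.ceil(0.1 * len(y)))  # within span width

    def test_sigmoid_rise_recovered(self):
        rng = np.random.default_rng(3)
        t = np.arange(400, dtype=float)
        rise = 250.0
        y = 100.0 / (1 + np.exp(-(t - rise) / 4.0)) + rng.normal(0, 1.0, t.size)
        smooth = ft.loess_smooth(y, span=0.1, degree=2)
        # smoothed noise is autocorrelated over the LOESS window, so the
        # sustained-excursion detector needs a conservative multiplier
        onset = ft.detect_onset(smooth, baseline_minutes=100, k=5.0)
        assert onset is not None
        assert abs(onset - rise) <= 0.1 * len(y)

    def test_baseline_window_must_fit(self):
        with pytest.raises(ValueError):
            ft.detect_onset(np.zeros(10), baseline_minutes=10)


class TestSeriesBundle:
    def test_build_fluorescence_series_shapes(self, rng):
        per_frame = rng.random(360)  # 6 minutes at 1 fps
        fs = ft.build_fluorescence_series(per_frame, frame_rate=1.0, span=1.0)
        assert len(fs.per_minute) == 6
        assert len(fs.smoothed) == 6
        assert fs.minutes.tolist() == [0, 1, 2, 3, 4, 5]
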