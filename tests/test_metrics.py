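"""Asymmetry index, growth curves, and replicate summaries."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from chemograd import (
    ChannelROI,
    ImageStack,
    InvalidParameterError,
    asymmetry_index,
    asymmetry_series,
    growth_curves,
    make_scenario,
    saturation_value,
    simulate_replicate,
    summarize_endpoint,
)
from chemograd.metrics import AsymmetrySeries

nonneg_frames = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(st.integers(2, 10), st.integers(2, 12)),
    elements=st.floats(0, 1e6, allow_nan=False),
)


def _stack(frames, interval=5.0):
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size_um=1.0,
        frame_interval_min=interval,
    )


class TestAsymmetryIndex:
    def test_uniform_frame_is_balanced(self):
        a, il, ir = asymmetry_index(np.full((4, 8), 3.0))
        assert a == 0.0
        assert il == ir == 3.0

    def test_all_signal_left_hits_upper_bound(self):
        frame = np.zeros((4, 8))
        frame[:, :4] = 5.0
        a, _, _ = asymmetry_index(frame)
        assert a == 1.0

    def test_three_to_one_ratio(self):
        frame = np.zeros((2, 8))
        frame[:, :4] = 3.0
        frame[:, 4:] = 1.0
        a, _, _ = asymmetry_index(frame)
        assert a == pytest.approx(0.5)

    def test_zero_frame_is_flagged_undefined(self):
        a, il, ir = asymmetry_index(np.zeros((4, 8)))
        assert math.isnan(a)
        assert il == ir == 0.0

    def test_odd_width_excludes_middle_column(self):
        frame = np.zeros((2, 5))
        frame[:, 2] = 1e6  # middle column must not count
        frame[:, 0:2] = 1.0
        frame[:, 3:5] = 1.0
        a, _, _ = asymmetry_index(frame)
        assert a == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(frame=nonneg_frames)
    def test_bounded_and_mirror_antisymmetric(self, frame):
        a, il, ir = asymmetry_index(frame)
        a_mirror, _, _ = asymmetry_index(frame[:, ::-1])
        if math.isnan(a):
            assert il + ir == 0.0
            assert math.isnan(a_mirror)
        else:
            assert -1.0 <= a <= 1.0
            assert a_mirror == pytest.approx(-a, abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(frame=nonneg_frames, scale=st.floats(1e-3, 1e3))
    def test_invariant_under_global_scaling(self, frame, scale):
        a, _, _ = asymmetry_index(frame)
        a_scaled, _, _ = asymmetry_index(scale * frame)
        if not math.isnan(a):
            assert a_scaled == pytest.approx(a, abs=1e-9)


class TestAsymmetrySeries:
    def test_identical_frames_give_constant_series(self, rng):
        frame = rng.random((6, 10))
        series = asymmetry_series(_stack([frame] * 5))
        assert np.allclose(series.A, series.A[0])
        assert np.allclose(series.time_min, [0, 5, 10, 15, 20])

    def test_empty_stack_rejected(self):
        with pytest.raises(InvalidParameterError):
            asymmetry_series(
                ImageStack(
                    frames=np.zeros((0, 4, 4)),
                    pixel_size_um=1.0,
                    frame_interval_min=5.0,
                )
            )

    def test_algae_asymmetry_rises_over_first_hours(self):
        """The calibrated gradient scenario drifts leftward: A computed
        straight from the density field is non-decreasing (averaged over
        30-min windows) across the first 4 h, and the centroid moves left."""
        spec = make_scenario("algae")
        _, dens, _ = simulate_replicate(spec, seed=11)
        # build two-row pseudo-frames from the density profile directly
        a_vals = np.array(
            [asymmetry_index(np.tile(row, (2, 1)))[0] for row in dens.b]
        )
        first4h = a_vals[dens.times <= 4 * 3600]
        coarse = first4h[: len(first4h) // 6 * 6].reshape(-1, 6).mean(axis=1)
        assert np.all(np.diff(coarse) > -1e-6)
        centroids = dens.centroid()
        assert centroids[-1] < centroids[0]


class TestGrowthCurves:
    def test_static_noise_free_stack_gives_constant_curves(self, noise_free_imaging, rng):
        frame = rng.random((6, 10)) * 100
        curves = growth_curves(_stack([frame] * 4))
        assert np.allclose(curves.mean_left, curves.mean_left[0])
        assert np.allclose(curves.mean_right, curves.mean_right[0])

    def test_exponential_growth_slope_recovered(self):
        """log(mean intensity) vs time is linear with slope r for a
        uniformly growing population rendered noise-free with zero offset."""
        r_per_h = 0.3
        times_min = np.arange(0, 6 * 60 + 1, 30.0)
        frames = [
            np.full((4, 8), 10.0 * np.exp(r_per_h * t / 60.0)) for t in times_min
        ]
        curves = growth_curves(_stack(frames, interval=30.0))
        slope = np.polyfit(curves.time_min / 60.0, np.log(curves.mean_left), 1)[0]
        assert slope == pytest.approx(r_per_h, rel=0.02)

    def test_drift_only_conserves_total_intensity(self):
        """With r0 = 0 the sum of half-channel means is constant: intensity
        only moves between halves (continuum rendering, no noise)."""
        spec = make_scenario("algae")
        imaging = dataclasses.replace(
            spec.imaging,
            mode="continuum",
            background_level=0.0,
            noise_model=dataclasses.replace(spec.imaging.noise_model, shot=False, read_sigma=0.0),
            background_inhomogeneity=dataclasses.replace(
                spec.imaging.background_inhomogeneity, amplitude=0.0
            ),
            duration_h=3.0,
        )
        pop = dataclasses.replace(spec.population, r0=0.0, growth_law="none")
        spec = dataclasses.replace(spec, imaging=imaging, population=pop)
        _, _, stack = simulate_replicate(spec, seed=5)
        curves = growth_curves(stack)
        total = curves.mean_left + curves.mean_right
        assert np.max(np.abs(total - total[0])) / total[0] < 0.01


class TestEndpointSummary:
    @staticmethod
    def _series(values):
        t = np.array([0.0, 540.0])
        return [
            AsymmetrySeries(
                time_min=t,
                A=np.array([0.0, v]),
                I_left=np.ones(2),
                I_right=np.ones(2),
            )
            for v in values
        ]

    def test_identical_replicates(self):
        s = summarize_endpoint(self._series([0.5, 0.5, 0.5]), 540.0)
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(0.0)

    def test_two_replicates_sample_sd(self):
        s = summarize_endpoint(self._series([0.4, 0.8]), 540.0)
        assert s.mean == pytest.approx(0.6)
        assert s.sd == pytest.approx(0.28284, abs=1e-4)

    def test_single_replicate_sd_undefined(self):
        s = summarize_endpoint(self._series([0.7]), 540.0)
        assert s.mean == pytest.approx(0.7)
        assert math.isnan(s.sd)

    def test_mirrored_replicates_negate_mean_keep_sd(self):
        fwd = summarize_endpoint(self._series([0.4, 0.8, 0.1]), 540.0)
        rev = summarize_endpoint(self._series([-0.4, -0.8, -0.1]), 540.0)
        assert rev.mean == pytest.approx(-fwd.mean)
        assert rev.sd == pytest.approx(fwd.sd)

    def test_endpoint_beyond_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            summarize_endpoint(self._series([0.5]), 1000.0)


class TestSaturation:
    def test_constant_series(self):
        t = np.arange(0, 121, 5.0)
        series = AsymmetrySeries(
            time_min=t, A=np.full(t.size, 0.55), I_left=np.ones(t.size), I_right=np.ones(t.size)
        )
        assert saturation_value(series, 60.0) == pytest.approx(0.55)

    def test_window_covering_last_two_frames(self):
        t = np.arange(0, 31, 5.0)
        a = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 0.6])
        series = AsymmetrySeries(
            time_min=t, A=a, I_left=np.ones(t.size), I_right=np.ones(t.size)
        )
        assert saturation_value(series, 5.0) == pytest.approx(0.55)

    def test_window_exceeding_series_rejected(self):
        t = np.arange(0, 31, 5.0)
        series = AsymmetrySeries(
            time_min=t, A=np.zeros(t.size), I_left=np.ones(t.size), I_right=np.ones(t.size)
        )
        with pytest.raises(InvalidParameterError):
            saturation_value(series, 60.0)
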