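"""Blink repair, recursive filtering, gaze merging, smoothing, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gazecog as gc
from gazecog.preprocess import FilterSpec, channel_stats


def direct_difference_loop(x, b, a):
    """Independent direct-form evaluation of the causal recursion."""
    y = np.zeros_like(x, dtype=float)
    for n in range(len(x)):
        acc = 0.0
        for i, bi in enumerate(b):
            if n - i >= 0:
                acc += bi * x[n - i]
        for j, aj in enumerate(a[1:], start=1):
            if n - j >= 0:
                acc -= aj * y[n - j]
        y[n] = acc / a[0]
    return y


class TestDetectBlinks:
    def test_fully_open_eyes_no_blinks(self):
        mask = gc.detect_blinks(np.ones(50), np.ones(50))
        assert not mask.any()

    def test_dip_marks_exact_span(self):
        ol = np.ones(30)
        ol[10:15] = 0.5
        mask = gc.detect_blinks(ol, np.ones(30), tau=0.9)
        assert mask[10:15].all() and mask.sum() == 5

    def test_either_eye_below_threshold_triggers(self):
        mask = gc.detect_blinks(np.array([0.95]), np.array([0.85]), tau=0.9)
        assert mask[0]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gc.detect_blinks(np.array([]), np.array([]))


class TestInterpolateGaps:
    def test_midpoint_fill(self):
        out = gc.interpolate_gaps(np.array([1.0, np.nan, 3.0]),
                                  np.array([False, True, False]))
        np.testing.assert_allclose(out, [1, 2, 3])

    def test_no_gaps_identity(self):
        x = np.array([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(
            gc.interpolate_gaps(x, np.zeros(3, dtype=bool)), x)

    def test_leading_gap_holds_first_valid(self):
        out = gc.interpolate_gaps(np.array([np.nan, np.nan, 5.0, 7.0]),
                                  np.array([True, True, False, False]))
        np.testing.assert_allclose(out, [5, 5, 5, 7])

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError):
            gc.interpolate_gaps(np.ones(4), np.ones(4, dtype=bool))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_unmasked_samples_never_modified(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        mask = rng.random(40) < 0.3
        mask[0] = False  # keep at least one anchor
        out = gc.interpolate_gaps(x, mask)
        np.testing.assert_array_equal(out[~mask], x[~mask])


class TestButterworth:
    def test_matches_direct_difference_loop(self):
        spec = FilterSpec.butterworth()
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        b = np.asarray(spec.h) / spec.omega
        a = np.concatenate([[1.0], spec.g])
        np.testing.assert_allclose(gc.butterworth_smooth(x, spec),
                                   direct_difference_loop(x, b, a),
                                   atol=1e-10)

    def test_unity_dc_gain_on_constant(self):
        y = gc.butterworth_smooth(np.full(400, 3.7))
        np.testing.assert_allclose(y[100:], 3.7, atol=1e-6)

    def test_nyquist_attenuation(self):
        x = np.resize([1.0, -1.0], 600)
        y = gc.butterworth_smooth(x)
        assert np.abs(y[200:]).max() < np.abs(x).max() / 20

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            gc.butterworth_smooth(np.array([1.0, np.nan, 2.0, 3.0]))

    def test_repeated_filtering_nearly_idempotent_in_passband(self):
        # a slow passband oscillation keeps its amplitude through a second
        # pass (the causal recursion adds phase delay but no attenuation)
        t = np.arange(1200) / 120.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y1 = gc.butterworth_smooth(x)
        y2 = gc.butterworth_smooth(y1)
        a1 = np.sqrt(np.mean(y1[400:] ** 2))
        a2 = np.sqrt(np.mean(y2[400:] ** 2))
        assert a2 / a1 == pytest.approx(1.0, abs=2e-3)


class TestMergeGaze:
    def test_stationary_endpoint_zero_velocity(self):
        from conftest import make_recording
        rec = make_recording(n=120)
        mg = gc.merge_gaze(rec)
        np.testing.assert_allclose(mg.angular_velocity, 0.0, atol=1e-9)

    def test_cyclopean_origin_is_midpoint(self):
        from conftest import make_recording
        rec = make_recording(n=10)
        mg = gc.merge_gaze(rec)
        np.testing.assert_allclose(mg.cyclopean_origin, 0.0, atol=1e-12)

    def test_one_degree_per_sample_gives_120_dps(self):
        from conftest import make_recording
        n = 60
        ang = np.radians(np.arange(n) * 1.0)
        gaze = np.column_stack([1.5 * np.sin(ang), np.zeros(n),
                                1.5 * np.cos(ang)])
        rec = make_recording(n=n, gaze=gaze)
        rec.eye_origin_left[:] = [-0.0, 0, 0]
        rec.eye_origin_right[:] = [0.0, 0, 0]
        mg = gc.merge_gaze(rec)
        np.testing.assert_allclose(mg.angular_velocity[1:-1], 120.0,
                                   rtol=1e-6)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        out = gc.gaussian_smooth(np.full((100, 6), 0.5), sigma=2.0)
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_impulse_response_is_kernel(self):
        x = np.zeros(81)
        x[40] = 1.0
        out = gc.gaussian_smooth(x, sigma=2.0)
        k = np.arange(-8, 9)
        kernel = np.exp(-k ** 2 / (2 * 2.0 ** 2))
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[32:49], kernel, atol=1e-8)

    def test_variance_never_increases(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(300, 6))
        assert gc.gaussian_smooth(x).var(axis=0).max() <= x.var(axis=0).max()


class TestZScore:
    def test_channel_equal_to_mean_gives_zeros(self):
        X = np.full((3, 50), 2.0)
        np.testing.assert_allclose(gc.zscore_channels(X), 0.0)

    def test_self_standardization(self):
        rng = np.random.default_rng(8)
        X = rng.normal(3, 2, size=(4, 500))
        Z = gc.zscore_channels(X)
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=1), 1.0, atol=1e-12)

    def test_train_stats_on_shifted_copy(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(2, 400))
        stats = channel_stats([X])
        shift = 1.5
        Z = gc.zscore_channels(X + shift, stats)
        np.testing.assert_allclose(Z.mean(axis=1), shift / stats[1],
                                   atol=1e-10)
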