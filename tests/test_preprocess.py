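import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from esngait.preprocess import (
    PreprocessConfig,
    build_input,
    highpass_bidirectional,
    integrate_cumulative,
    range_normalize,
    reorient_pca,
    resample_grf,
    segment_at_foot_off,
    zscore_signal,
)
from esngait.signal_io import ACCEL_FS, GaitEventSeries, SampledSignal


def _sig(values, fs):
    return SampledSignal(np.asarray(values, dtype=float), fs=fs)


class TestResample:
    def test_dc_preserved(self):
        s = _sig(np.full((1, 7000), 500.0), 1000.0)
        out = resample_grf(s, ACCEL_FS)
        assert out.n_samples == 1000
        np.testing.assert_allclose(out.values, 500.0, rtol=1e-6)
        assert out.fs == pytest.approx(ACCEL_FS, rel=1e-12)

    def test_sine_matches_analytic(self):
        t = np.arange(7000) / 1000.0
        s = _sig(np.sin(2 * np.pi * 5.0 * t)[None, :], 1000.0)
        out = resample_grf(s, ACCEL_FS)
        expect = np.sin(2 * np.pi * 5.0 * out.times)
        interior = slice(30, -30)
        assert np.max(np.abs(out.values[0][interior] - expect[interior])) < 1e-3

    def test_identity(self):
        s = _sig(np.random.default_rng(0).normal(size=(1, 100)), 100.0)
        out = resample_grf(s, 100.0)
        np.testing.assert_array_equal(out.values, s.values)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_grf(_sig(np.zeros((1, 10)), 100.0), 200.0)


class TestReorientPca:
    def test_single_axis_variance(self):
        a = _sig([[1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 0, 0]], 100.0)
        out = reorient_pca(a)
        np.testing.assert_allclose(out.values[0], [-1.5, -0.5, 0.5, 1.5], atol=1e-12)

    def test_matches_brute_force_eigendecomposition(self, rng):
        vals = rng.normal(size=(3, 200)) * np.array([[3.0], [1.0], [0.5]])
        out = reorient_pca(_sig(vals, 100.0)).values[0]
        centered = vals - vals.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(np.cov(centered))
        ref = evecs[:, np.argmax(evals)] @ centered
        err = min(np.max(np.abs(out - ref)), np.max(np.abs(out + ref)))
        assert err < 1e-9
        assert np.var(out, ddof=1) == pytest.approx(np.max(evals), rel=1e-9)

    def test_rotation_invariance(self, rng):
        vals = rng.normal(size=(3, 300)) * np.array([[3.0], [1.0], [0.5]])
        base = reorient_pca(_sig(vals, 100.0)).values[0]
        R = Rotation.random(rng=rng).as_matrix()
        rot = reorient_pca(_sig(R @ vals, 100.0)).values[0]
        err = min(np.max(np.abs(rot - base)), np.max(np.abs(rot + base)))
        assert err < 1e-8

    def test_degenerate_covariance(self):
        with pytest.raises(ValueError, match="degenerate covariance"):
            reorient_pca(_sig(np.zeros((3, 10)), 100.0))


class TestHighpass:
    def test_dc_removed(self):
        s = _sig(np.full((1, 500), 3.0), ACCEL_FS)
        out = highpass_bidirectional(s, 1.0, 2)
        assert np.max(np.abs(out.values[0][50:-50])) < 1e-6 * 3.0

    def test_passband_amplitude_and_zero_lag(self):
        t = np.arange(2000) / ACCEL_FS
        x = np.sin(2 * np.pi * 10.0 * t)
        out = highpass_bidirectional(_sig(x[None, :], ACCEL_FS), 1.0, 2).values[0]
        interior = slice(200, -200)
        amp = np.max(np.abs(out[interior]))
        assert amp == pytest.approx(1.0, rel=0.02)
        xc = np.correlate(out[interior], x[interior], mode="full")
        lag = int(np.argmax(xc)) - (len(x[interior]) - 1)
        assert lag == 0

    def test_stopband_attenuation(self):
        t = np.arange(8000) / ACCEL_FS
        x = np.sin(2 * np.pi * 0.1 * t)
        out = highpass_bidirectional(_sig(x[None, :], ACCEL_FS), 1.0, 2).values[0]
        assert np.max(np.abs(out[1000:-1000])) < 0.1

    def test_cutoff_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_bidirectional(_sig(np.zeros((1, 100)), 100.0), 60.0)


class TestIntegrate:
    def test_zero(self):
        out = integrate_cumulative(_sig(np.zeros((1, 50)), 100.0))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_constant_one_second(self):
        out = integrate_cumulative(_sig(np.ones((1, 101)), 100.0))
        assert out.values[0, -1] == pytest.approx(1.0, abs=1e-9)

    def test_cosine_analytic(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = np.cos(2 * np.pi * 10 * t)
        out = integrate_cumulative(_sig(x[None, :], fs)).values[0]
        expect = np.sin(2 * np.pi * 10 * t) / (2 * np.pi * 10)
        assert np.max(np.abs(out - expect)) < 1e-3 / (2 * np.pi * 10) + 1e-4


class TestRangeNormalize:
    def test_example(self):
        # divide by peak-to-peak range, no centering: [0, 2, 4] / 4
        out = range_normalize(_sig([[0.0, 2.0, 4.0]], 10.0))
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 100))
    @settings(max_examples=25, deadline=None)
    def test_unit_range_property(self, seed, n):
        v = np.random.default_rng(seed).normal(size=(1, n))
        if v.max() - v.min() <= 0:
            return
        out = range_normalize(_sig(v, 10.0)).values[0]
        assert out.max() - out.min() == pytest.approx(1.0, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            range_normalize(_sig(np.ones((1, 5)), 10.0))


class TestZscore:
    def test_sample_sd_convention(self):
        out = zscore_signal(_sig([[1.0, 2.0, 3.0]], 10.0))
        np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_moments(self, rng):
        out = zscore_signal(_sig(rng.normal(size=(1, 500)), 10.0)).values[0]
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1.0) < 1e-12

    def test_idempotent(self, rng):
        s = _sig(rng.normal(size=(1, 100)), 10.0)
        once = zscore_signal(s)
        twice = zscore_signal(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore_signal(_sig(np.full((1, 5), 2.0), 10.0))


class TestBuildInput:
    def test_shape_and_unit_ranges(self, walking_trial):
        x = build_input(walking_trial.accel).x
        assert x.shape[0] == 3
        np.testing.assert_allclose(x.max(axis=1) - x.min(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance(self, walking_trial):
        a = walking_trial.accel
        x1 = build_input(a).x
        x2 = build_input(SampledSignal(2.0 * a.values, fs=a.fs)).x
        assert np.max(np.abs(x1 - x2)) < 1e-8

    def test_rotation_invariance_up_to_sign(self, walking_trial, rng):
        a = walking_trial.accel
        x1 = build_input(a).x
        R = Rotation.random(rng=rng).as_matrix()
        x2 = build_input(SampledSignal(R @ a.values, fs=a.fs)).x
        for row1, row2 in zip(x1, x2):
            err = min(np.max(np.abs(row1 - row2)), np.max(np.abs(row1 + row2)))
            assert err < 1e-8

    def test_zero_variance_propagates(self):
        with pytest.raises(ValueError, match="degenerate covariance"):
            build_input(SampledSignal(np.zeros((3, 100)), fs=100.0))


class TestSegmentation:
    def _events(self, fos, fs=100.0):
        fcs = [f - 30 for f in fos]
        return GaitEventSeries(fcs, fos, fs=fs)

    def test_two_segments(self):
        x = np.zeros((3, 500))
        z = np.zeros(500)
        segs = segment_at_foot_off(x, z, self._events([100, 250, 400]),
                                   PreprocessConfig(transient_samples=0))
        assert [(s.start, s.end) for s in segs] == [(100, 250), (250, 400)]

    def test_transient_mask_count(self):
        x = np.zeros((3, 500))
        z = np.zeros(500)
        segs = segment_at_foot_off(x, z, self._events([100, 250]),
                                   PreprocessConfig(transient_samples=36))
        assert segs[0].mask.sum() == 150 - 72

    def test_zero_transient_all_true(self):
        segs = segment_at_foot_off(
            np.zeros((3, 500)), np.zeros(500), self._events([100, 250]),
            PreprocessConfig(transient_samples=0),
        )
        assert segs[0].mask.all()

    def test_too_few_foot_offs(self, caplog):
        with caplog.at_level("WARNING"):
            segs = segment_at_foot_off(
                np.zeros((3, 100)), np.zeros(100),
                GaitEventSeries([10], [50], fs=100.0),
            )
        assert segs == []

    def test_concatenation_reconstructs_span(self, rng):
        x = rng.normal(size=(3, 600))
        z = rng.normal(size=600)
        fos = [50, 200, 340, 520]
        segs = segment_at_foot_off(x, z, self._events(fos),
                                   PreprocessConfig(transient_samples=0))
        xcat = np.hstack([s.x for s in segs])
        zcat = np.concatenate([s.z for s in segs])
        np.testing.assert_array_equal(xcat, x[:, 50:520])
        np.testing.assert_array_equal(zcat, z[50:520])


class TestResampleStancePreservation:
    def test_stance_duration_preserved(self, walking_trial):
        from esngait.gait_events import detect_events

        g = resample_grf(walking_trial.grf, ACCEL_FS)
        ev = detect_events(g)
        gt = walking_trial.events
        stance_det = ev.foot_offs[: len(ev.foot_contacts)] - ev.foot_contacts
        stance_gt = gt.foot_offs - gt.foot_contacts
        n = min(len(stance_det), len(stance_gt))
        assert np.max(np.abs(stance_det[:n] - stance_gt[:n])) <= 2
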