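"""Window segmentation, QVR baseline removal and the adaptive mains notch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import tastemg as tm
from conftest import make_window

FS = 1000.0
T = np.arange(1000) / FS


def _short_trial(duration_s, subject="S1"):
    n = int(duration_s * FS)
    return tm.RawTrial(
        signal=np.arange(6 * n, dtype=float).reshape(6, n),
        stimulus=tm.StimulusSpec.from_intensity("Sour", 1),
        subject_id=subject, session=1, scale_score=2.0, sampling_rate=FS,
    )


class TestAugmentWindows:
    def test_twelve_second_trial_yields_45_windows(self, salty_trials):
        windows = tm.augment_windows(salty_trials[0])
        assert len(windows) == 45  # floor((12000-1000)/250)+1
        assert [w.window_offset for w in windows] == list(range(0, 11001, 250))

    def test_one_second_trial_single_window(self):
        windows = tm.augment_windows(_short_trial(1.0))
        assert len(windows) == 1 and windows[0].window_offset == 0

    def test_window_contents_match_trial_slices(self, salty_trials):
        trial = salty_trials[0]
        for w in tm.augment_windows(trial)[::9]:
            off = w.window_offset
            assert np.array_equal(w.signal, trial.signal[:, off:off + 1000])

    def test_stride_equal_to_window_tiles_trial_exactly(self):
        trial = _short_trial(4.0)
        windows = tm.augment_windows(trial, window_s=1.0, step_s=1.0)
        tiled = np.concatenate([w.signal for w in windows], axis=1)
        assert np.array_equal(tiled, trial.signal)

    def test_too_short_trial_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert tm.augment_windows(_short_trial(0.5)) == []


class TestQVR:
    def test_constant_input_maps_to_zero(self):
        for lam in (0.0, 2.0, 100.0):
            out = tm.qvr(np.full(100, 3.7), lam)
            np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_lambda_zero_maps_anything_to_zero(self):
        x = np.random.default_rng(0).standard_normal(200)
        np.testing.assert_allclose(tm.qvr(x, 0.0), 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [16, 50, 200])
    def test_tridiagonal_solve_matches_dense_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        lam = 2.0
        D = np.diff(np.eye(n), axis=0)  # (n-1) x n first differences
        dense_baseline = np.linalg.solve(np.eye(n) + lam * D.T @ D, x)
        expected = x - dense_baseline
        got = tm.qvr(x, lam)
        assert np.linalg.norm(got - expected) <= 1e-10 * max(np.linalg.norm(expected), 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 64))
        lhs = tm.qvr(a * x + b * y, 2.0)
        rhs = a * tm.qvr(x, 2.0) + b * tm.qvr(y, 2.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_large_lambda_limit_is_demeaned_signal(self):
        x = np.random.default_rng(1).standard_normal(500) + 10.0
        out = tm.qvr(x, 1e9)
        np.testing.assert_allclose(out, x - x.mean(), atol=1e-5)

    def test_baseline_retrievable_and_consistent(self):
        x = np.random.default_rng(2).standard_normal(300) + np.linspace(0, 50, 300)
        detrended, baseline = tm.qvr(x, 2.0, return_baseline=True)
        np.testing.assert_allclose(detrended + baseline, x, atol=1e-10)

    def test_removes_synthetic_wander(self):
        """Large slow drift is mostly removed while the carrier band survives."""
        rng = np.random.default_rng(3)
        sos = sps.butter(4, (20, 450), btype="bandpass", fs=FS, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(1000))
        wander = 100 * np.sin(2 * np.pi * 0.5 * T)
        cleaned = tm.qvr(carrier + wander, 2.0)
        f, p = sps.periodogram(cleaned, FS)
        assert p[f < 5].sum() / p.sum() < 0.05

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            tm.qvr(np.array([1.0, np.nan, 2.0]), 2.0)


class TestAdaptiveNotch:
    def test_pure_50hz_attenuated_at_least_20db(self):
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 50 * T) + 0.01 * rng.standard_normal(1000)
        cleaned, report = tm.adaptive_notch(make_window(x))
        before = np.abs(np.fft.rfft(x))[50]
        after = np.abs(np.fft.rfft(cleaned.signal[0]))[50]
        assert 20 * np.log10(before / after) >= 20.0
        assert 0.0 <= report.removed_power_fraction <= 1.0

    def test_interference_free_tone_untouched(self):
        x = np.sin(2 * np.pi * 80 * T)
        cleaned, report = tm.adaptive_notch(make_window(x))
        rms_change = np.sqrt(np.mean((cleaned.signal - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert rms_change <= 0.01
        assert report.modified_bins == []

    def test_carrier_band_power_preserved_outside_notch(self):
        rng = np.random.default_rng(1)
        sos = sps.butter(4, (20, 450), btype="bandpass", fs=FS, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(1000))
        carrier /= np.sqrt(np.mean(carrier**2))
        x = carrier + 10 * np.sin(2 * np.pi * 50 * T)
        cleaned, report = tm.adaptive_notch(make_window(x))
        mask = np.ones(501, dtype=bool)
        for _k, bins in report.modified_bins:
            mask[bins] = False
        band = np.zeros(501, dtype=bool)
        band[20:451] = True
        sel = band & mask
        p_carrier = np.sum(np.abs(np.fft.rfft(carrier))[sel] ** 2)
        p_clean = np.sum(np.abs(np.fft.rfft(cleaned.signal[0]))[sel] ** 2)
        assert p_clean == pytest.approx(p_carrier, rel=0.05)

    def test_notch_is_projection_like(self):
        """A second pass changes the signal by < 1% RMS."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1000) + 8 * np.sin(2 * np.pi * 50 * T)
        once, _ = tm.adaptive_notch(make_window(x))
        twice, _ = tm.adaptive_notch(once)
        change = (np.sqrt(np.mean((twice.signal - once.signal) ** 2))
                  / np.sqrt(np.mean(once.signal**2)))
        assert change < 0.01


class TestRejectDistorted:
    def test_keep_and_reject_thresholds(self):
        keep = tm.NotchReport([], [0.0] * 6, 0.0)
        drop = tm.NotchReport([], [0.1] * 5 + [0.95], 0.95)
        assert not tm.reject_distorted(keep)
        assert tm.reject_distorted(drop)

    def test_constructed_batch_rejects_exactly_the_heavy_windows(self):
        """100 windows, 7 with overwhelming 50 Hz interference -> 7 rejected."""
        rng = np.random.default_rng(3)
        sos = sps.butter(4, (20, 450), btype="bandpass", fs=FS, output="sos")
        n_rejected = 0
        for i in range(100):
            carrier = sps.sosfiltfilt(sos, rng.standard_normal(1000))
            carrier /= np.sqrt(np.mean(carrier**2))
            amp = 50.0 if i < 7 else 0.5  # 50x RMS mains vs negligible
            x = carrier + amp * np.sin(2 * np.pi * 50 * T + rng.uniform(0, 2 * np.pi))
            _, report = tm.adaptive_notch(make_window(x, n_channels=1))
            n_rejected += tm.reject_distorted(report)
        assert n_rejected == 7
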