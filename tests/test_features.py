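"""Spectral/time feature extraction and the 330-vector ordering contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tastemg as tm
from conftest import make_window
from tastemg import features as feat

FS = 1000.0
T = np.arange(1000) / FS


def tone(freq, amp=1.0, phase=0.0):
    return amp * np.cos(2 * np.pi * freq * T + phase)


class TestSpectrum:
    def test_zero_signal_all_zero_magnitudes(self):
        spec = tm.spectrum(np.zeros(1000), FS)
        assert spec.magnitudes.shape == (500,)
        assert np.all(spec.magnitudes == 0)

    def test_integer_periodic_tone_is_a_single_bin(self):
        spec = tm.spectrum(tone(25), FS)
        peak = spec.magnitudes[25]
        others = np.delete(spec.magnitudes, range(22, 29))
        assert np.argmax(spec.magnitudes) == 25
        assert np.all(others < 1e-9 * peak)

    def test_two_tones_two_dominant_bins(self):
        spec = tm.spectrum(tone(25) + tone(125), FS)
        assert set(np.argsort(spec.magnitudes)[-2:]) == {25, 125}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tm.spectrum(np.array([np.inf] * 1000), FS)


class TestBandFeatures:
    def test_tone_mass_in_expected_band(self):
        bands = tm.band_features(tm.spectrum(tone(25), FS))
        assert bands.shape == (50,)
        assert bands[2] > 0.999 * bands.sum()  # band 3 covers 20-29 Hz

    def test_partition_conserves_total_magnitude_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        spec = tm.spectrum(x, FS)
        assert tm.band_features(spec).sum() == pytest.approx(
            spec.magnitudes.sum(), rel=1e-12)

    def test_zero_signal_fifty_zeros(self):
        assert np.all(tm.band_features(tm.spectrum(np.zeros(1000), FS)) == 0)


class TestMomentFeatures:
    def test_point_mass_tone(self):
        fc, rmsf, rvf = tm.moment_features(tm.spectrum(tone(25), FS))
        assert fc == pytest.approx(25.0, abs=1e-6)
        assert rmsf == pytest.approx(25.0, abs=1e-6)
        assert rvf == pytest.approx(0.0, abs=1e-3)

    def test_two_point_distribution(self):
        """Equal mass at 20 and 30 Hz: FC=25, RVF=5, RMSF=sqrt(650)."""
        mags = np.zeros(500)
        mags[20] = mags[30] = 1.0
        spec = tm.ChannelSpectrum(mags, 1.0)
        fc, rmsf, rvf = tm.moment_features(spec)
        assert fc == pytest.approx(25.0)
        assert rvf == pytest.approx(5.0)
        assert rmsf == pytest.approx(np.sqrt(25**2 + 5**2))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rmsf_identity(self, seed):
        """RMSF^2 = FC^2 + RVF^2 for any nonnegative spectrum."""
        mags = np.random.default_rng(seed).uniform(0, 1, 500)
        fc, rmsf, rvf = tm.moment_features(tm.ChannelSpectrum(mags, 1.0))
        assert rmsf**2 == pytest.approx(fc**2 + rvf**2, rel=1e-9)

    def test_zero_spectrum_flagged_nan(self):
        fc, rmsf, rvf = tm.moment_features(tm.ChannelSpectrum(np.zeros(500), 1.0))
        assert np.isnan(fc) and np.isnan(rmsf) and np.isnan(rvf)


class TestTimeFeatures:
    @pytest.mark.parametrize("amp", [1.0, 2.5])
    def test_sinusoid_closed_forms(self, amp):
        rms, mav = tm.time_features(tone(25, amp))
        assert rms == pytest.approx(amp / np.sqrt(2), rel=1e-3)
        assert mav == pytest.approx(2 * amp / np.pi, rel=5e-3)

    def test_constant(self):
        rms, mav = tm.time_features(np.full(1000, -3.0))
        assert rms == 3.0 and mav == 3.0


class TestExtract:
    def test_length_and_per_channel_blocks(self, salty_windows):
        vec = tm.extract(salty_windows[0])
        assert vec.shape == (330,)
        assert feat.FEATURES_PER_CHANNEL == 55
        assert len(feat.channel_columns(3)) == 55

    def test_ordering_contract(self):
        assert feat.channel_of_feature(1) == 1
        assert feat.channel_of_feature(55) == 1
        assert feat.channel_of_feature(56) == 2
        assert feat.channel_of_feature(330) == 6
        assert feat.group_of_feature(1) == 1
        assert feat.group_of_feature(5) == 1
        assert feat.group_of_feature(6) == 2
        assert feat.group_of_feature(55) == 11
        assert feat.group_columns(1, 1) == ["f001", "f002", "f003", "f004", "f005"]
        assert feat.group_columns(2, 11) == ["f106", "f107", "f108", "f109", "f110"]

    def test_known_tone_lands_in_documented_positions(self):
        """Channel-major layout: channel c's F_k sits at index 55(c-1)+k-1."""
        sig = np.zeros((6, 1000))
        sig[3] = tone(25)  # channel 4
        vec = tm.extract(tm.WindowSample(sig, "t", 0, FS, {}))
        ch4 = vec[3 * 55:4 * 55]
        assert ch4[2] > 0  # band 3
        assert ch4[50] == pytest.approx(25.0, abs=1e-6)  # FC
        assert np.isnan(vec[50])  # zero channel 1: FC flagged

    def test_zero_sample_bands_zero_moments_nan(self):
        vec = tm.extract(make_window(np.zeros(1000)))
        for ch in range(6):
            block = vec[ch * 55:(ch + 1) * 55]
            assert np.all(block[:50] == 0)
            assert np.all(np.isnan(block[50:53]))
            assert block[53] == 0 and block[54] == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50))
    def test_scale_equivariance(self, seed, scale):
        """Scaling the window scales bands/RMS/MAV by |c|; moments unchanged."""
        x = np.random.default_rng(seed).standard_normal(1000)
        v1 = tm.extract(make_window(x))
        v2 = tm.extract(make_window(scale * x))
        block1, block2 = v1[:55], v2[:55]
        np.testing.assert_allclose(block2[:50], scale * block1[:50], rtol=1e-9)
        np.testing.assert_allclose(block2[53:], scale * block1[53:], rtol=1e-9)
        np.testing.assert_allclose(block2[50:53], block1[50:53], rtol=1e-9)
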