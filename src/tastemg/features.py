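"""Per-channel spectral and time-domain features (55 per channel, 330 total).

For each 1 s, 1 kHz channel the one-sided magnitude spectrum (500 bins at
1 Hz resolution) is summarized as:

* F1-F50   — band magnitudes: sums over fifty 10 Hz intervals covering
             0-499 Hz (band n covers [(n-1)*10, n*10) Hz);
* F51      — FC, the spectral centroid (Hz);
* F52      — RMSF, root-mean-square frequency (Hz);
* F53      — RVF, root-variance frequency, i.e. spectral spread (Hz);
* F54      — RMS of the time-domain window;
* F55      — MAV, mean absolute value of the time-domain window.

Six channels concatenated channel-major give the 330-dimensional vector.
Within a channel, the 55 features fall into 11 consecutive groups of 5
(group g covers features 5(g-1)+1 .. 5g) — the unit of grouped feature
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import WindowSample

N_BANDS = 50
FEATURES_PER_CHANNEL = 55
N_CHANNELS = 6
N_FEATURES = N_CHANNELS * FEATURES_PER_CHANNEL  # 330
GROUP_SIZE = 5
N_GROUPS = FEATURES_PER_CHANNEL // GROUP_SIZE  # 11


@dataclass(frozen=True)
class ChannelSpectrum:
    """One-sided magnitude spectrum: bins i = 0..L/2-1 at fs/L Hz each."""

    magnitudes: np.ndarray
    bin_resolution: float  # Hz per bin


def spectrum(x: np.ndarray, fs: float = 1000.0) -> ChannelSpectrum:
    """Unnormalized one-sided magnitude spectrum (no taper; DC included)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spectrum input contains non-finite values")
    L = x.size
    mags = np.abs(np.fft.rfft(x))[: L // 2]
    return ChannelSpectrum(magnitudes=mags, bin_resolution=fs / L)


def band_features(spec: ChannelSpectrum) -> np.ndarray:
    """Fifty band magnitude sums; band n sums bins (n-1)*10 .. n*10-1.

    The bands partition the spectrum, so their sum equals the total
    spectral magnitude exactly.
    """
    mags = spec.magnitudes
    if mags.size != N_BANDS * 10:
        raise ValueError(f"expected {N_BANDS * 10} spectral bins, got {mags.size}")
    return mags.reshape(N_BANDS, 10).sum(axis=1)


def moment_features(spec: ChannelSpectrum) -> tuple[float, float, float]:
    """(FC, RMSF, RVF): centroid, rms frequency and spread of the spectrum.

    Treats the magnitude spectrum as a mass distribution over bin
    frequencies nu_i = i * fs/L.  An all-zero spectrum has no defined
    moments; (nan, nan, nan) is returned so the window can be flagged.
    """
    mags = spec.magnitudes
    total = mags.sum()
    if total == 0:
        return (float("nan"),) * 3
    freqs = np.arange(mags.size) * spec.bin_resolution
    fc = float(np.sum(mags * freqs) / total)
    rmsf = float(np.sqrt(np.sum(mags * freqs**2) / total))
    rvf = float(np.sqrt(np.sum(mags * (freqs - fc) ** 2) / total))
    return fc, rmsf, rvf


def time_features(x: np.ndarray) -> tuple[float, float]:
    """(RMS, MAV) of the time-domain window."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("time_features input contains non-finite values")
    return float(np.sqrt(np.mean(x**2))), float(np.mean(np.abs(x)))


def extract(sample: WindowSample) -> np.ndarray:
    """The full 330-value feature vector of a preprocessed window.

    Channel-major: channel 1's F1..F55, then channel 2's, and so on.
    Moments of an all-zero channel come out NaN (flagged missing).
    """
    blocks = []
    for ch in sample.signal:
        spec = spectrum(ch, sample.sampling_rate)
        fc, rmsf, rvf = moment_features(spec)
        rms, mav = time_features(ch)
        blocks.append(np.concatenate([band_features(spec), [fc, rmsf, rvf, rms, mav]]))
    vec = np.concatenate(blocks)
    assert vec.size == N_FEATURES
    return vec


# ---------------------------------------------------------------------------
# Ordering contract helpers: feature j (1-based) belongs to channel
# ceil(j/55); its within-channel index is ((j-1) mod 55) + 1.

def feature_names() -> list[str]:
    """Column names f001..f330 in extraction order."""
    return [f"f{j:03d}" for j in range(1, N_FEATURES + 1)]


def channel_of_feature(j: int) -> int:
    """Channel (1-6) owning 1-based feature index j."""
    if not 1 <= j <= N_FEATURES:
        raise ValueError(f"feature index must be 1..{N_FEATURES}")
    return (j - 1) // FEATURES_PER_CHANNEL + 1


def group_of_feature(j: int) -> int:
    """Within-channel group (1-11) of 1-based feature index j."""
    within = (j - 1) % FEATURES_PER_CHANNEL
    return within // GROUP_SIZE + 1


def channel_columns(channel: int) -> list[str]:
    """The 55 feature column names of one channel."""
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError("channel must be 1..6")
    start = (channel - 1) * FEATURES_PER_CHANNEL
    return [f"f{j:03d}" for j in range(start + 1, start + FEATURES_PER_CHANNEL + 1)]


def group_columns(channel: int, group: int) -> list[str]:
    """The 5 feature column names of one (channel, group)."""
    if not 1 <= group <= N_GROUPS:
        raise ValueError("group must be 1..11")
    start = (channel - 1) * FEATURES_PER_CHANNEL + (group - 1) * GROUP_SIZE
    return [f"f{j:03d}" for j in range(start + 1, start + GROUP_SIZE + 1)]
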