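"""Window segmentation, baseline removal (QVR) and adaptive mains notch.

The preprocessing chain cuts each trial into 1 s windows at a 0.25 s
step, removes baseline wander per channel with quadratic variation
reduction (QVR), removes 50 Hz power-line interference and its harmonics
with an adaptive spectral-interpolation notch, and drops windows whose
interference was so heavy that notching removed most of their power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.linalg import solveh_banded

from .synthetic import RawTrial

#: Default smoothing weight of the QVR baseline fit.
DEFAULT_LAMBDA = 2.0

#: Default fraction of removed power above which a window is discarded.
DEFAULT_MAX_REMOVED_FRACTION = 0.8


@dataclass(frozen=True)
class WindowSample:
    """One sliding-window segment of a trial (all channels cut identically)."""

    signal: np.ndarray  # (channels, window_length)
    trial_id: str
    window_offset: int  # samples from trial start
    sampling_rate: float = 1000.0
    labels: Mapping[str, Any] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def length(self) -> int:
        return self.signal.shape[1]


@dataclass
class NotchReport:
    """What the adaptive notch did to one window."""

    modified_bins: list[tuple[int, list[int]]]  # (harmonic k, bins) over all channels
    per_channel_removed: list[float]  # fraction of power removed, each channel
    removed_power_fraction: float  # max over channels
    rejected: bool = False


def augment_windows(
    trial: RawTrial, window_s: float = 1.0, step_s: float = 0.25
) -> list[WindowSample]:
    """Cut a trial into overlapping windows at offsets 0, step, 2*step, ...

    The last partial window is discarded.  A trial shorter than one window
    yields an empty list and a warning.
    """
    fs = trial.sampling_rate
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    n = trial.signal.shape[1]
    if n < win:
        warnings.warn(
            f"trial {trial.trial_id} ({n / fs:.3g} s) is shorter than one "
            f"{window_s:g} s window; no samples produced",
            stacklevel=2,
        )
        return []
    labels = {
        "subject": trial.subject_id,
        "session": trial.session,
        "taste": trial.stimulus.taste_type,
        "concentration": trial.stimulus.concentration,
        "intensity": trial.stimulus.intensity_index,
        "scale_score": trial.scale_score,
    }
    out = []
    for off in range(0, n - win + 1, step):
        out.append(
            WindowSample(
                signal=trial.signal[:, off : off + win].copy(),
                trial_id=trial.trial_id,
                window_offset=off,
                sampling_rate=fs,
                labels=labels,
            )
        )
    return out


def qvr(x: np.ndarray, lambda_: float = DEFAULT_LAMBDA, return_baseline: bool = False):
    """Quadratic variation reduction: subtract a penalized-smoothness baseline.

    The baseline s solves (I + lambda * D'D) s = x, where D is the
    (n-1) x n first-difference matrix; the detrended signal is x - s.
    I + lambda*D'D is symmetric positive-definite tridiagonal, so the
    solve is linear-time (banded Cholesky).

    With lambda = 0 the baseline equals the input (output all zero); as
    lambda -> inf the baseline tends to the input's mean.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("qvr expects a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("qvr input contains non-finite values")
    if lambda_ < 0:
        raise ValueError("lambda_ must be nonnegative")
    n = x.size
    # D'D is tridiagonal: diag (1, 2, ..., 2, 1), off-diagonals -1.
    diag = np.full(n, 1.0 + 2.0 * lambda_)
    diag[0] = diag[-1] = 1.0 + lambda_
    ab = np.zeros((2, n))
    ab[0, 1:] = -lambda_
    ab[1] = diag
    baseline = solveh_banded(ab, x)
    detrended = x - baseline
    if return_baseline:
        return detrended, baseline
    return detrended


def qvr_window(sample: WindowSample, lambda_: float = DEFAULT_LAMBDA) -> WindowSample:
    """Apply QVR independently to every channel of a window."""
    cleaned = np.vstack([qvr(ch, lambda_) for ch in sample.signal])
    return WindowSample(cleaned, sample.trial_id, sample.window_offset,
                        sample.sampling_rate, sample.labels)


def _notch_channel(
    x: np.ndarray,
    fs: float,
    f0: float,
    harmonics_max: int,
    detect_ratio: float,
    halfwidth: int,
) -> tuple[np.ndarray, list[tuple[int, list[int]]], float]:
    """Notch one channel; returns (signal, modified bins, removed power fraction)."""
    n = x.size
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    phase = np.angle(spec)
    modified: list[tuple[int, list[int]]] = []
    power_before = float(np.sum(x**2))
    for k in range(1, harmonics_max + 1):
        fbin = int(round(k * f0 * n / fs))
        lo_flank = np.arange(fbin - 8, fbin - 2)
        hi_flank = np.arange(fbin + 3, fbin + 9)
        if lo_flank[0] < 0 or hi_flank[-1] >= mag.size:
            continue
        med_lo = float(np.median(mag[lo_flank]))
        med_hi = float(np.median(mag[hi_flank]))
        flank_med = float(np.median(np.concatenate([mag[lo_flank], mag[hi_flank]])))
        band = np.arange(fbin - halfwidth, fbin + halfwidth + 1)
        peak = float(mag[band].max())
        if flank_med == 0 and peak == 0:
            continue
        if peak > detect_ratio * max(flank_med, np.finfo(float).tiny):
            # Replace band magnitudes by linear interpolation between the
            # flanking medians; phases are kept.
            left_edge, right_edge = band[0] - 1, band[-1] + 1
            mag[band] = np.interp(band, [left_edge, right_edge], [med_lo, med_hi])
            modified.append((k, band.tolist()))
    if not modified:
        return x, [], 0.0
    spec_new = mag * np.exp(1j * phase)
    y = np.fft.irfft(spec_new, n=n)
    power_after = float(np.sum(y**2))
    removed = 0.0 if power_before == 0 else 1.0 - power_after / power_before
    return y, modified, float(np.clip(removed, 0.0, 1.0))


def adaptive_notch(
    sample: WindowSample,
    harmonics_max: int = 9,
    detect_ratio: float = 5.0,
    notch_halfwidth_bins: int = 1,
    powerline_freq: float = 50.0,
) -> tuple[WindowSample, NotchReport]:
    """Remove power-line interference only where it is abnormally strong.

    Per channel, each harmonic k*f0 whose spectral peak exceeds
    ``detect_ratio`` times the median of its flanking bins (offsets 3-8
    bins either side) has the notch band (peak +/- halfwidth bins)
    replaced by linear interpolation of the flanking medians, keeping
    phases.  Harmonics that look normal are left untouched, so clean
    signals pass through unchanged.
    """
    if harmonics_max * powerline_freq >= sample.sampling_rate / 2:
        raise ValueError("harmonics_max * powerline frequency must be below Nyquist")
    out = np.empty_like(sample.signal, dtype=float)
    all_mod: list[tuple[int, list[int]]] = []
    removed: list[float] = []
    for c, ch in enumerate(sample.signal):
        y, mod, frac = _notch_channel(
            np.asarray(ch, dtype=float), sample.sampling_rate, powerline_freq,
            harmonics_max, detect_ratio, notch_halfwidth_bins,
        )
        out[c] = y
        all_mod.extend(mod)
        removed.append(frac)
    report = NotchReport(
        modified_bins=all_mod,
        per_channel_removed=removed,
        removed_power_fraction=max(removed) if removed else 0.0,
    )
    cleaned = WindowSample(out, sample.trial_id, sample.window_offset,
                           sample.sampling_rate, sample.labels)
    return cleaned, report


def reject_distorted(
    report: NotchReport, max_removed_fraction: float = DEFAULT_MAX_REMOVED_FRACTION
) -> bool:
    """True (drop the window) iff notching removed more than the allowed
    power fraction on any channel — the signal left behind is mostly
    interference residue, not muscle activity."""
    return any(f > max_removed_fraction for f in report.per_channel_removed)


def preprocess_trial(
    trial: RawTrial,
    window_s: float = 1.0,
    step_s: float = 0.25,
    lambda_: float = DEFAULT_LAMBDA,
    harmonics_max: int = 9,
    detect_ratio: float = 5.0,
    notch_halfwidth_bins: int = 1,
    powerline_freq: float = 50.0,
    max_removed_fraction: float = DEFAULT_MAX_REMOVED_FRACTION,
) -> tuple[list[WindowSample], list[NotchReport], int]:
    """Full chain for one trial: window -> QVR -> adaptive notch -> reject.

    Returns (kept windows, all notch reports, number rejected).
    """
    kept: list[WindowSample] = []
    reports: list[NotchReport] = []
    n_rejected = 0
    for w in augment_windows(trial, window_s, step_s):
        w = qvr_window(w, lambda_)
        w, report = adaptive_notch(w, harmonics_max, detect_ratio,
                                   notch_halfwidth_bins, powerline_freq)
        report.rejected = reject_distorted(report, max_removed_fraction)
        reports.append(report)
        if report.rejected:
            n_rejected += 1
        else:
            kept.append(w)
    return kept, reports, n_rejected
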