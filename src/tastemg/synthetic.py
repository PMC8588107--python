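"""Synthetic six-channel facial sEMG generator.

Real recordings for this task are not publicly deposited, so the pipeline
is exercised on a generator that reproduces the statistical structure the
analysis assumes:

* a band-limited stochastic EMG carrier (Gaussian noise band-passed to the
  20-450 Hz surface-EMG energy band), with per-channel amplitude that
  grows with stimulus intensity for negative-hedonic tastes and stays flat
  for positive-hedonic ones;
* large low-frequency baseline wander (random sub-2 Hz sinusoids plus a
  slow ramp) for the baseline-removal stage to work on;
* additive 50 Hz power-line interference with harmonics for the adaptive
  notch to remove.

Every output is a pure function of its arguments: per-trial seeds are
derived by hashing (master seed, subject, session, taste, intensity), so
regenerating any single trial is order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .stimuli import CHANNEL_MUSCLES, TASTES, StimulusSpec

#: Default per-taste hedonic gains: strong intensity response for the
#: negative-hedonic tastes, near-flat for Sweet/Umami.
DEFAULT_HEDONIC_GAIN: dict[str, float] = {
    "Sour": 1.0,
    "Bitter": 1.0,
    "Salty": 1.0,
    "Sweet": 0.05,
    "Umami": 0.1,
}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject response parameters.

    ``hedonic_gain`` multiplies the intensity-dependent part of each
    channel's activation; near-zero values emulate a taste the subject has
    no facial response to.  ``score_noise_sd`` is the sd of the subject's
    0-10 intensity rating around its intensity-determined mean.
    """

    subject_id: str
    hedonic_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEDONIC_GAIN)
    )
    score_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for taste in ("Sour", "Bitter", "Salty"):
            if self.hedonic_gain.get(taste, 0.0) <= 0:
                raise ValueError(
                    f"hedonic_gain for negative-hedonic taste {taste} must be > 0"
                )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic acquisition.

    ``channel_slopes`` set how steeply each channel's activation grows per
    intensity step; the depressor anguli oris (channel 2) and procerus
    (channel 5) are the steepest, matching the observed facial response
    ordering.  The effective carrier amplitude on channel c is

        base_amplitude_uv * (1 + slope_c * hedonic_gain[taste] * intensity).

    ``wander_amplitude_uv`` defaults to 10x the carrier base amplitude so
    baseline removal has real work to do.
    """

    sampling_rate: float = 1000.0
    trial_duration: float = 12.0
    channel_count: int = 6
    channel_slopes: tuple[float, ...] = (0.15, 0.60, 0.35, 0.15, 0.45, 0.15)
    base_amplitude_uv: float = 10.0
    carrier_band: tuple[float, float] = (20.0, 450.0)
    wander_amplitude_uv: float = 100.0
    wander_cutoff_hz: float = 2.0
    powerline_freq: float = 50.0
    harmonic_amplitudes_uv: tuple[float, ...] = (20.0, 10.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carrier_band[1] >= self.sampling_rate / 2:
            raise ValueError("carrier_band upper edge must be below Nyquist")
        if len(self.channel_slopes) != self.channel_count:
            raise ValueError("need one channel slope per channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))


@dataclass(frozen=True)
class RawTrial:
    """One recorded trial: channel x time signal plus stimulus metadata."""

    signal: np.ndarray  # (channels, samples), µV
    stimulus: StimulusSpec
    subject_id: str
    session: int
    scale_score: float
    sampling_rate: float = 1000.0
    channel_muscles: Mapping[int, str] = field(default_factory=lambda: dict(CHANNEL_MUSCLES))

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("trial signal contains non-finite values")

    @property
    def trial_id(self) -> str:
        s = self.stimulus
        return f"{self.subject_id}.s{self.session}.{s.taste_type}.i{s.intensity_index}"

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate


def muscle_gain(
    config: GeneratorConfig,
    subject: SubjectProfile,
    taste_type: str,
    channel: int,
    intensity_index: int,
) -> float:
    """Carrier amplitude multiplier for one (taste, channel, intensity).

    Nondecreasing in intensity; equals 1 at intensity 0 for every taste,
    so flat-response tastes keep normal baseline muscle tone.
    """
    slope = config.channel_slopes[channel - 1]
    hedonic = float(subject.hedonic_gain.get(taste_type, 0.0))
    return 1.0 + slope * hedonic * intensity_index


def trial_seed(master_seed: int, subject_id: str, session: int, taste_type: str,
               intensity_index: int, tag: str = "trial") -> int:
    """Stable per-trial seed: CRC32 hash of the trial coordinates (< 2^31)."""
    key = f"{master_seed}:{subject_id}:{session}:{taste_type}:{intensity_index}:{tag}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _bandlimited_carrier(rng: np.random.Generator, n: int, fs: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to *band* (zero-phase filter)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _baseline_wander(rng: np.random.Generator, t: np.ndarray, amplitude: float,
                     cutoff_hz: float, n_components: int = 5) -> np.ndarray:
    """Slow drift: random sub-cutoff sinusoids plus a linear ramp."""
    if amplitude == 0:
        return np.zeros_like(t)
    wander = np.zeros_like(t)
    freqs = rng.uniform(0.05, cutoff_hz, n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    amps = rng.uniform(0.5, 1.0, n_components) / n_components
    for f, ph, a in zip(freqs, phases, amps):
        wander += a * np.sin(2 * np.pi * f * t + ph)
    ramp = rng.uniform(0.2, 0.5) * (t / t[-1] - 0.5)
    return amplitude * (wander + ramp)


def _powerline(rng: np.random.Generator, t: np.ndarray, f0: float,
               harmonic_amplitudes: Sequence[float]) -> np.ndarray:
    """Mains interference: f0 sinusoid plus integer harmonics."""
    x = np.zeros_like(t)
    for k, amp in enumerate(harmonic_amplitudes, start=1):
        if amp == 0:
            continue
        x += amp * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
    return x


def generate_trial(
    stimulus: StimulusSpec,
    subject: SubjectProfile,
    config: GeneratorConfig,
    seed: int,
    scale_score: float | None = None,
) -> RawTrial:
    """Generate one 12 s six-channel trial under *stimulus*.

    Each channel is an independent unit-RMS band-limited carrier scaled by
    ``base_amplitude_uv * muscle_gain(...)``, plus shared-model (but
    per-channel randomized) baseline wander and power-line interference.
    Identical arguments give a bit-identical trial.
    """
    rng = np.random.default_rng(seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    sig = np.empty((config.channel_count, n))
    for ch in range(1, config.channel_count + 1):
        gain = muscle_gain(config, subject, stimulus.taste_type, ch,
                           stimulus.intensity_index)
        carrier = _bandlimited_carrier(rng, n, config.sampling_rate, config.carrier_band)
        wander = _baseline_wander(rng, t, config.wander_amplitude_uv,
                                  config.wander_cutoff_hz)
        mains = _powerline(rng, t, config.powerline_freq, config.harmonic_amplitudes_uv)
        sig[ch - 1] = config.base_amplitude_uv * gain * carrier + wander + mains
    if scale_score is None:
        scale_score = assign_scale_score(
            stimulus, subject,
            trial_seed(seed, subject.subject_id, 0, stimulus.taste_type,
                       stimulus.intensity_index, tag="score"),
        )
    return RawTrial(
        signal=sig,
        stimulus=stimulus,
        subject_id=subject.subject_id,
        session=0,
        scale_score=scale_score,
        sampling_rate=config.sampling_rate,
    )


def assign_scale_score(stimulus: StimulusSpec, subject: SubjectProfile, seed: int) -> float:
    """Subject-reported 0-10 intensity rating.

    Mean is linear in the strength label (0 -> 0, 5 -> 10); Gaussian noise
    with sd ``score_noise_sd`` is added and the result clamped to [0, 10].
    """
    mean = 2.0 * stimulus.intensity_index
    if subject.score_noise_sd == 0:
        return float(mean)
    rng = np.random.default_rng(seed)
    return float(np.clip(mean + rng.normal(0.0, subject.score_noise_sd), 0.0, 10.0))


def generate_dataset(
    subjects: Sequence[SubjectProfile],
    sessions_per_subject: int,
    config: GeneratorConfig,
    tastes: Sequence[str] = TASTES,
) -> list[RawTrial]:
    """One trial per (subject, session, taste, intensity).

    A full session covers 5 tastes x 6 intensities = 30 trials; per-trial
    seeds are hashed from the master seed so any subset regenerates
    identically.  ``tastes`` restricts generation to a subset of tastes
    (single-taste datasets are the unit of the regression analyses).
    """
    if not subjects:
        raise ValueError("need at least one subject")
    trials: list[RawTrial] = []
    for subject in subjects:
        for session in range(1, sessions_per_subject + 1):
            for taste in tastes:
                for intensity in range(6):
                    stim = StimulusSpec.from_intensity(taste, intensity)
                    tseed = trial_seed(config.seed, subject.subject_id, session,
                                       taste, intensity)
                    sseed = trial_seed(config.seed, subject.subject_id, session,
                                       taste, intensity, tag="score")
                    trial = generate_trial(
                        stim, subject, config, tseed,
                        scale_score=assign_scale_score(stim, subject, sseed),
                    )
                    trials.append(replace(trial, session=session))
    return trials
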