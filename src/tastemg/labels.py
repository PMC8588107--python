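"""Intensity label schemes attached to each stimulus.

Three schemes are supported as regression targets:

* **strength label** — integer 0-5; 5 at the series maximum, minus one per
  half-order-of-magnitude drop in concentration, 0 for water.  Decreases
  exponentially with concentration.
* **relative concentration** — concentration divided by the series maximum
  (0-1).  Decreases linearly with concentration.
* **scale score** — the subject's own 0-10 intensity rating (carried on
  the trial, not derived here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .stimuli import CONCENTRATION_SERIES, StimulusSpec, _series_index

LABEL_SCHEMES = ("strength_label", "relative_concentration", "scale_score")


@dataclass(frozen=True)
class LabelSet:
    strength_label: int
    relative_concentration: float
    scale_score: float


def strength_label(stimulus: StimulusSpec) -> int:
    """Exponential intensity label: 5 at the maximum, -1 per half decade, 0 for water."""
    idx = _series_index(stimulus.taste_type, stimulus.concentration)
    return 5 - idx


def relative_concentration(stimulus: StimulusSpec) -> float:
    """Linear intensity label: concentration over the taste's maximum concentration."""
    _series_index(stimulus.taste_type, stimulus.concentration)  # validates grid membership
    cmax = CONCENTRATION_SERIES[stimulus.taste_type][0]
    return stimulus.concentration / cmax


def label_set(stimulus: StimulusSpec, scale_score: float) -> LabelSet:
    return LabelSet(
        strength_label=strength_label(stimulus),
        relative_concentration=relative_concentration(stimulus),
        scale_score=float(scale_score),
    )
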