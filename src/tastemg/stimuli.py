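"""Tastant stimuli: the five primary tastes and their concentration series.

Each taste is delivered as an aqueous tastant solution at one of six
concentrations (including 0 mol/L, i.e. deionized water).  Consecutive
nonzero concentrations differ by half an order of magnitude, so the
integer position in the series doubles as the exponential "strength
label" used for regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

#: Fixed taste order used throughout.
TASTES: tuple[str, ...] = ("Sour", "Sweet", "Bitter", "Salty", "Umami")

#: Negative-hedonic tastes drive visible facial responses; positive ones mostly do not.
NEGATIVE_HEDONIC: frozenset[str] = frozenset({"Sour", "Bitter", "Salty"})

#: Tastant used for each taste (aqueous solution).
TASTANTS: dict[str, str] = {
    "Sour": "citric acid",
    "Sweet": "sucrose",
    "Bitter": "magnesium chloride",
    "Salty": "sodium chloride",
    "Umami": "sodium glutamate",
}

#: Concentration series (mol/L), ordered by strength label 5, 4, 3, 2, 1, 0.
#: Nonzero steps are half an order of magnitude (x10^-0.5, printed rounded).
CONCENTRATION_SERIES: dict[str, tuple[float, ...]] = {
    "Sour": (0.200, 0.063, 0.020, 0.006, 0.002, 0.0),
    "Sweet": (1.000, 0.316, 0.100, 0.032, 0.010, 0.0),
    "Bitter": (1.000, 0.316, 0.100, 0.032, 0.010, 0.0),
    "Salty": (2.000, 0.632, 0.200, 0.063, 0.020, 0.0),
    "Umami": (1.000, 0.316, 0.100, 0.032, 0.010, 0.0),
}

#: Relative tolerance for matching a concentration to the printed grid.
CONCENTRATION_RTOL = 1e-6

#: Electrode channel -> recorded muscle. Channels 1 and 6 are both on the
#: masseter (right/left); channel 6, a single electrode, is used for
#: masseter activity summaries.
CHANNEL_MUSCLES: dict[int, str] = {
    1: "masseter",
    2: "depressor anguli oris",
    3: "levator labii superioris",
    4: "risorius",
    5: "procerus",
    6: "masseter",
}


def _series_index(taste_type: str, concentration: float) -> int:
    """Position of *concentration* in the taste's series (0 = strongest)."""
    if taste_type not in TASTES:
        raise ValueError(f"unknown taste type {taste_type!r}; expected one of {TASTES}")
    series = CONCENTRATION_SERIES[taste_type]
    for idx, c in enumerate(series):
        if c == concentration:
            return idx
        if c > 0 and math.isclose(c, concentration, rel_tol=CONCENTRATION_RTOL):
            return idx
    raise ValueError(
        f"concentration {concentration!r} mol/L is not in the {taste_type} "
        f"({TASTANTS[taste_type]}) series {series}"
    )


@dataclass(frozen=True)
class StimulusSpec:
    """One tastant stimulus: taste type, concentration and intensity index.

    ``intensity_index`` runs 0-5; 0 corresponds to deionized water and 5 to
    the strongest concentration in the taste's series.
    """

    taste_type: str
    concentration: float
    intensity_index: int

    def __post_init__(self) -> None:
        idx = _series_index(self.taste_type, self.concentration)
        expected = 5 - idx
        if self.intensity_index != expected:
            raise ValueError(
                f"intensity_index {self.intensity_index} does not match "
                f"{self.taste_type} concentration {self.concentration} mol/L "
                f"(expected {expected})"
            )

    @classmethod
    def from_intensity(cls, taste_type: str, intensity_index: int) -> "StimulusSpec":
        """Build the stimulus at a given intensity of a taste's series."""
        if not 0 <= intensity_index <= 5:
            raise ValueError(f"intensity_index must be 0-5, got {intensity_index}")
        series = CONCENTRATION_SERIES[taste_type]
        return cls(taste_type, series[5 - intensity_index], intensity_index)

    @property
    def tastant(self) -> str:
        return TASTANTS[self.taste_type]

    @property
    def is_water(self) -> bool:
        return self.intensity_index == 0


def all_stimuli() -> list[StimulusSpec]:
    """All 30 (taste, intensity) stimuli: 5 tastes x 6 intensities."""
    return [StimulusSpec.from_intensity(t, i) for t in TASTES for i in range(6)]


def distinct_solutions(stimuli: Iterable[StimulusSpec]) -> set[tuple[str, float]]:
    """Distinct solutions among *stimuli*, counting deionized water once.

    The full protocol uses 26: five nonzero concentrations per taste plus
    one shared water.
    """
    out: set[tuple[str, float]] = set()
    for s in stimuli:
        if s.is_water:
            out.add(("deionized water", 0.0))
        else:
            out.add((s.tastant, s.concentration))
    return out
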