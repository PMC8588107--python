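"""Muscle-activity summaries from spectral amplitude integrals.

The integral of a channel's spectrum amplitude reflects the sEMG energy
and hence the strength of the underlying muscle's activity.  For every
(taste type T, intensity I, channel C) the mean integral S_{T,I,C} over
all windows in that cell is computed; dividing by the intensity-0 value
S_{T,0,C} normalizes each (taste, channel) to 1 at no stimulus.  Channels
2-6 map to the depressor anguli oris, levator labii superioris, risorius,
procerus and masseter; channel 1 (the masseter differential pair) is
excluded because the single-electrode channel 6 reflects raw signal
strength more directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import spectrum
from .preprocess import WindowSample
from .stimuli import CHANNEL_MUSCLES, TASTES

DEFAULT_ACTIVITY_CHANNELS = (2, 3, 4, 5, 6)


@dataclass
class ActivityTable:
    """Tidy grid of mean spectral integrals, raw and normalized.

    ``frame`` has one row per (taste, intensity, channel) with columns
    S (mean integral), S_norm (S / intensity-0 value) and n (window
    count); empty cells carry NaN.
    """

    frame: pd.DataFrame
    channels: tuple[int, ...] = DEFAULT_ACTIVITY_CHANNELS

    def pivot(self, value: str = "S_norm") -> pd.DataFrame:
        """(taste, channel) x intensity matrix of one column."""
        return self.frame.pivot_table(index=["taste", "channel"],
                                      columns="intensity", values=value)


def spectral_integral(sample: WindowSample, channel: int) -> float:
    """Sum of one channel's one-sided spectrum magnitudes (bins 0..L/2-1).

    Equals the sum of the channel's 50 band features exactly.
    """
    return float(spectrum(sample.signal[channel - 1], sample.sampling_rate).magnitudes.sum())


def activity_table(
    samples: list[WindowSample],
    channels: tuple[int, ...] = DEFAULT_ACTIVITY_CHANNELS,
) -> ActivityTable:
    """Mean spectral integral per (taste, intensity, channel) cell.

    Five tastes x six intensities x five channels = 150 S values in the
    full design.  Normalization divides by the same (taste, channel)'s
    intensity-0 mean; it is refused (NaN, with a warning) where that mean
    is zero or the intensity-0 cell is empty.
    """
    recs = []
    for w in samples:
        for ch in channels:
            recs.append({
                "taste": w.labels["taste"],
                "intensity": w.labels["intensity"],
                "channel": ch,
                "integral": spectral_integral(w, ch),
            })
    obs = pd.DataFrame(recs)
    grouped = (obs.groupby(["taste", "intensity", "channel"])["integral"]
               .agg(S="mean", n="size").reset_index())

    tastes_present = [t for t in TASTES if t in set(grouped["taste"])]
    full = pd.MultiIndex.from_product(
        [tastes_present, range(6), channels], names=["taste", "intensity", "channel"]
    )
    grid = (grouped.set_index(["taste", "intensity", "channel"])
            .reindex(full).reset_index())
    grid["n"] = grid["n"].fillna(0).astype(int)

    base = grid[grid["intensity"] == 0].set_index(["taste", "channel"])["S"]
    def _norm(row):
        s0 = base.get((row["taste"], row["channel"]), np.nan)
        if not np.isfinite(s0) or s0 == 0:
            return np.nan
        return row["S"] / s0
    grid["S_norm"] = grid.apply(_norm, axis=1)
    bad = base[(base == 0) | ~np.isfinite(base)]
    if len(bad):
        warnings.warn(
            f"normalization refused for {len(bad)} (taste, channel) cell(s) with "
            "zero or missing intensity-0 activity", stacklevel=2)
    return ActivityTable(frame=grid, channels=tuple(channels))


def colorize(table: ActivityTable, colormap: str = "Greys"):
    """Render the normalized activity grid as per-stimulus color panels.

    One panel per (taste, nonzero intensity) plus a single panel for no
    stimulus (every muscle normalized to 1), each showing the five
    activity channels; values map linearly onto the colormap over the
    table's normalized range, darker meaning stronger activity.  Returns
    the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    frame = table.frame
    vals = frame["S_norm"].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    if vmin == vmax:  # constant table: uniform color
        vmax = vmin + 1.0
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    cmap = plt.get_cmap(colormap)

    tastes = [t for t in TASTES if t in set(frame["taste"])]
    n_rows = len(tastes) + 1  # top row holds the shared no-stimulus panel
    fig = plt.figure(figsize=(2.0 * 5, 1.6 * n_rows))

    def _panel(ax, taste, intensity, title):
        cell = frame[(frame["taste"] == taste) & (frame["intensity"] == intensity)]
        cell = cell.sort_values("channel")
        ax.imshow(cell["S_norm"].to_numpy()[None, :], cmap=cmap, norm=norm,
                  aspect="auto")
        ax.set_xticks(range(len(table.channels)))
        ax.set_xticklabels([f"ch{c}" for c in table.channels], fontsize=6)
        ax.set_yticks([])
        ax.set_title(title, fontsize=7)

    ax0 = fig.add_subplot(n_rows, 5, 1)
    _panel(ax0, tastes[0], 0, "None")
    for r, taste in enumerate(tastes, start=1):
        for i in range(1, 6):
            ax = fig.add_subplot(n_rows, 5, r * 5 + i)
            _panel(ax, taste, i, f"{taste} I={i}")
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=fig.axes,
                 orientation="horizontal", fraction=0.03, pad=0.04)
    return fig
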