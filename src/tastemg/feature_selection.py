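"""Greedy channel-wise grouped forward feature selection.

Each channel's 55 features form 11 ordered groups of 5.  Per channel,
groups are added one at a time, each step taking the group whose addition
gives the best cross-validated R²; the resulting curve of R² against the
number of features NF (5, 10, ..., 55) typically rises and then decays as
redundant information hurts the model.  The curve's "inflection point" is
the largest NF whose R² is within a tolerance (default 0.02) of the
curve's maximum; groups added up to that point are the channel's reserved
features.  The union of reserved features over all six channels is the
reduced feature set, which is refit to confirm performance held up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import GROUP_SIZE, N_GROUPS, group_columns
from .model_eval import DEFAULT_SEED, CVResult, fit_cv

DEFAULT_INFLECTION_TOL = 0.02


@dataclass
class SelectionTrace:
    """Greedy-selection record for one channel."""

    channel: int
    order_added: list[int]  # group indices in addition order
    curve: list[tuple[int, float]]  # (NF, R2_NF), NF = 5, 10, ..., 55
    inflection_nf: int
    reserved_groups: set[int]  # groups added up to the inflection point
    n_fits: int = 0

    @property
    def reserved_columns(self) -> list[str]:
        cols: list[str] = []
        for g in sorted(self.reserved_groups):
            cols.extend(group_columns(self.channel, g))
        return cols


def inflection_point(curve: list[tuple[int, float]], tolerance: float = DEFAULT_INFLECTION_TOL) -> int:
    """Largest NF whose R² is within *tolerance* of the curve's maximum.

    Adding features past this point buys no meaningful performance, so it
    marks where the curve effectively turns over.
    """
    if not curve:
        raise ValueError("empty selection curve")
    best = max(r2 for _, r2 in curve)
    return max(nf for nf, r2 in curve if r2 >= best - tolerance)


def greedy_channel_selection(
    df: pd.DataFrame,
    channel: int,
    label_column: str,
    folds: int = 5,
    grouping: str = "sample",
    seed: int = DEFAULT_SEED,
    svr_params: dict | None = None,
    tolerance: float = DEFAULT_INFLECTION_TOL,
) -> SelectionTrace:
    """Greedy forward selection over one channel's 11 feature groups.

    At each step every remaining group is tried in combination with the
    groups already chosen (11 + 10 + ... + 1 = 66 cross-validated fits in
    total); ties go to the lowest group index.
    """
    order: list[int] = []
    chosen_cols: list[str] = []
    curve: list[tuple[int, float]] = []
    remaining = list(range(1, N_GROUPS + 1))
    n_fits = 0
    while remaining:
        best_group, best_r2 = None, None
        for g in remaining:  # ascending, so ties keep the lowest index
            cols = chosen_cols + group_columns(channel, g)
            res = fit_cv(df, label_column, feature_columns=cols, folds=folds,
                         grouping=grouping, seed=seed, svr_params=svr_params)
            n_fits += 1
            if best_r2 is None or res.mean_r2 > best_r2:
                best_group, best_r2 = g, res.mean_r2
        order.append(best_group)
        remaining.remove(best_group)
        chosen_cols = chosen_cols + group_columns(channel, best_group)
        curve.append((len(chosen_cols), best_r2))
    nf_star = inflection_point(curve, tolerance)
    reserved = set(order[: nf_star // GROUP_SIZE])
    return SelectionTrace(channel=channel, order_added=order, curve=curve,
                          inflection_nf=nf_star, reserved_groups=reserved,
                          n_fits=n_fits)


def reduced_feature_columns(traces: list[SelectionTrace]) -> list[str]:
    """Union of every channel's reserved features, in feature order.

    Its size equals the sum of the per-channel inflection NFs.
    """
    cols: list[str] = []
    for trace in sorted(traces, key=lambda t: t.channel):
        cols.extend(trace.reserved_columns)
    return cols


def combine_channels(
    traces: list[SelectionTrace],
    df: pd.DataFrame,
    label_column: str,
    folds: int = 5,
    grouping: str = "sample",
    seed: int = DEFAULT_SEED,
    svr_params: dict | None = None,
) -> tuple[list[str], CVResult]:
    """Refit on the combined reduced feature set from all channels."""
    if len({t.channel for t in traces}) != len(traces):
        raise ValueError("need exactly one trace per channel")
    cols = reduced_feature_columns(traces)
    result = fit_cv(df, label_column, feature_columns=cols, folds=folds,
                    grouping=grouping, seed=seed, svr_params=svr_params)
    return cols, result
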