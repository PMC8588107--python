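"""Multi-subject analysis: model performance across subject combinations.

For a pool of subjects, a dataset is built for every nonempty subset (a
5-subject pool gives 31), the cross-validated model is fit on each, and
R²_NS — the mean R² over all subsets of size NS — traces how performance
changes as subject diversity grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .model_eval import DEFAULT_SEED, fit_cv


@dataclass(frozen=True)
class CombinationResult:
    """CV outcome on the pooled data of one subject subset."""

    subjects: tuple[str, ...]
    ns: int
    mean_r2: float


def subject_combinations(pool: list[str]) -> list[tuple[str, ...]]:
    """All nonempty subject subsets, ordered by size then lexicographically."""
    if not pool:
        raise ValueError("subject pool is empty")
    ordered = sorted(pool)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        out.extend(combinations(ordered, size))
    return out


def r2_ns_curve(
    df: pd.DataFrame,
    label_column: str,
    taste: str | None = None,
    feature_columns: list[str] | None = None,
    folds: int = 5,
    grouping: str = "sample",
    seed: int = DEFAULT_SEED,
    svr_params: dict | None = None,
) -> tuple[dict[int, float], list[CombinationResult]]:
    """Mean CV R² per pool size over every subject combination.

    The feature table must carry a ``subject`` column; ``taste`` restricts
    to one taste's rows first.  Returns ({NS: R²_NS}, per-subset results);
    a pool of P subjects costs 2^P - 1 cross-validated fits.
    """
    if "subject" not in df.columns:
        raise ValueError("feature table needs a 'subject' column")
    work = df if taste is None else df[df["taste"] == taste]
    pool = sorted(work["subject"].unique())
    results: list[CombinationResult] = []
    for combo in subject_combinations(pool):
        sub = work[work["subject"].isin(combo)]
        res = fit_cv(sub, label_column, feature_columns=feature_columns,
                     folds=folds, grouping=grouping, seed=seed,
                     svr_params=svr_params)
        results.append(CombinationResult(subjects=combo, ns=len(combo),
                                         mean_r2=res.mean_r2))
    curve: dict[int, float] = {}
    for ns in range(1, len(pool) + 1):
        scores = [r.mean_r2 for r in results if r.ns == ns]
        curve[ns] = sum(scores) / len(scores)
    return curve, results
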