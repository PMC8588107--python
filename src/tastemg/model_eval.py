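"""Epsilon-SVR (RBF kernel) with five-fold cross-validation, scored by R².

The coefficient of determination,

    R² = 1 - Σ(ŷ_i - y_i)² / Σ(ȳ - y_i)²,

ranges over (-inf, 1]: 1 is a perfect fit, 0 no better than predicting
the mean.  Features are standardized per training fold (the scaler never
sees the held-out fold) before the support-vector fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import feature_names

#: Default SVR hyperparameters: C=1, epsilon=0.1, gamma = 1/(d * var(X))
#: after standardization (sklearn's "scale").
DEFAULT_SVR_PARAMS: dict = {"C": 1.0, "epsilon": 0.1, "gamma": "scale"}

DEFAULT_SEED = 42


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination of predictions against targets.

    Undefined (raises) for constant targets or fewer than two samples.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and the same length")
    if y_true.size < 2:
        raise ValueError("R² needs at least two samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² is undefined for a constant target")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVResult:
    """Outcome of one cross-validated fit."""

    fold_scores: np.ndarray  # per-fold held-out R²
    mean_r2: float
    fold_assignment: np.ndarray  # fold index per row of the input table
    model_params: dict
    scaling_params: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    feature_columns: list[str] = field(default_factory=list)
    seed: int = DEFAULT_SEED
    grouping: str = "sample"


def _assign_folds(
    df: pd.DataFrame, folds: int, grouping: str, rng: np.random.Generator
) -> np.ndarray:
    n = len(df)
    fold_of = np.empty(n, dtype=int)
    if grouping == "sample":
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % folds
    elif grouping == "trial":
        if "trial_id" not in df.columns:
            raise ValueError("trial grouping needs a 'trial_id' column")
        trials = np.asarray(sorted(df["trial_id"].unique()))
        perm = rng.permutation(len(trials))
        trial_fold = dict(zip(trials[perm], np.arange(len(trials)) % folds))
        fold_of[:] = df["trial_id"].map(trial_fold).to_numpy()
    else:
        raise ValueError("grouping must be 'sample' or 'trial'")
    return fold_of


def fit_cv(
    df: pd.DataFrame,
    label_column: str,
    feature_columns: list[str] | None = None,
    folds: int = 5,
    grouping: str = "sample",
    seed: int = DEFAULT_SEED,
    svr_params: dict | None = None,
) -> CVResult:
    """Cross-validated RBF-kernel support-vector regression on a feature table.

    ``grouping='sample'`` shuffles windows freely into folds (the study's
    default); ``grouping='trial'`` keeps all windows of one trial in one
    fold, so overlapping windows never leak between train and test.
    Constant feature columns are dropped with a warning; rows with missing
    feature values (flagged windows) are dropped with a warning.
    """
    if feature_columns is None:
        feature_columns = [c for c in feature_names() if c in df.columns]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in table")
    if len(df) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")

    work = df.reset_index(drop=True)
    X = work[feature_columns].to_numpy(dtype=float)
    y = work[label_column].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant label: nothing to regress")

    bad_rows = ~np.all(np.isfinite(X), axis=1)
    if bad_rows.any():
        warnings.warn(f"dropping {bad_rows.sum()} rows with missing feature values",
                      stacklevel=2)
        keep = ~bad_rows
        work, X, y = work[keep].reset_index(drop=True), X[keep], y[keep]

    const = np.ptp(X, axis=0) == 0
    if const.any():
        dropped = [c for c, b in zip(feature_columns, const) if b]
        warnings.warn(f"dropping {len(dropped)} constant feature column(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                      stacklevel=2)
        feature_columns = [c for c, b in zip(feature_columns, const) if not b]
        X = X[:, ~const]

    params = dict(DEFAULT_SVR_PARAMS)
    if svr_params:
        params.update(svr_params)

    rng = np.random.default_rng(seed)
    fold_of = _assign_folds(work, folds, grouping, rng)

    scores = []
    scalers: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(folds):
        test = fold_of == k
        model = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **params))])
        model.fit(X[~test], y[~test])
        scaler: StandardScaler = model.named_steps["scale"]
        scalers.append((scaler.mean_.copy(), scaler.scale_.copy()))
        scores.append(r2_score(y[test], model.predict(X[test])))

    scores = np.asarray(scores)
    return CVResult(
        fold_scores=scores,
        mean_r2=float(scores.mean()),
        fold_assignment=fold_of,
        model_params=params,
        scaling_params=scalers,
        feature_columns=list(feature_columns),
        seed=seed,
        grouping=grouping,
    )
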