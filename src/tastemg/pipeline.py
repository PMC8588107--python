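"""End-to-end assembly: raw trials -> labeled window feature table.

The feature table is the common currency of the downstream analyses: one
row per kept window, metadata and the three intensity labels first, then
feature columns f001..f330 in the documented channel-major order.
"""

from __future__ import annotations

import pandas as pd

from . import features as feat
from .labels import relative_concentration, strength_label
from .preprocess import preprocess_trial
from .synthetic import RawTrial

METADATA_COLUMNS = [
    "trial_id", "subject", "session", "taste", "concentration", "window_offset",
    "strength_label", "relative_concentration", "scale_score",
]


def feature_table(trials: list[RawTrial], **preprocess_kwargs) -> pd.DataFrame:
    """Preprocess every trial and extract features from each kept window.

    Keyword arguments are forwarded to :func:`preprocess_trial` (window
    and step length, QVR lambda, notch settings, rejection threshold).
    """
    rows = []
    cols = feat.feature_names()
    for trial in trials:
        kept, _reports, _n_rej = preprocess_trial(trial, **preprocess_kwargs)
        s = trial.stimulus
        meta = {
            "trial_id": trial.trial_id,
            "subject": trial.subject_id,
            "session": trial.session,
            "taste": s.taste_type,
            "concentration": s.concentration,
            "strength_label": strength_label(s),
            "relative_concentration": relative_concentration(s),
            "scale_score": trial.scale_score,
        }
        for w in kept:
            row = dict(meta, window_offset=w.window_offset)
            row.update(zip(cols, feat.extract(w)))
            rows.append(row)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + cols)
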