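"""Plain-text trial store: one delimited signal table per trial plus a
dataset-level metadata table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import StimulusSpec
from .synthetic import RawTrial

_META_COLUMNS = ["trial_id", "subject", "session", "taste", "concentration",
                 "intensity_index", "scale_score", "sampling_rate", "path"]


def save_trials(trials: list[RawTrial], outdir: str | Path) -> Path:
    """Write trials as TSV (rows = samples, columns = channels) plus
    ``metadata.tsv``; returns the metadata path."""
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    records = []
    for t in trials:
        rel = f"signals/{t.trial_id}.tsv"
        frame = pd.DataFrame(t.signal.T,
                             columns=[f"ch{i}" for i in range(1, t.signal.shape[0] + 1)])
        frame.to_csv(outdir / rel, sep="\t", index=False, float_format="%.6g")
        s = t.stimulus
        records.append(dict(zip(_META_COLUMNS, [
            t.trial_id, t.subject_id, t.session, s.taste_type, s.concentration,
            s.intensity_index, t.scale_score, t.sampling_rate, rel,
        ])))
    meta_path = outdir / "metadata.tsv"
    pd.DataFrame(records, columns=_META_COLUMNS).to_csv(meta_path, sep="\t", index=False)
    return meta_path


def load_trials(indir: str | Path) -> list[RawTrial]:
    """Read a trial store written by :func:`save_trials`."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    trials = []
    for rec in meta.to_dict("records"):
        sig = pd.read_csv(indir / rec["path"], sep="\t").to_numpy(dtype=float).T
        stim = StimulusSpec(rec["taste"], float(rec["concentration"]),
                            int(rec["intensity_index"]))
        trials.append(RawTrial(signal=np.ascontiguousarray(sig), stimulus=stim,
                               subject_id=str(rec["subject"]),
                               session=int(rec["session"]),
                               scale_score=float(rec["scale_score"]),
                               sampling_rate=float(rec["sampling_rate"])))
    return trials
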