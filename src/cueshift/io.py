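"""Reading and writing the pipeline's file formats.

Trial tables are plain CSV with columns
``subject_id,image_id,stimulus_class,cue,rating``.  Fit collections are
JSON lists.  EEG epochs are HDF5 files with datasets ``/data``
(trials x channels x samples), ``/labels`` and ``/condition`` plus
``sfreq``, ``window_ms`` and ``baseline_ms`` attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .simulate import EegEpochs

TRIAL_COLUMNS = ["subject_id", "image_id", "stimulus_class", "cue", "rating"]


def write_trials(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df


def write_fits(fits, path) -> None:
    """Serialize an iterable of MixtureFit (or dicts) to JSON."""
    rows = [f if isinstance(f, dict) else f.to_dict() for f in fits]
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1, default=float)


def read_fits(path) -> list:
    with open(path) as fh:
        return json.load(fh)


def write_epochs(epochs: EegEpochs, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype="S"))
        f.create_dataset("condition", data=np.asarray(epochs.condition, dtype="S"))
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["window_ms"] = epochs.window_ms
        f.attrs["baseline_ms"] = epochs.baseline_ms


def read_epochs(path) -> EegEpochs:
    with h5py.File(path, "r") as f:
        return EegEpochs(
            data=f["data"][()],
            labels=f["labels"][()].astype(str),
            condition=f["condition"][()].astype(str),
            sfreq=float(f.attrs["sfreq"]),
            window_ms=tuple(f.attrs["window_ms"]),
            baseline_ms=tuple(f.attrs["baseline_ms"]),
        )
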