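"""Reading and writing recordings.

Synthetic recordings are written to a plain CSV dialect: first column
``time_s``, one column per channel named by its 10-20 montage label.
Clinical-style EDF/EDF+ files are read through :mod:`mne`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from neurocx.synthetic import STANDARD_1020_19, Recording


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Write one recording as CSV: time_s column plus one column per channel."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.fs
    frame = pd.DataFrame({"time_s": t})
    for label, row in zip(recording.channel_labels, recording.data):
        frame[label] = row
    frame.to_csv(path, index=False, float_format="%.8g")
    return path


def _validate_labels(labels: list[str], allow_nonstandard: bool) -> None:
    unknown = [lb for lb in labels if lb not in STANDARD_1020_19]
    if unknown and not allow_nonstandard:
        raise ValueError(
            f"channel labels not in the standard 10-20 set: {unknown}; "
            "pass allow_nonstandard=True to accept them"
        )


def read_recording_csv(
    path: str | Path,
    *,
    subject_id: str | None = None,
    group: str = "",
    allow_nonstandard: bool = False,
) -> Recording:
    """Read a recording from the CSV dialect written by :func:`write_recording_csv`.

    The sampling rate is inferred from the time column.  Channel labels
    are validated against the 10-20 montage unless ``allow_nonstandard``.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    t = frame["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    labels = [c for c in frame.columns if c != "time_s"]
    _validate_labels(labels, allow_nonstandard)
    data = frame[labels].to_numpy().T
    return Recording(
        subject_id=subject_id if subject_id is not None else path.stem,
        group=group,
        data=data,
        fs=float(fs),
        channel_labels=tuple(labels),
    )


def read_recording_edf(
    path: str | Path,
    *,
    subject_id: str | None = None,
    group: str = "",
    allow_nonstandard: bool = False,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` via mne."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    _validate_labels(labels, allow_nonstandard)
    return Recording(
        subject_id=subject_id if subject_id is not None else path.stem,
        group=group,
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(labels),
    )


def read_recording(path: str | Path, **kwargs) -> Recording:
    """Dispatch on file extension: .edf -> EDF reader, otherwise CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, **kwargs)
    return read_recording_csv(path, **kwargs)
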