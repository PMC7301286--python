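"""Band-pass filtering, fixed-offset epoch extraction, amplitude rejection.

The epoching scheme follows the acquisition protocol of 3-minute
resting recordings sampled at 1 kHz: three 5-second segments taken at
fixed offsets (samples 25,000 / 85,000 / 145,000 by default), giving
three 5,000-sample epochs per channel.  Windows are half-open
``[offset, offset + length)`` in 0-based indexing, so "samples
25,000-30,000" yields exactly 5,000 samples.

Ocular-artifact removal by ICA is deliberately not re-implemented; a
peak-amplitude rejection hook stands in for it, and real data should be
ICA-cleaned with existing tooling (e.g. mne) before entering the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class EpochSpec:
    """Fixed epoch windows: start offsets (samples) and common length."""

    offsets: tuple[int, ...] = (25_000, 85_000, 145_000)
    length: int = 5_000

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("epoch length must be positive")
        offs = tuple(int(o) for o in self.offsets)
        if any(o < 0 for o in offs):
            raise ValueError("offsets must be non-negative")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("offsets must be strictly increasing")
        object.__setattr__(self, "offsets", offs)


@dataclass
class Epoch:
    """One channel's fixed-length segment with provenance."""

    subject_id: str
    group: str
    channel_label: str
    epoch_index: int
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be a 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite values")


def bandpass_filter(
    signal: np.ndarray, fs: float, f_lo: float = 0.5, f_hi: float = 70.0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    A 4th-order Butterworth filter applied forward-backward
    (``sosfiltfilt``), so the output has no phase distortion and the
    effective attenuation one octave outside the passband exceeds
    20 dB.  Output length equals input length.

    The reflect padding spans about three time constants of the f_lo
    corner; a low corner such as 0.5 Hz still rings for a few seconds
    at the record edges, so epochs should be cut well inside a filtered
    recording (the default epoch offsets start 25 s in).
    """
    if not 0.0 < f_lo < f_hi:
        raise ValueError(f"need 0 < f_lo < f_hi, got {f_lo}, {f_hi}")
    if f_hi >= fs / 2.0:
        raise ValueError(f"f_hi={f_hi} must be below the Nyquist rate {fs / 2}")
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    padlen = int(min(x.size - 1, 3.0 * fs / f_lo))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def filter_recording(recording, f_lo: float = 0.5, f_hi: float = 70.0):
    """Return a copy of the recording with every channel band-passed."""
    from neurocx.synthetic import Recording

    filtered = np.vstack(
        [bandpass_filter(row, recording.fs, f_lo, f_hi) for row in recording.data]
    )
    return Recording(
        subject_id=recording.subject_id,
        group=recording.group,
        data=filtered,
        fs=recording.fs,
        channel_labels=recording.channel_labels,
    )


def extract_epochs(recording, spec: EpochSpec | None = None) -> list[Epoch]:
    """Cut one epoch per (channel, offset) from a recording.

    Slicing is exact — no filtering or detrending happens here — so the
    concatenation of extracted samples reproduces the source slices.

    Raises
    ------
    ValueError
        If the recording is shorter than ``offset + length`` for any
        offset; the error names the offending offset.
    """
    spec = spec if spec is not None else EpochSpec()
    n = recording.n_samples
    for off in spec.offsets:
        if off + spec.length > n:
            raise ValueError(
                f"recording shorter than epoch window: offset {off} + "
                f"length {spec.length} exceeds {n} samples"
            )
    epochs: list[Epoch] = []
    for label, row in zip(recording.channel_labels, recording.data):
        for idx, off in enumerate(spec.offsets):
            epochs.append(
                Epoch(
                    subject_id=recording.subject_id,
                    group=recording.group,
                    channel_label=label,
                    epoch_index=idx,
                    samples=row[off : off + spec.length].copy(),
                    fs=recording.fs,
                )
            )
    return epochs


def reject_epochs(
    epochs: list[Epoch], amplitude_limit: float
) -> tuple[list[Epoch], list[Epoch]]:
    """Partition epochs by peak absolute amplitude.

    Epochs whose ``max |x|`` exceeds ``amplitude_limit`` go to the
    rejected list; the partition is exhaustive and disjoint.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive")
    kept, rejected = [], []
    for ep in epochs:
        if np.max(np.abs(ep.samples)) > amplitude_limit:
            rejected.append(ep)
        else:
            kept.append(ep)
    return kept, rejected
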