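"""Welch band power in the low-alpha, high-alpha and beta bands."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from neurocx.complexity import FEATURE_COLUMNS


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got {self.f_lo}, {self.f_hi}")


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("low_alpha", 8.0, 10.0),
    Band("high_alpha", 10.0, 12.0),
    Band("beta", 13.0, 30.0),
)


def welch_psd(
    signal: np.ndarray, fs: float, window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with Hann windows and 50% overlap.

    The 2-s default window gives 0.5 Hz resolution, so the Hann main
    lobe of an on-bin alpha tone stays inside a 2-Hz band (a 1-s
    window leaks a sixth of a 9 Hz tone's power into the neighbouring
    band).
    """
    x = np.asarray(signal, dtype=float)
    nperseg = min(int(round(window_s * fs)), x.size)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")


def band_power(
    signal: np.ndarray, fs: float, band: Band, window_s: float = 2.0
) -> float:
    """Integrated Welch PSD over the half-open band [f_lo, f_hi).

    Power is absolute (not relative) and, because of the constant
    detrend, invariant to the signal mean.  Bands partitioning
    [0, Nyquist) sum to the total Welch power.
    """
    if band.f_hi >= fs / 2.0 + 1e-12:
        # allow f_hi == Nyquist so band partitions can close the axis
        if band.f_hi > fs / 2.0 + 1e-12:
            raise ValueError(
                f"band {band.name} [{band.f_lo}, {band.f_hi}) exceeds "
                f"the Nyquist rate {fs / 2}"
            )
    x = np.asarray(signal, dtype=float)
    if x.size < 2.0 * fs:
        raise ValueError(f"need at least 2 s of signal, got {x.size / fs:.3g} s")
    freqs, psd = welch_psd(x, fs, window_s)
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    return float(psd[mask].sum() * df)


def band_power_table(
    epochs, bands: tuple[Band, ...] = DEFAULT_BANDS, window_s: float = 2.0
) -> pd.DataFrame:
    """One feature row per (epoch, band), same long format as complexity."""
    rows = []
    for ep in epochs:
        for band in bands:
            rows.append(
                (
                    ep.subject_id,
                    ep.group,
                    ep.channel_label,
                    ep.epoch_index,
                    band.name,
                    band_power(ep.samples, ep.fs, band, window_s),
                    True,
                )
            )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
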