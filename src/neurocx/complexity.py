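"""Higuchi fractal dimension and sample entropy.

These two time-domain complexity measures are the analytical core of
the package.

**Higuchi's fractal dimension (HFD).**  For a series X(1..N) and delay
k, the normalised curve length of the subsequence starting at offset m
(1-based, 1 <= m <= k) is

    L_m(k) = [ sum_{i=1..M} |X(m+ik) - X(m+(i-1)k)| ] * (N-1) / (M k) / k,

with M = floor((N-m)/k).  L(k) is the mean of L_m(k) over m = 1..k, and
the fractal dimension is the slope of the ordinary least-squares line
of ln L(k) against ln(1/k) for k = 1..k_max.  A smooth curve gives
FD = 1, plane-filling noise FD = 2; for fractional Gaussian noise with
Hurst exponent H the theoretical value is 2 - H.

**Sample entropy (SampEn).**  With template length m and tolerance r,
B counts unordered pairs of length-m templates within Chebyshev
distance r, A the same at length m+1; both counts run over the same
N - m template start positions and exclude self-matches.  SampEn is
-ln(A/B), the negative log conditional probability that sequences close
for m points stay close at the next point.  Here r = 0.15 x the epoch's
(population) standard deviation and m = 2 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit


@dataclass(frozen=True)
class HiguchiParams:
    """k_max: largest delay of the Higuchi log-log regression (default 8)."""

    k_max: int = 8

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


@dataclass(frozen=True)
class SampEnParams:
    """Template length m (default 2) and tolerance multiplier of the SD."""

    m: int = 2
    r_factor: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


@dataclass(frozen=True)
class ComplexityValue:
    """A single measure value; ``defined`` is False when SampEn has no matches."""

    measure: str  # "HFD" or "SampEn"
    value: float
    defined: bool = True


def higuchi_curve_length(signal: np.ndarray, k: int, m_offset: int) -> float:
    """Normalised Higuchi curve length L_m(k).

    ``m_offset`` is 1-based (1 <= m_offset <= k), matching the original
    algorithm's indexing; M = floor((N - m_offset)/k) decimated steps
    are summed and rescaled by (N-1)/(M k) and divided by k.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if not 1 <= m_offset <= k:
        raise ValueError(f"m_offset must lie in [1, k]={k}, got {m_offset}")
    n_steps = (n - m_offset) // k
    if n_steps < 1:
        raise ValueError(
            f"subsequence too short: N={n}, k={k}, m_offset={m_offset}"
        )
    sub = x[m_offset - 1 :: k][: n_steps + 1]
    total = np.abs(np.diff(sub)).sum()
    return float(total * (n - 1) / (n_steps * k) / k)


def higuchi_fd(
    signal: np.ndarray, params: HiguchiParams | None = None
) -> ComplexityValue:
    """Higuchi fractal dimension via the log-log slope over k = 1..k_max.

    L(k) averages L_m(k) over the k offsets; FD is the OLS slope of
    ln L(k) on ln(1/k) (natural log, unweighted).  A constant signal has
    L(k) = 0 for every k and is returned as undefined.
    """
    params = params if params is not None else HiguchiParams()
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n <= 2 * params.k_max:
        raise ValueError(f"need N > 2*k_max = {2 * params.k_max}, got N={n}")
    ks = np.arange(1, params.k_max + 1)
    lengths = np.array(
        [
            np.mean([higuchi_curve_length(x, k, m) for m in range(1, k + 1)])
            for k in ks
        ]
    )
    if np.any(lengths <= 0):
        return ComplexityValue("HFD", float("nan"), defined=False)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)[0]
    return ComplexityValue("HFD", float(slope))


@njit
def _sampen_counts_kernel(x: np.ndarray, m: int, r: float):  # pragma: no cover
    n = x.shape[0]
    n_templates = n - m
    a = 0
    b = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d = 0.0
            for t in range(m):
                diff = abs(x[i + t] - x[j + t])
                if diff > d:
                    d = diff
                if d > r:
                    break
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sampen_counts(signal: np.ndarray, m: int, r_absolute: float) -> tuple[int, int]:
    """Template match counts (A, B) for sample entropy.

    Both counts run over the same N - m start positions: B counts
    unordered pairs i < j whose length-m templates are within Chebyshev
    distance ``r_absolute`` (closed tolerance, <= r), A the pairs still
    within r at template length m + 1.  Self-matches are excluded by
    i < j.  The inner loop is numba-compiled so a 5,000-sample epoch
    evaluates in well under a second.
    """
    x = np.ascontiguousarray(signal, dtype=np.float64)
    n = x.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m + 1:
        raise ValueError(f"need N > m + 1, got N={n}, m={m}")
    if r_absolute < 0:
        raise ValueError("r_absolute must be non-negative")
    a, b = _sampen_counts_kernel(x, m, float(r_absolute))
    return int(a), int(b)


def sample_entropy(
    signal: np.ndarray, params: SampEnParams | None = None
) -> ComplexityValue:
    """Sample entropy -ln(A/B) with r = r_factor x population SD.

    Undefined (flagged) when A or B is zero.  A constant signal yields
    r = 0 with all templates matching exactly, hence SampEn = 0.
    """
    params = params if params is not None else SampEnParams()
    x = np.asarray(signal, dtype=float)
    r = params.r_factor * float(np.std(x))
    a, b = sampen_counts(x, params.m, r)
    if a == 0 or b == 0:
        return ComplexityValue("SampEn", float("nan"), defined=False)
    return ComplexityValue("SampEn", float(-np.log(a / b)))


FEATURE_COLUMNS = ("subject", "group", "channel", "epoch", "measure", "value", "defined")


def features_for_epochs(
    epochs,
    hfd_params: HiguchiParams | None = None,
    sampen_params: SampEnParams | None = None,
) -> pd.DataFrame:
    """Long-format feature table: one HFD and one SampEn row per epoch.

    Columns: subject, group, channel, epoch, measure, value, defined.
    Undefined values carry ``defined=False`` and NaN, never a
    fabricated number.
    """
    rows = []
    for ep in epochs:
        for cv in (
            higuchi_fd(ep.samples, hfd_params),
            sample_entropy(ep.samples, sampen_params),
        ):
            rows.append(
                (
                    ep.subject_id,
                    ep.group,
                    ep.channel_label,
                    ep.epoch_index,
                    cv.measure,
                    cv.value,
                    cv.defined,
                )
            )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
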