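import numpy as np
import pytest

from neurocx.synthetic import Recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def white_recording():
    """19-channel, 12 s @ 1 kHz white-noise recording (cheap stand-in)."""
    gen = np.random.default_rng(7)
    from neurocx.synthetic import STANDARD_1020_19

    return Recording(
        subject_id="S0",
        group="C",
        data=gen.standard_normal((19, 12_000)),
        fs=1000.0,
        channel_labels=STANDARD_1020_19,
    )


def brute_sampen_counts(x, m, r):
    """O(N^2) reference for SampEn match counts via numpy broadcasting.

    Independent of the compiled kernel: builds the full pairwise
    Chebyshev distance matrices for template lengths m and m+1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    nt = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    dm = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    dm1 = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    iu = np.triu_indices(nt, k=1)
    b = int(np.count_nonzero(dm[iu] <= r))
    a = int(np.count_nonzero(dm1[iu] <= r))
    return a, b


def anova_by_sums_of_squares(groups):
    """Hand one-way ANOVA oracle from between/within sums of squares."""
    from scipy.stats import f as fdist

    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = allv.size - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, dfb, dfw, float(fdist.sf(f, dfb, dfw))
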