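"""Group-level statistics: log10 normalisation, Kolmogorov-Smirnov
normality check, one-way ANOVA with Bonferroni post hoc (globally and
per electrode), and PCA separability of the complexity features.

The analysis ensemble follows the study design: every (subject, epoch,
channel) value enters as one observation, which treats epochs of a
subject as independent — a documented simplification of the original
analysis, whose degrees of freedom imply the same choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA: F statistic, degrees of freedom, p-value."""

    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PcaResult:
    """Top-3 principal components of the sample covariance matrix.

    ``loadings`` is variables x k with orthonormal columns, ``scores``
    observations x k, and ``explained_variance_ratio`` the ratio of the
    retained eigenvalue sum to the total variance of the original
    variables.  ``rank_deficient`` flags inputs with rank < 3, for
    which fewer components are returned.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: float
    eigenvalues: np.ndarray
    rank_deficient: bool = False


def log10_normalize(values) -> np.ndarray:
    """Elementwise base-10 logarithm; rejects non-positive input.

    Raises a ValueError naming the offending positions, since zero
    SampEn epochs must be excluded (or offset) upstream rather than
    silently dropped here.
    """
    x = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(
            f"log10 normalization requires positive values; offending "
            f"rows (first 10): {bad[:10].tolist()}"
        )
    return np.log10(x)


def ks_normality(
    values, mean: float | None = None, sd: float | None = None
) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal reference.

    By default the reference normal uses the sample's own mean and SD
    (a Lilliefors-style plug-in, so the p-value is approximate and
    anti-conservative); pass ``mean``/``sd`` for a fixed reference.
    Returns (D, p) where D = sup |F_emp - F_ref|.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    mu = float(np.mean(x)) if mean is None else float(mean)
    sigma = float(np.std(x, ddof=1)) if sd is None else float(sd)
    if not sigma > 0:
        raise ValueError("zero-variance sample: KS reference is degenerate")
    res = sstats.kstest(x, "norm", args=(mu, sigma))
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Standard between/within sums-of-squares one-way ANOVA."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    f, p = sstats.f_oneway(*arrays)
    n_total = sum(g.size for g in arrays)
    return AnovaResult(
        F=float(f),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p=float(p),
    )


def bonferroni_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise pooled-variance t-tests with Bonferroni adjustment.

    Each raw two-sided p is multiplied by C(n_groups, 2) and capped at
    1.  Columns: group_a, group_b, mean_difference, p_raw, p_adjusted,
    significant.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    labels = labels if labels is not None else [str(i) for i in range(len(arrays))]
    n_comp = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(arrays), 2):
        t = sstats.ttest_ind(a, b, equal_var=True)
        p_adj = min(1.0, float(t.pvalue) * n_comp)
        rows.append(
            {
                "group_a": labels[ia],
                "group_b": labels[ib],
                "mean_difference": float(np.mean(a) - np.mean(b)),
                "p_raw": float(t.pvalue),
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def _ensemble_values(
    table: pd.DataFrame, measure: str, log10: bool
) -> pd.DataFrame:
    sub = table[(table["measure"] == measure) & table["defined"]].copy()
    if log10:
        sub = sub[sub["value"] > 0]
        sub["value"] = np.log10(sub["value"])
    return sub

def global_anova(
    table: pd.DataFrame,
    measure: str,
    alpha: float = 0.05,
    log10: bool = True,
    aggregate: str = "none",
) -> tuple[AnovaResult, pd.DataFrame]:
    """Whole-scalp ANOVA + post hoc over the feature ensemble.

    ``aggregate="none"`` (default) enters every (subject, epoch,
    channel) value as one observation; ``aggregate="channels"``
    averages over electrodes first, so each (subject, epoch) pair is
    one observation — with 42 subjects and 3 epochs that yields the
    126-unit ensemble whose ANOVA has df = (2, 123).
    """
    if aggregate not in ("none", "channels"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    sub = _ensemble_values(table, measure, log10)
    if aggregate == "channels":
        sub = (
            sub.groupby(["subject", "group", "epoch"], as_index=False)["value"]
            .mean()
        )
    labels = sorted(sub["group"].unique())
    groups = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in labels]
    return one_way_anova(groups), bonferroni_posthoc(groups, labels, alpha)


def per_electrode_anova(
    table: pd.DataFrame,
    measure: str,
    alpha: float = 0.05,
    log10: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """ANOVA + Bonferroni post hoc repeated independently per channel.

    Returns (anova table keyed by channel, post hoc table keyed by
    channel, channels significant for *all* pairwise contrasts — the
    full-ordering criterion).  Raises if any channel lacks a group.
    """
    sub = _ensemble_values(table, measure, log10)
    if sub.empty:
        raise ValueError(f"no defined values for measure {measure!r}")
    labels = sorted(sub["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    missing = []
    for ch, chunk in sub.groupby("channel", sort=False):
        present = set(chunk["group"].unique())
        missing.extend((ch, g) for g in labels if g not in present)
    if missing:
        raise ValueError(f"missing channel/group cells: {missing}")

    anova_rows, posthoc_frames, all_sig = [], [], []
    for ch in sub["channel"].unique():
        chunk = sub[sub["channel"] == ch]
        groups = [chunk.loc[chunk["group"] == g, "value"].to_numpy() for g in labels]
        res = one_way_anova(groups)
        anova_rows.append(
            {
                "channel": ch,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
            }
        )
        ph = bonferroni_posthoc(groups, labels, alpha)
        ph.insert(0, "channel", ch)
        posthoc_frames.append(ph)
        if bool(ph["significant"].all()):
            all_sig.append(ch)
    return (
        pd.DataFrame(anova_rows),
        pd.concat(posthoc_frames, ignore_index=True),
        all_sig,
    )


def feature_matrix(
    table: pd.DataFrame, measures: list[str] | None = None
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Pivot the long feature table into observations x variables.

    Observations are (subject, epoch) pairs; variables are
    (channel, measure) combinations — the layout used for PCA.
    Returns (matrix, observation index frame, variable names).
    Rows with any undefined value are dropped listwise.
    """
    sub = table[table["defined"]].copy()
    if measures is not None:
        sub = sub[sub["measure"].isin(measures)]
    wide = sub.pivot_table(
        index=["subject", "group", "epoch"],
        columns=["channel", "measure"],
        values="value",
    )
    n_before = len(wide)
    wide = wide.dropna(axis=0, how="any")
    if len(wide) < n_before:
        import warnings

        warnings.warn(
            f"dropped {n_before - len(wide)} observation rows with "
            "undefined feature values",
            stacklevel=2,
        )
    obs = wide.index.to_frame(index=False)
    variables = [f"{ch}:{ms}" for ch, ms in wide.columns]
    return wide.to_numpy(), obs, variables


def pca_top3(matrix: np.ndarray, n_components: int = 3) -> PcaResult:
    """PCA by eigendecomposition of the sample covariance matrix.

    Columns are mean-centred (not scaled); the top ``n_components``
    eigenvectors give loadings and scores, and the explained variance
    ratio is the retained eigenvalue sum over the total variance of the
    original variables.  Rank-deficient inputs return the available
    components with ``rank_deficient=True``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be observations x variables")
    n, p = x.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    if p < n_components:
        raise ValueError(f"need at least {n_components} variables, got {p}")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite values")
    centered = x - x.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    total = eigvals.sum()
    tol = max(n, p) * np.finfo(float).eps * max(eigvals[0], 1.0)
    rank = int(np.sum(eigvals > tol))
    k = min(n_components, rank) if rank > 0 else 1
    loadings = eigvecs[:, :k]
    return PcaResult(
        loadings=loadings,
        scores=centered @ loadings,
        explained_variance_ratio=float(eigvals[:k].sum() / total) if total > 0 else 1.0,
        eigenvalues=eigvals,
        rank_deficient=rank < n_components,
    )


def group_scatter_ratio(scores: np.ndarray, groups) -> float:
    """Between-group / within-group scatter of PCA scores.

    Ratio of the trace of the between-group scatter matrix (weighted by
    group size) to the trace of the pooled within-group scatter; values
    above 1 indicate visible group separation in the score space.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    grand = scores.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in np.unique(groups):
        sub = scores[groups == g]
        mu = sub.mean(axis=0)
        between += sub.shape[0] * float(np.sum((mu - grand) ** 2))
        within += float(np.sum((sub - mu) ** 2))
    if within == 0:
        return float("inf")
    return between / within
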