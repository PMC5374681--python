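"""Evaluation machinery: per-stratum descriptive statistics, a two-group
rank test, per-filter ROC/AUC and post-filtering selection reports.

Descriptive statistics follow the replicate-median convention: the
median of each replicate's values is taken first, then the mean and
sample standard deviation across replicates, so replicate is the unit
of summarization.  Undefined statistics (empty groups, single
replicates) are reported as NaN markers rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata

from .annotations import FEATURE_NAMES


def median_of_replicates(
    values, replicate_ids
) -> tuple[pd.Series, float, float]:
    """Per-replicate medians, then their mean and sample sd (ddof=1).

    Returns ``(medians, mean, sd)``; ``sd`` is NaN with a single
    replicate, and both are NaN with no data at all.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    r = pd.Series(np.asarray(replicate_ids))
    if len(s) == 0:
        return pd.Series(dtype=float), float("nan"), float("nan")
    medians = s.groupby(r).median()
    mean = float(medians.mean())
    sd = float(medians.std(ddof=1)) if len(medians) > 1 else float("nan")
    return medians, mean, sd


def _kw_statistic(ranks: np.ndarray, n1: int, tie_correction: float) -> float:
    """Tie-corrected two-group Kruskal-Wallis H from pooled midranks."""
    n = len(ranks)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    n2 = n - n1
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / n2) - 3.0 * (n + 1)
    return h / tie_correction


_EXACT_LIMIT = 8  # per-group size up to which the exact null is enumerated


def rank_test(tv_values, fv_values) -> float:
    """Two-group Kruskal-Wallis rank test p-value (tie-corrected H).

    For group sizes up to 8 the exact permutation null of H is
    enumerated (p = fraction of label assignments with H at least the
    observed value); larger inputs use the chi-square (1 df)
    approximation.  Returns NaN when a group is empty and 1.0 when the
    pooled data are all ties (statistic 0).
    """
    tv = np.asarray(tv_values, dtype=float)
    fv = np.asarray(fv_values, dtype=float)
    n1, n2 = len(tv), len(fv)
    if n1 == 0 or n2 == 0:
        return float("nan")
    pooled = np.concatenate([tv, fv])
    if np.all(pooled == pooled[0]):
        return 1.0
    if max(n1, n2) <= _EXACT_LIMIT:
        from itertools import combinations

        ranks = rankdata(pooled)
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_c = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
        h_obs = _kw_statistic(ranks, n1, tie_c)
        hits = total = 0
        idx = np.arange(n)
        for group1 in combinations(idx, n1):
            rest = np.setdiff1d(idx, group1, assume_unique=True)
            perm = np.concatenate([ranks[list(group1)], ranks[rest]])
            if _kw_statistic(perm, n1, tie_c) >= h_obs - 1e-12:
                hits += 1
            total += 1
        return hits / total
    _, p = kruskal(tv, fv)
    return float(p)


def roc_auc(tv_values, fv_values) -> float:
    """Area under the ROC curve of one filter as TV-vs-FV discriminator.

    Computed as the tie-adjusted Mann-Whitney statistic U/(n_tv*n_fv)
    and reported orientation-free as max(A, 1-A), so 0.5 means an
    uninformative filter.  Returns NaN on single-label input.
    """
    tv = np.asarray(tv_values, dtype=float)
    fv = np.asarray(fv_values, dtype=float)
    n1, n2 = len(tv), len(fv)
    if n1 == 0 or n2 == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([tv, fv]))
    u_tv = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u_tv / (n1 * n2)
    return float(max(auc, 1.0 - auc))


def descriptive_stats(
    frame: pd.DataFrame, features=FEATURE_NAMES
) -> pd.DataFrame:
    """Per-filter descriptive rows for one call subset: TV and FV
    replicate-median mean +/- sd plus a pooled rank-test p-value."""
    rows = []
    tv = frame[frame["label"] == "TV"]
    fv = frame[frame["label"] == "FV"]
    for feat in features:
        _, tv_mean, tv_sd = median_of_replicates(tv[feat], tv["replicate"])
        _, fv_mean, fv_sd = median_of_replicates(fv[feat], fv["replicate"])
        p = rank_test(tv[feat].dropna(), fv[feat].dropna())
        rows.append(
            {
                "filter": feat,
                "tv_mean": tv_mean,
                "tv_sd": tv_sd,
                "fv_mean": fv_mean,
                "fv_sd": fv_sd,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def auc_table(frame: pd.DataFrame, features=FEATURE_NAMES) -> pd.Series:
    """Per-filter AUC for one call subset (NaN when a label is absent)."""
    tv = frame[frame["label"] == "TV"]
    fv = frame[frame["label"] == "FV"]
    return pd.Series(
        {f: roc_auc(tv[f].dropna(), fv[f].dropna()) for f in features},
        name="AUC",
    )


@dataclass(frozen=True)
class SelectionCounts:
    """Pre/post-filter confusion counts for one stratum."""

    n_tv: int
    n_fv: int
    retained_tv: int
    retained_fv: int

    def __post_init__(self) -> None:
        if self.retained_tv > self.n_tv or self.retained_fv > self.n_fv:
            raise ValueError("retained counts cannot exceed overall counts")

    @property
    def n(self) -> int:
        return self.n_tv + self.n_fv

    @property
    def n_retained(self) -> int:
        return self.retained_tv + self.retained_fv

    @property
    def selected_percent(self) -> float:
        return 100.0 * self.n_retained / self.n if self.n else float("nan")

    @property
    def overall_tv_percent(self) -> float:
        return 100.0 * self.n_tv / self.n if self.n else float("nan")

    @property
    def overall_fv_percent(self) -> float:
        return 100.0 * self.n_fv / self.n if self.n else float("nan")

    @property
    def retained_tv_percent(self) -> float:
        return (
            100.0 * self.retained_tv / self.n_retained
            if self.n_retained
            else float("nan")
        )

    @property
    def retained_fv_percent(self) -> float:
        return (
            100.0 * self.retained_fv / self.n_retained
            if self.n_retained
            else float("nan")
        )

    @property
    def tv_retention(self) -> float:
        """Fraction of true variants surviving the filter."""
        return self.retained_tv / self.n_tv if self.n_tv else float("nan")


def selection_report(
    overall: pd.DataFrame, retained: pd.DataFrame
) -> SelectionCounts:
    """Confusion/selection counts for one stratum's call set."""
    return SelectionCounts(
        n_tv=int((overall["label"] == "TV").sum()),
        n_fv=int((overall["label"] == "FV").sum()),
        retained_tv=int((retained["label"] == "TV").sum()),
        retained_fv=int((retained["label"] == "FV").sum()),
    )
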