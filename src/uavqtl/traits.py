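"""Derived plant-height traits, descriptive statistics and group contrasts.

Seven traits per line: the absolute heights PH_1..PH_4 at the four flights,
and three growth-rate ratios GRPH_1t2, GRPH_2t3, GRPH_3t4, each defined as
the height increase over the interval divided by the height at the start of
the interval (dimensionless, hence invariant to rescaling all heights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PH_TRAITS",
    "GRPH_TRAITS",
    "ALL_TRAITS",
    "TraitSummary",
    "GroupComparison",
    "compute_grph",
    "summarize_trait",
    "summarize_all",
    "correlation_matrix",
    "group_compare",
]

PH_TRAITS = ("PH_1", "PH_2", "PH_3", "PH_4")
GRPH_TRAITS = ("GRPH_1t2", "GRPH_2t3", "GRPH_3t4")
ALL_TRAITS = PH_TRAITS + GRPH_TRAITS
_INTERVALS = (("PH_1", "PH_2", "GRPH_1t2"),
              ("PH_2", "PH_3", "GRPH_2t3"),
              ("PH_3", "PH_4", "GRPH_3t4"))


@dataclass(frozen=True)
class TraitSummary:
    """Max/min/mean/sd in trait units plus the coefficient of variation (%)."""

    name: str
    max: float
    min: float
    mean: float
    sd: float
    cv: float  # percent, 100 * sd / mean


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    means: dict
    test: str


def compute_grph(heights: pd.DataFrame) -> pd.DataFrame:
    """Fill the growth-rate columns: GRPH_atb = (PH_b - PH_a) / PH_a.

    Missing heights propagate; a zero initial height yields a missing ratio
    with a warning (the ratio is undefined there).
    """
    out = heights.copy()
    for a, b, name in _INTERVALS:
        if a not in out.columns or b not in out.columns:
            raise ValueError(f"height columns {a}/{b} required for {name}")
        pa, pb = out[a].astype(float), out[b].astype(float)
        zero = pa == 0
        if zero.any():
            logger.warning("%s: %d line(s) with %s = 0 -> missing ratio",
                           name, int(zero.sum()), a)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[name] = np.where(zero, np.nan, (pb - pa) / pa)
    return out


def summarize_trait(values, name: str) -> TraitSummary:
    """Descriptive statistics with sample (n-1) sd and CV = 100 sd/mean (%)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(f"{name}: need at least 2 non-missing values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    return TraitSummary(name, float(v.max()), float(v.min()), mean, sd, cv)


def summarize_all(table: pd.DataFrame, traits=ALL_TRAITS) -> pd.DataFrame:
    rows = [vars(summarize_trait(table[t], t)) for t in traits if t in table]
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame, traits=ALL_TRAITS) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among the seven traits.

    Symmetric with unit diagonal; a zero-variance trait gets a missing
    row/column and a warning.
    """
    present = [t for t in traits if t in table.columns]
    sub = table[present].astype(float)
    if len(sub.dropna(how="any")) < 3:
        raise ValueError("need at least 3 lines with complete traits")
    corr = sub.corr(method="pearson", min_periods=3)
    for t in present:
        col = sub[t].dropna()
        if col.nunique() <= 1:
            logger.warning("trait %s has zero variance; correlations undefined", t)
            corr.loc[t, :] = np.nan
            corr.loc[:, t] = np.nan
    np.fill_diagonal(corr.values, np.where(sub.nunique() > 1, 1.0, np.nan))
    return corr


def group_compare(values, groups, test: str = "wilcoxon") -> GroupComparison:
    """Two-sided TEM-vs-TST style contrast for one trait.

    Default is the Wilcoxon rank-sum (Mann-Whitney) test without continuity
    correction, so identical samples give p = 1; ``test='t'`` uses Welch's t.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g):
        raise ValueError("values and groups must align")
    labels = pd.unique(g[np.isfinite(v)])
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    a = v[(g == labels[0]) & np.isfinite(v)]
    b = v[(g == labels[1]) & np.isfinite(v)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 members")
    means = {labels[0]: float(a.mean()), labels[1]: float(b.mean())}
    if test == "wilcoxon":
        if np.ptp(np.concatenate([a, b])) == 0:
            return GroupComparison(len(a) * len(b) / 2.0, 1.0, means, test)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 use_continuity=False, method="asymptotic")
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(float(res.statistic), float(res.pvalue), means, test)
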