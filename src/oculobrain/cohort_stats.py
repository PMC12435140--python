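"""Group-comparison statistics for the cohort demographics table.

Pearson chi-square tests on categorical counts (no continuity correction),
one-way ANOVA in both raw-data and summary-statistic (n/mean/SD) forms, and
the tie-corrected Kruskal-Wallis test.  Which test applies to which variable
is a configuration input (normality/variance pre-tests are out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass
class ContingencyTable:
    """An r x c table of non-negative counts with optional labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("contingency table must be 2-D")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise InputError("contingency table is empty")


@dataclass
class GroupSummaries:
    """Per-group (n, mean, SD) for the summary-statistic ANOVA."""

    ns: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.ns = np.asarray(self.ns, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.ns) == len(self.means) == len(self.sds)):
            raise InputError("ns, means and sds must have equal length")
        if (self.ns < 2).any():
            raise InputError("each group needs n >= 2 for the summary form")
        if (self.sds < 0).any():
            raise InputError("SDs must be non-negative")


def chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table: (chi2, df, p).

    Expected counts E = row * col / total; df = (r-1)(c-1); no Yates
    continuity correction.  A zero row or column margin is an error.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError("chi-square needs at least a 2x2 table")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise InputError("zero row/column margin in contingency table")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA on raw per-group value lists: (F, df1, df2, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("each group needs at least 2 observations")
    if all(np.ptp(g) == 0 for g in groups):
        raise InputError("zero within-group variance in every group")
    res = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(res.statistic), df1, df2, float(res.pvalue)


def anova_from_summary(summaries: GroupSummaries) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group n/mean/SD only.

    SS_between is taken about the n-weighted grand mean and
    SS_within = sum (n_i - 1) s_i^2, so the result is algebraically identical
    to :func:`anova_oneway` on any raw data with these summaries.
    """
    ns, means, sds = summaries.ns, summaries.means, summaries.sds
    if len(ns) < 2:
        raise InputError("need at least 2 groups")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df1 = len(ns) - 1
    df2 = n_total - len(ns)
    if ss_within == 0:
        raise InputError("zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return f, df1, df2, p


def summarize(groups: list[np.ndarray]) -> GroupSummaries:
    """n/mean/SD summaries (ddof=1) of raw per-group data."""
    return GroupSummaries(
        ns=[len(g) for g in groups],
        means=[float(np.mean(g)) for g in groups],
        sds=[float(np.std(g, ddof=1)) for g in groups],
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis test: (H, df, p) with df = k - 1.

    All-identical pooled data yields H = 0 with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    if sum(len(g) for g in groups) < 5:
        raise InputError("need at least 5 observations in total")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical; H defined as 0", stacklevel=2)
        return 0.0, df, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# Table-style summary of a subjects table
# ---------------------------------------------------------------------------

CATEGORICAL_VARS = ("sex", "hypertension", "diabetes")
CONTINUOUS_ANOVA_VARS = ("age",)
CONTINUOUS_KW_VARS = ("education", "MMSE", "MoCA", "BNT", "CDT", "BDST",
                      "TMT-A", "TMT-B")


def summarize_cohort(subjects: pd.DataFrame,
                     group_order: tuple[str, ...] = ("HC", "SCD", "MCI", "AD")
                     ) -> pd.DataFrame:
    """Demographics-table-style statistics per variable across groups.

    Categorical variables get chi-square on their 2 x k count table, age gets
    one-way ANOVA, the remaining continuous variables get Kruskal-Wallis.
    """
    groups = [subjects.loc[subjects["group"] == g] for g in group_order]
    rows = []
    for var in CATEGORICAL_VARS:
        if var not in subjects.columns:
            continue
        counts = np.array([[int((g[var] == v).sum()) for g in groups]
                           for v in (1, 0)])
        try:
            chi2, df, p = chi_square(ContingencyTable(counts))
        except InputError as exc:  # degenerate margin in a tiny cohort
            warnings.warn(f"{var}: {exc}; statistic omitted", stacklevel=2)
            chi2, df, p = float("nan"), 0, float("nan")
        rows.append({"variable": var, "test": "chi-square",
                     "statistic": chi2, "df": df, "p": p})
    for var in CONTINUOUS_ANOVA_VARS:
        if var not in subjects.columns:
            continue
        f, df1, df2, p = anova_oneway([g[var].to_numpy(float) for g in groups])
        rows.append({"variable": var, "test": "anova",
                     "statistic": f, "df": df1, "p": p})
    for var in CONTINUOUS_KW_VARS:
        if var not in subjects.columns:
            continue
        h, df, p = kruskal_wallis([g[var].to_numpy(float) for g in groups])
        rows.append({"variable": var, "test": "kruskal-wallis",
                     "statistic": h, "df": df, "p": p})
    return pd.DataFrame(rows)
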