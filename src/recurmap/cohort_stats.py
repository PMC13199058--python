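"""Cohort-level statistics on per-case region counts.

Two-group comparisons of voxel counts are normality-gated: each group is
tested with Shapiro-Wilk and a two-sample t-test is used only when both
groups look normal at the chosen alpha, otherwise a two-sided Mann-Whitney U
test. The Mann-Whitney p-value is exact (full null distribution) when both
groups have at most 8 observations and the pooled sample is tie-free,
otherwise the tie-corrected normal approximation with continuity correction.
Categorical covariates are compared with Pearson's chi-squared statistic
(no Yates correction). Progression-free survival is summarized per group by
Kaplan-Meier medians with a log-rank test; non-progressed cases are treated
as censored at their last recorded follow-up.

No multiple-testing correction is applied by default; per-region and
per-subgroup p-values are reported raw, with a Benjamini-Hochberg helper
available for users who want adjusted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CohortComparison",
    "CategoricalComparison",
    "SurvivalSummary",
    "choose_test",
    "compare_region",
    "compare_categorical",
    "subgroup_compare",
    "survival_summary",
    "benjamini_hochberg",
]

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"


@dataclass
class CohortComparison:
    """One region's two-group comparison."""

    region: str
    group_a: str
    group_b: str
    group_a_median: float
    group_a_iqr: tuple[float, float]
    group_b_median: float
    group_b_iqr: tuple[float, float]
    test_used: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    stratum_field: Optional[str] = None
    stratum_level: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        for med, (q1, q3) in [
            (self.group_a_median, self.group_a_iqr),
            (self.group_b_median, self.group_b_iqr),
        ]:
            if not (q1 <= med <= q3):
                raise ValueError("quartiles must bracket the median")


@dataclass
class CategoricalComparison:
    """Chi-squared comparison of a categorical covariate across groups."""

    variable: str
    table: np.ndarray
    statistic: float
    dof: int
    p_value: float

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table)
        rows, cols = self.table.shape
        if self.dof != (rows - 1) * (cols - 1):
            raise ValueError("dof inconsistent with table shape")


@dataclass
class SurvivalSummary:
    """Per-group progression summary."""

    group: str
    n: int
    events: int
    median_pfs_months: Optional[float]
    progression_proportion_pct: float

    def __post_init__(self) -> None:
        if self.events > self.n:
            raise ValueError("events cannot exceed n")


def _is_constant(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def choose_test(sample_a: Sequence[float], sample_b: Sequence[float],
                alpha: float = 0.05) -> str:
    """Pick t-test vs Mann-Whitney from Shapiro-Wilk normality of both groups.

    Returns ``t_test`` iff the Shapiro-Wilk p-value is >= alpha in *both*
    samples. Constant samples, for which Shapiro-Wilk is undefined, route to
    Mann-Whitney.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations per group")
    if _is_constant(a) or _is_constant(b):
        return MANN_WHITNEY
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_a = stats.shapiro(a).pvalue
        p_b = stats.shapiro(b).pvalue
    return T_TEST if (p_a >= alpha and p_b >= alpha) else MANN_WHITNEY


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples."""
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _quartiles(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), (float(q1), float(q3))


def _group_values(
    cohort: pd.DataFrame, region: str, group_field: str
) -> tuple[str, np.ndarray, str, np.ndarray]:
    if region not in cohort.columns:
        raise KeyError(f"unknown region column {region!r}")
    if group_field not in cohort.columns:
        raise KeyError(f"unknown group column {group_field!r}")
    levels = list(pd.unique(cohort[group_field].astype(str)))
    if len(levels) != 2:
        raise ValueError(f"{group_field} must have exactly 2 levels, got {levels}")
    # Stable, reproducible ordering: proton before photon when present,
    # otherwise lexicographic.
    if set(levels) == {"proton", "photon"}:
        levels = ["proton", "photon"]
    else:
        levels = sorted(levels)
    out = []
    for level in levels:
        vals = cohort.loc[cohort[group_field].astype(str) == level, region]
        vals = np.asarray(vals.dropna(), dtype=float)
        if len(vals) == 0:
            raise ValueError(f"group {level!r} has no observations for {region}")
        out.append(vals)
    return levels[0], out[0], levels[1], out[1]


def compare_region(
    cohort: pd.DataFrame,
    region: str,
    group_field: str = "group",
    alpha: float = 0.05,
    method: str = "auto",
) -> CohortComparison:
    """Two-group comparison of one region's counts.

    Medians and IQRs (q1-q3, linear interpolation) per group; with
    ``method="auto"`` the test is chosen by :func:`choose_test`, otherwise
    ``method`` forces ``t_test`` or ``mann_whitney``. P-values are two-sided.
    """
    name_a, a, name_b, b = _group_values(cohort, region, group_field)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"each group needs >= 3 cases for {region}")
    if method == "auto":
        test = choose_test(a, b, alpha=alpha)
    elif method in (T_TEST, MANN_WHITNEY):
        test = method
    else:
        raise ValueError(f"unknown method {method!r}")
    if test == T_TEST:
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        statistic, p = _mann_whitney(a, b)
    med_a, iqr_a = _quartiles(a)
    med_b, iqr_b = _quartiles(b)
    return CohortComparison(
        region=region, group_a=name_a, group_b=name_b,
        group_a_median=med_a, group_a_iqr=iqr_a,
        group_b_median=med_b, group_b_iqr=iqr_b,
        test_used=test, statistic=statistic, p_value=p,
        n_a=len(a), n_b=len(b),
    )


def subgroup_compare(
    cohort: pd.DataFrame,
    region: str,
    stratum_field: str,
    stratum_level: str,
    group_field: str = "group",
    alpha: float = 0.05,
) -> CohortComparison:
    """Restrict the cohort to one stratum level, then compare groups."""
    if stratum_field not in cohort.columns:
        raise KeyError(f"unknown stratum column {stratum_field!r}")
    sub = cohort[cohort[stratum_field].astype(str) == str(stratum_level)]
    if sub.empty:
        raise ValueError(f"stratum {stratum_field}={stratum_level!r} is empty")
    groups = sub[group_field].astype(str)
    for level in pd.unique(cohort[group_field].astype(str)):
        if (groups == level).sum() == 0:
            raise ValueError(
                f"stratum {stratum_field}={stratum_level!r} has no "
                f"{group_field}={level!r} cases"
            )
    result = compare_region(sub, region, group_field=group_field, alpha=alpha)
    result.stratum_field = stratum_field
    result.stratum_level = str(stratum_level)
    return result


def compare_categorical(
    records: pd.DataFrame,
    variable: str,
    group_field: str = "group",
    drop_unknown: bool = True,
) -> CategoricalComparison:
    """Pearson chi-squared (no continuity correction) on a group x level table."""
    frame = records
    if variable not in frame.columns:
        raise KeyError(f"unknown variable {variable!r}")
    sub = frame[[group_field, variable]].astype(str)
    if drop_unknown:
        sub = sub[sub[variable] != "unknown"]
    table = pd.crosstab(sub[group_field], sub[variable])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"{variable}: need at least a 2x2 table, got {table.shape}")
    counts = table.to_numpy()
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError(f"{variable}: zero marginal row or column")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return CategoricalComparison(
        variable=variable, table=counts, statistic=float(chi2),
        dof=int(dof), p_value=float(p),
    )


def survival_summary(
    records: pd.DataFrame,
    group_field: str = "group",
) -> tuple[list[SurvivalSummary], Optional[float]]:
    """Kaplan-Meier PFS medians and progression proportions per group.

    The progression proportion is 100 * events / n, rounded to one decimal.
    Cases without a recorded time contribute to the proportion but not to
    the Kaplan-Meier curve. Returns the per-group summaries plus a log-rank
    p-value when exactly two groups are present.
    """
    levels = list(pd.unique(records[group_field].astype(str)))
    if set(levels) == {"proton", "photon"}:
        levels = ["proton", "photon"]
    summaries = []
    timed = {}
    total_events = 0
    for level in levels:
        sub = records[records[group_field].astype(str) == level]
        n = len(sub)
        events = int(sub["progressed"].astype(bool).sum())
        total_events += events
        with_time = sub[sub["pfs_months"].notna()]
        median = None
        if len(with_time) > 0:
            kmf = KaplanMeierFitter()
            kmf.fit(
                with_time["pfs_months"].astype(float),
                event_observed=with_time["progressed"].astype(bool),
            )
            med = float(kmf.median_survival_time_)
            median = med if np.isfinite(med) else None
            timed[level] = with_time
        summaries.append(
            SurvivalSummary(
                group=level, n=n, events=events, median_pfs_months=median,
                progression_proportion_pct=round(100.0 * events / n, 1),
            )
        )
    if total_events == 0:
        raise ValueError("no progression events in any group")
    logrank_p = None
    if len(levels) == 2 and all(level in timed for level in levels):
        a, b = (timed[level] for level in levels)
        res = logrank_test(
            a["pfs_months"].astype(float), b["pfs_months"].astype(float),
            event_observed_A=a["progressed"].astype(bool),
            event_observed_B=b["progressed"].astype(bool),
        )
        logrank_p = float(res.p_value)
    return summaries, logrank_p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in the pipeline)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
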