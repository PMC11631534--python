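"""The phenotype statistics battery: exact tests, survival analysis, CIs.

Covers every comparison used for the organismal phenotypes measured
alongside mistranslation: Fisher's exact test for stage-survival,
deformity, and climbing proportions; Wilcoxon rank-sum for developmental
times; Welch's t for replicate frequency vectors; Holm-Bonferroni
family-wise correction; Kaplan-Meier curves with Greenwood-based log-log
confidence intervals and log-rank tests for longevity; and Wilson score
intervals for proportions.

Survival data arrive as an event table (CSV) with columns
``subject_id, group, sex, day, status`` where status is ``dead`` or
``censored`` (escaped animals are censored).  Count data are 2x2 tables of
successes and failures per group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CountTable2x2",
    "fisher_exact_2x2",
    "holm_bonferroni",
    "wilcoxon_rank_sum",
    "welch_t_test",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "top_quantile_subset",
    "proportion_ci",
    "load_survival_csv",
    "load_counts_csv",
    "load_devtime_csv",
    "SURVIVAL_COLUMNS",
]

SURVIVAL_COLUMNS = ["subject_id", "group", "sex", "day", "status"]


@dataclass(frozen=True)
class CountTable2x2:
    """A 2x2 count table: rows are groups, columns outcome / no-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table: CountTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    With margins fixed, the p-value is the sum of hypergeometric
    probabilities of all tables whose point probability does not exceed
    the observed table's (a relative slack of 1e-12 absorbs floating-point
    ties).  Degenerate tables (an all-zero row or column) carry no
    information: p = 1 with a warning.
    """
    if not isinstance(table, CountTable2x2):
        (a, b), (c, d) = table
        table = CountTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        warnings.warn("degenerate margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    k = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, row1, col1)
    observed = stats.hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= observed * (1 + 1e-12)].sum())
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(scaled))
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='exact'`` enumerates the exact rank-sum distribution (requires
    no ties); ``'normal'`` uses the normal approximation with tie and
    continuity corrections; ``'auto'`` picks exact when n_x + n_y <= 12
    and there are no ties.  Returns (U statistic for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 12 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free data")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        warnings.warn("zero variance in both groups", stacklevel=2)
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(x) - np.mean(y)), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class KMEstimate:
    """A Kaplan-Meier curve: survival probability with 95% CI at each event time."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    times: Sequence[float], observed: Sequence[bool], alpha: float = 0.05
) -> KMEstimate:
    """Product-limit survival estimate with Greenwood log-log CIs.

    ``observed`` is True for a death and False for a censored subject;
    censoring removes a subject from the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=observed)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)
    # drop the synthetic S(0)=1 baseline row unless 0 is an observed time
    if timeline.size and timeline[0] == 0.0 and not np.any(times == 0):
        timeline, surv, lo, hi = timeline[1:], surv[1:], lo[1:], hi[1:]
    return KMEstimate(timeline=timeline, survival=surv, ci_lower=lo, ci_upper=hi)


def logrank_test(
    times_a: Sequence[float],
    observed_a: Sequence[bool],
    times_b: Sequence[float],
    observed_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    observed_a = np.asarray(observed_a, dtype=bool)
    observed_b = np.asarray(observed_b, dtype=bool)
    if not (observed_a.any() or observed_b.any()):
        raise ValueError("no deaths in either group")
    res = _ll_logrank(
        np.asarray(times_a, dtype=float),
        np.asarray(times_b, dtype=float),
        event_observed_A=observed_a,
        event_observed_B=observed_b,
    )
    return float(res.test_statistic), float(res.p_value)


def top_quantile_subset(events: pd.DataFrame, q: float = 0.25) -> pd.DataFrame:
    """Longest-lived deaths per group: the ceil(q*n) largest observed times.

    Operates on an event table with columns ``subject_id, group, day,
    status``; only deaths are considered (n is the per-group death count).
    Ties at the cutoff are broken deterministically by ``subject_id``.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    deaths = events[events["status"] == "dead"]
    parts = []
    for group, sub in deaths.groupby("group", sort=True):
        if sub.empty:
            raise ValueError(f"group {group!r} has no deaths")
        n_keep = math.ceil(q * len(sub))
        ordered = sub.sort_values(
            ["day", "subject_id"], ascending=[False, True], kind="stable"
        )
        parts.append(ordered.iloc[:n_keep])
    return pd.concat(parts, axis=0)


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(max(0.0, lo)), float(min(1.0, hi))


def load_survival_csv(path: str) -> pd.DataFrame:
    """Load a survival event table, validating columns and status labels."""
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table {path} missing columns {missing}")
    bad = set(df["status"].unique()) - {"dead", "censored"}
    if bad:
        raise ValueError(f"unknown status labels {sorted(bad)} in {path}")
    if (df["day"] < 0).any():
        raise ValueError(f"negative times in {path}")
    return df


def load_counts_csv(path: str) -> pd.DataFrame:
    """Load a per-group success/failure count table."""
    df = pd.read_csv(path)
    missing = [c for c in ("group", "success", "failure") if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} missing columns {missing}")
    if (df[["success", "failure"]] < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return df


def load_devtime_csv(path: str) -> pd.DataFrame:
    """Load developmental-time records (subject_id, group, stage, hours)."""
    df = pd.read_csv(path)
    missing = [
        c for c in ("subject_id", "group", "stage", "hours") if c not in df.columns
    ]
    if missing:
        raise ValueError(f"development table {path} missing columns {missing}")
    if (df["hours"] < 0).any():
        raise ValueError(f"negative times in {path}")
    return df
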