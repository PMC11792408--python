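"""Survival estimation and hypothesis tests for cohort analyses.

Thin, contract-stable wrappers over lifelines (Kaplan–Meier, Mantel–Cox
log-rank, univariate Cox with Efron tie handling), scipy (rank tests,
Pearson chi-square without continuity correction) and scikit-survival
(IPCW time-dependent AUC), plus an in-package Dunn's post hoc for the
Kruskal–Wallis omnibus (tie-corrected z tests with family-wise
adjustment), which no installed library provides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .errors import UnfittableError

NOT_REACHED = "not reached"


def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and the same length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan–Meier

@dataclass
class KMEstimate:
    """Product-limit estimate: step function plus median survival."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # math.inf when the curve never reaches 0.5

    @property
    def median_label(self) -> str:
        return NOT_REACHED if math.isinf(self.median) else f"{self.median:g}"

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan–Meier estimate; median is the first time with S(t) ≤ 0.5."""
    t, e = _as_time_event(times, events)
    if len(t) == 0:
        raise ValueError("at least one subject required")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        median=float(kmf.median_survival_time_),
    )


# ---------------------------------------------------------------------------
# log-rank

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    n_events: int


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group Mantel–Cox log-rank test (chi-square, 1 df, two-sided)."""
    ta, ea = _as_time_event(times_a, events_a)
    tb, eb = _as_time_event(times_b, events_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    n_events = int(ea.sum() + eb.sum())
    if n_events == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return LogrankResult(0.0, 1.0, 0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not math.isfinite(stat):  # degenerate (e.g. all ties, no variance)
        stat, p = 0.0, 1.0
    return LogrankResult(stat, p, n_events)


# ---------------------------------------------------------------------------
# univariate Cox

@dataclass(frozen=True)
class CoxHRResult:
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    flagged_monotone: bool = False


def cox_hr(groups, times, events, alpha: float = 0.05) -> CoxHRResult:
    """Univariate proportional-hazards hazard ratio for a binary group.

    Efron tie handling, Wald confidence interval. When one group has no
    events the partial likelihood is monotone; the fit is flagged and the
    reported HR is the penalised bound lifelines converges to.
    """
    t, e = _as_time_event(times, events)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"binary group required, got levels {levels!r}")
    if e.sum() < 2:
        raise UnfittableError("fewer than 2 events")
    x = (g == levels[1]).astype(float)
    monotone = any(e[x == v].sum() == 0 for v in (0.0, 1.0))
    df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
    cph = CoxPHFitter(penalizer=1e-6 if not monotone else 0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="t", event_col="e")
        except ConvergenceError:
            # quasi-separation: the partial likelihood is (near-)monotone
            # even with events in both groups; report the ridge-stabilised
            # bound and flag it
            monotone = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="t", event_col="e")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = sps.norm.ppf(1 - alpha / 2)
    return CoxHRResult(
        hr=math.exp(beta),
        ci_lower=math.exp(beta - z * se),
        ci_upper=math.exp(beta + z * se),
        p_value=float(cph.summary.loc["x", "p"]),
        flagged_monotone=monotone,
    )


# ---------------------------------------------------------------------------
# time-dependent AUC

def time_dependent_auc(scores, times, events, horizons) -> pd.Series:
    """IPCW time-dependent AUC(t) at the requested horizons.

    Cumulative/dynamic definition with inverse-probability-of-censoring
    weights (Uno estimator). Horizons at or beyond the last observed
    event time yield NaN.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    t, e = _as_time_event(times, events)
    s = np.asarray(scores, dtype=float)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if e.sum() == 0:
        return pd.Series(np.nan, index=horizons)
    y = Surv.from_arrays(event=e, time=t)
    last_event = t[e].max()
    first = t.min()
    out = pd.Series(np.nan, index=pd.Index(horizons, name="horizon_months"))
    ok = (horizons >= first) & (horizons < last_event)
    if ok.any():
        auc, _ = cumulative_dynamic_auc(y, y, s, horizons[ok])
        out.iloc[np.flatnonzero(ok)] = auc
    return out


# ---------------------------------------------------------------------------
# rank tests

@dataclass
class RankTestResult:
    method: str
    p_value: float
    statistic: float
    pairwise_adjusted: dict[tuple[int, int], float] = field(default_factory=dict)


def _all_identical(groups: Sequence[np.ndarray]) -> bool:
    pooled = np.concatenate(groups)
    return bool(np.all(pooled == pooled[0]))


def dunn_posthoc(groups: Sequence[np.ndarray]) -> dict[tuple[int, int], float]:
    """Dunn's pairwise z tests after Kruskal–Wallis, tie-corrected.

    Ranks are assigned over the pooled sample (mid-ranks for ties); the
    z statistic for groups i, j uses the tie-corrected variance
    ``(N(N+1)/12 − ΣT/(12(N−1)))·(1/n_i + 1/n_j)`` with ``T = t³ − t``
    summed over tie groups. Two-sided p-values are family-wise adjusted
    by multiplication with the number of comparisons (capped at 1).
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1)))
    base_var = n * (n + 1) / 12.0 - tie_term
    k = len(list(combinations(range(len(groups)), 2)))
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(groups)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            out[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        out[(i, j)] = min(1.0, p * k)
    return out


def rank_tests(groups: Sequence, method: str = "auto") -> RankTestResult:
    """Rank-based group comparison.

    Two groups → Wilcoxon rank-sum (Mann–Whitney U, two-sided, exact for
    small tie-free samples, tie-corrected normal approximation
    otherwise). Three or more groups → Kruskal–Wallis omnibus plus
    Dunn's family-wise-adjusted pairwise comparisons.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("at least two groups required")
    if any(len(a) < 1 for a in arrs):
        raise ValueError("every group needs at least one observation")
    if method == "auto":
        method = "wilcoxon" if len(arrs) == 2 else "kruskal_wallis_dunn"

    if method == "wilcoxon":
        if len(arrs) != 2:
            raise ValueError("wilcoxon compares exactly two groups")
        if _all_identical(arrs):
            return RankTestResult(method, 1.0, statistic=len(arrs[0]) * len(arrs[1]) / 2.0)
        res = sps.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided", method="auto")
        return RankTestResult(method, float(res.pvalue), float(res.statistic))

    if method == "kruskal_wallis_dunn":
        if _all_identical(arrs):
            return RankTestResult(method, 1.0, 0.0,
                                  {pair: 1.0 for pair in combinations(range(len(arrs)), 2)})
        stat, p = sps.kruskal(*arrs)
        return RankTestResult(method, float(p), float(stat), dunn_posthoc(arrs))

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# contingency tables

@dataclass(frozen=True)
class ContingencyTable:
    """An r × c table of non-negative integer counts."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    column_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2×2")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_table(table: ContingencyTable | Sequence[Sequence[int]]) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Σ(O−E)²/E with df = (r−1)(c−1); two-sided p from the chi-square
    distribution. A zero row or column marginal makes the expected counts
    degenerate and raises ``ValueError``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(tuple(int(v) for v in row) for row in table))
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))
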