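"""Survival machinery and hypothesis tests against closed forms and
independent implementations."""

import math

import numpy as np
import pandas as pd
import pytest

from tlsscape.datasets import BASELINE_TABLE, REPORTED_SURVIVAL
from tlsscape.errors import UnfittableError
from tlsscape.stats import (
    ContingencyTable,
    chi_square_table,
    cox_hr,
    dunn_posthoc,
    kaplan_meier,
    logrank_test,
    rank_tests,
    time_dependent_auc,
)


# ---------------------------------------------------------------------------
# Kaplan–Meier

def test_km_all_censored_survival_one_median_not_reached():
    km = kaplan_meier([5.0, 8.0, 12.0], [False, False, False])
    assert km.at(12.0) == 1.0
    assert math.isinf(km.median)
    assert km.median_label == "not reached"


def test_km_closed_form_three_events():
    km = kaplan_meier([1.0, 2.0, 3.0], [True, True, True])
    assert km.at(1.0) == pytest.approx(2 / 3)
    assert km.at(2.0) == pytest.approx(1 / 3)
    assert km.median == 2.0


def test_km_median_of_exponential_sample(rng):
    """n=100 exponential(rate 0.1): median near ln2/0.1 ≈ 6.93 months.
    The MC standard error of a sample median is 1/(2 f(m) √n) ≈ 1.0."""
    t = rng.exponential(10.0, 100)
    km = kaplan_meier(t, np.ones(100, bool))
    assert abs(km.median - math.log(2) / 0.1) < 3.0


def test_km_survival_is_monotone_step_function(rng):
    t = rng.exponential(5.0, 80)
    e = rng.uniform(size=80) < 0.7
    km = kaplan_meier(t, e)
    assert km.at(0.0) == 1.0
    assert (np.diff(km.survival) <= 1e-12).all()


def test_km_negative_time_rejected():
    with pytest.raises(ValueError):
        kaplan_meier([-1.0, 2.0], [True, True])


# ---------------------------------------------------------------------------
# log-rank

def naive_logrank(ta, ea, tb, eb):
    """Mantel–Cox statistic computed directly from the O/E tables."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for t in event_times:
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        d1, d2 = ((ta == t) & ea).sum(), ((tb == t) & eb).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (o_minus_e ** 2) / var if var > 0 else 0.0


def test_logrank_identical_groups():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [True, True, False, True]
    res = logrank_test(t, e, t, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_no_events_warns_p_one():
    with pytest.warns(UserWarning, match="no events"):
        res = logrank_test([1, 2], [False, False], [3, 4], [False, False])
    assert res.p_value == 1.0


def test_logrank_matches_hand_computed_tables():
    """Small worked datasets, including a 6+6 example with ties and
    censoring, agree with the direct observed/expected computation."""
    cases = [
        ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], [2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1]),
        ([1, 1, 2, 5, 8, 9], [1, 0, 1, 1, 0, 1], [2, 3, 3, 7, 10, 12], [1, 1, 0, 1, 1, 0]),
        ([3, 5], [1, 1], [1, 2, 9], [1, 0, 1]),
    ]
    for ta, ea, tb, eb in cases:
        got = logrank_test(ta, np.array(ea, bool), tb, np.array(eb, bool))
        assert got.statistic == pytest.approx(naive_logrank(ta, ea, tb, eb), rel=1e-9)


def test_logrank_symmetric_in_group_labels(rng):
    ta, tb = rng.exponential(5, 30), rng.exponential(8, 25)
    ea, eb = rng.uniform(size=30) < 0.8, rng.uniform(size=25) < 0.8
    r1 = logrank_test(ta, ea, tb, eb)
    r2 = logrank_test(tb, eb, ta, ea)
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


# ---------------------------------------------------------------------------
# Cox hazard ratio

def test_cox_identical_groups_hr_one(rng):
    t = rng.exponential(5, 40)
    groups = np.r_[np.zeros(20), np.ones(20)]
    t = np.tile(t[:20], 2)
    hr = cox_hr(groups, t, np.ones(40, bool))
    assert hr.hr == pytest.approx(1.0, abs=1e-3)


def test_cox_matches_statsmodels_phreg(rng):
    """Independent implementation check: statsmodels PHReg with Efron ties."""
    from statsmodels.duration.hazard_regression import PHReg

    n = 120
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.05 * np.exp(-0.8 * x)))
    cens = rng.exponential(30, n)
    times, events = np.minimum(t, cens), t <= cens
    got = cox_hr(x, times, events)
    ref = PHReg(times, x[:, None], status=events.astype(int), ties="efron").fit()
    assert math.log(got.hr) == pytest.approx(float(ref.params[0]), abs=1e-3)


def test_cox_monotone_likelihood_flagged():
    groups = np.r_[np.zeros(10), np.ones(10)]
    times = np.arange(1.0, 21.0)
    events = np.r_[np.ones(10, bool), np.zeros(10, bool)]  # no events in group 1
    hr = cox_hr(groups, times, events)
    assert hr.flagged_monotone


def test_cox_too_few_events_unfittable():
    with pytest.raises(UnfittableError):
        cox_hr([0, 1, 0, 1], [1.0, 2.0, 3.0, 4.0], [True, False, False, False])


# ---------------------------------------------------------------------------
# time-dependent AUC

def test_tauc_null_score_near_half(rng):
    n = 500
    t = rng.exponential(10, n)
    e = rng.uniform(size=n) < 0.8
    s = rng.normal(size=n)
    auc = time_dependent_auc(s, t, e, [5.0, 10.0, 15.0])
    assert np.nanmax(np.abs(auc.to_numpy() - 0.5)) < 0.06


def test_tauc_informative_score_above_half(rng):
    n = 400
    x = rng.normal(size=n)
    t = rng.exponential(1 / (0.1 * np.exp(x)))
    e = np.ones(n, bool)
    auc = time_dependent_auc(x, t, e, [2.0, 5.0, 10.0])
    assert (auc.dropna() > 0.55).all()


def test_tauc_perfect_separation_is_one():
    # high scores all die by t=5; low scores all die after t=10
    t = np.array([1, 2, 3, 4, 11, 12, 13, 14], float)
    s = np.array([4, 3, 2, 1, -1, -2, -3, -4], float)
    auc = time_dependent_auc(s, t, np.ones(8, bool), [5.0, 8.0])
    assert np.allclose(auc.to_numpy(), 1.0)


def test_tauc_horizon_beyond_last_event_is_missing(rng):
    t = rng.exponential(5, 50)
    auc = time_dependent_auc(rng.normal(size=50), t, np.ones(50, bool),
                             [t.max() + 10.0])
    assert auc.isna().all()


# ---------------------------------------------------------------------------
# rank tests

def test_wilcoxon_exact_small_sample():
    """{1,2,3} vs {4,5,6}: 2/20 arrangements are as extreme → p = 0.1."""
    res = rank_tests([[1, 2, 3], [4, 5, 6]])
    assert res.method == "wilcoxon"
    assert res.p_value == pytest.approx(0.1)


def test_identical_samples_p_one_both_methods():
    assert rank_tests([[2, 2, 2], [2, 2, 2]]).p_value == 1.0
    res = rank_tests([[1, 1], [1, 1], [1, 1]])
    assert res.p_value == 1.0
    assert all(p == 1.0 for p in res.pairwise_adjusted.values())


def test_rank_tests_validates_groups():
    with pytest.raises(ValueError):
        rank_tests([[1, 2, 3]])
    with pytest.raises(ValueError):
        rank_tests([[1, 2], []])


def test_dunn_hand_computed_example():
    """No ties, groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2/5/8,
    pairwise SE = √(7.5·(2/3)) ≈ 2.236; z = ∓1.342/∓2.683, adjusted ×3."""
    res = rank_tests([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.method == "kruskal_wallis_dunn"
    adj = res.pairwise_adjusted
    assert adj[(0, 1)] == pytest.approx(3 * 0.17971, abs=2e-4)
    assert adj[(0, 2)] == pytest.approx(3 * 0.0072878, abs=2e-5)
    assert adj[(1, 2)] == pytest.approx(adj[(0, 1)])


def test_dunn_tie_correction_reduces_variance(rng):
    tied = [list(rng.integers(0, 3, 15)) for _ in range(3)]
    adj = dunn_posthoc([np.array(g, float) for g in tied])
    assert all(0.0 <= p <= 1.0 for p in adj.values())


# ---------------------------------------------------------------------------
# chi-square

@pytest.mark.parametrize(
    "variable, expected_p",
    [
        ("age", 0.706),
        ("gender", 0.917),
        ("differentiation", 0.006),
        ("lauren", 0.226),
        ("her2", 0.265),
        ("microsatellite", 0.120),
        ("stage", 0.863),
    ],
)
def test_baseline_table_p_values(variable, expected_p):
    """Pearson chi-square (no continuity correction) on the printed
    cohort cross-tabulations reproduces the printed p-values to 3 dp."""
    res = chi_square_table(BASELINE_TABLE[variable])
    assert round(res.p_value, 3) == expected_p


def test_chi_square_identical_proportions_is_zero():
    res = chi_square_table([[10, 20], [5, 10], [15, 30]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_table([[0, 0], [3, 4]])


def test_chi_square_invariant_to_permutation(rng):
    arr = rng.integers(1, 30, (4, 2))
    base = chi_square_table(arr.tolist())
    perm = arr[rng.permutation(4)][:, ::-1]
    got = chi_square_table(perm.tolist())
    assert got.statistic == pytest.approx(base.statistic)
    assert got.p_value == pytest.approx(base.p_value)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(((1,), (2,)))
    with pytest.raises(ValueError):
        ContingencyTable(((1, -2), (3, 4)))


def test_reported_survival_values_are_metadata_only():
    """The cohort's published survival headline numbers ship as flagged
    reference metadata; patient-level times are not available, so nothing
    in the package recomputes them."""
    for key, entry in REPORTED_SURVIVAL.items():
        assert entry["source"] == "reported", key
        assert isinstance(entry["value"], float)
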