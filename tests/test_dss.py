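"""DSS model: feature assembly, scoring arithmetic, LASSO-Cox fitting and
optimal-cutoff dichotomisation."""

import numpy as np
import pandas as pd
import pytest

from tlsscape.dss import (
    DSSModel,
    assemble_features,
    find_optimal_cutoff,
    fit_lasso_cox,
    published_dss_model,
    save_dss_model,
    load_dss_model,
    score_dss,
)
from tlsscape.errors import AlignmentError, ConfigError, UnfittableError
from tlsscape.simulate import CohortSimConfig, simulate_cohort
from tlsscape.stats import logrank_test

PUBLISHED_COEFS = (-0.0027, -0.0003, -0.0004, -0.1978, -0.1214)


def test_published_model_terms_and_signs():
    model = published_dss_model()
    assert len(model.terms) == 5
    assert tuple(model.coefficients) == PUBLISHED_COEFS
    assert all(c < 0 for c in model.coefficients)
    densities = [f for f in model.features if f.startswith("density::")]
    effscores = [f for f in model.features if f.startswith("effscore::")]
    assert len(densities) == 3 and len(effscores) == 2
    assert all(f.endswith("::TC-TLS") for f in model.features)


def test_score_zero_features_is_zero():
    model = published_dss_model()
    row = pd.Series(0.0, index=model.features)
    assert score_dss(row, model) == 0.0


def test_score_single_density_term():
    """100 cells/mm² of the first density feature alone → −0.27."""
    model = published_dss_model()
    row = pd.Series(0.0, index=model.features)
    row["density::CD8+LAG-3+::TC-TLS"] = 100.0
    assert score_dss(row, model) == pytest.approx(-0.27)


def test_score_equals_independent_dot_product(rng):
    model = published_dss_model()
    for _ in range(20):
        vals = rng.uniform(0, 500, 5)
        row = pd.Series(vals, index=model.features)
        expected = sum(c * v for (_, c), v in zip(model.terms, vals))
        assert score_dss(row, model) == pytest.approx(expected, rel=1e-14)


def test_score_linearity_to_machine_precision(rng):
    model = published_dss_model()
    x = pd.Series(rng.uniform(0, 300, 5), index=model.features)
    for a in (2.0, -3.5, 0.25):
        assert score_dss(a * x, model) == pytest.approx(a * score_dss(x, model), rel=1e-12)


def test_score_missing_term_propagates_nan_and_absent_column_raises():
    model = published_dss_model()
    frame = pd.DataFrame(
        [[np.nan, 0, 0, 0, 0], [1, 2, 3, 4, 5]],
        index=["P1", "P2"], columns=model.features,
    )
    scores = score_dss(frame, model)
    assert np.isnan(scores["P1"]) and np.isfinite(scores["P2"])
    with pytest.raises(ConfigError, match="absent"):
        score_dss(frame.iloc[:, :4], model)


def test_score_nonincreasing_in_every_feature(rng):
    """All published coefficients are negative: raising any feature can
    only lower the DSS (low DSS ↔ denser/closer infiltrate)."""
    model = published_dss_model()
    base = pd.Series(rng.uniform(0, 100, 5), index=model.features)
    s0 = score_dss(base, model)
    for f in model.features:
        bumped = base.copy()
        bumped[f] += 10.0
        assert score_dss(bumped, model) < s0


def test_model_yaml_round_trip(tmp_path):
    model = DSSModel(terms=(("density::x::TC-TLS", -0.5),), cutoff=1.25)
    p = tmp_path / "m.yaml"
    save_dss_model(model, p)
    assert load_dss_model(p) == model


# ---------------------------------------------------------------------------
# assembly

def _slices(n=52, n_density=100, n_spatial=43, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id")
    dens = pd.DataFrame(rng.uniform(0, 300, (n, n_density)), index=idx,
                        columns=[f"density::d{j}::TC-TLS" for j in range(n_density)])
    spat = pd.DataFrame(rng.uniform(0, 3, (n, n_spatial)), index=idx,
                        columns=[f"effscore::c{j}::s{j}::TC-TLS" for j in range(n_spatial)])
    return dens, spat


def test_assemble_143_feature_space():
    dens, spat = _slices()
    X = assemble_features(dens, spat)
    assert X.shape == (52, 143)
    assert list(X.columns[:100]) == list(dens.columns)


def test_assemble_empty_spatial_slice_equals_density_slice():
    dens, spat = _slices()
    X = assemble_features(dens, spat.iloc[:, :0])
    pd.testing.assert_frame_equal(X, dens.sort_index(), check_like=False)


def test_assemble_disjoint_patients_is_alignment_error():
    dens, spat = _slices()
    spat.index = pd.Index([f"Q{i}" for i in range(len(spat))], name="patient_id")
    with pytest.raises(AlignmentError):
        assemble_features(dens, spat)


def test_assemble_column_order_stable_under_row_shuffle(rng):
    dens, spat = _slices()
    perm = rng.permutation(len(dens))
    X1 = assemble_features(dens, spat)
    X2 = assemble_features(dens.iloc[perm], spat.iloc[rng.permutation(len(spat))])
    assert list(X1.columns) == list(X2.columns)
    pd.testing.assert_frame_equal(X1, X2)


def test_assemble_filters_to_tc_tls_and_records_missingness():
    dens, spat = _slices()
    dens["density::d0::N-TLS"] = 1.0
    dens.iloc[:13, 0] = np.nan
    X = assemble_features(dens, spat)
    assert not any(c.endswith("::N-TLS") for c in X.columns)
    assert X.attrs["missing_fraction"][dens.columns[0]] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# LASSO-Cox

def test_single_strong_feature_recovers_sign(rng):
    n = 200
    x = rng.normal(0, 1, n)
    h = 0.05 * np.exp(-0.9 * x)
    t = rng.exponential(1 / h)
    idx = pd.Index([f"P{i}" for i in range(n)], name="patient_id")
    X = pd.DataFrame({"density::f::TC-TLS": x}, index=idx)
    out = pd.DataFrame({"time": t, "event": np.ones(n, bool)}, index=idx)
    fit = fit_lasso_cox(X, out, folds=5, seed=0)
    assert fit.coefficients.iloc[0] < 0


def test_zero_events_is_unfittable():
    idx = pd.Index(["P1", "P2", "P3"], name="patient_id")
    X = pd.DataFrame({"density::f::TC-TLS": [1.0, 2.0, 3.0]}, index=idx)
    out = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [False] * 3}, index=idx)
    with pytest.raises(UnfittableError):
        fit_lasso_cox(X, out, folds=2, seed=0)


def test_all_missing_column_dropped_with_warning():
    X, clinical = simulate_cohort(CohortSimConfig(seed=5, n_patients=80, n_decoy_features=10))
    X["density::void::TC-TLS"] = np.nan
    with pytest.warns(UserWarning, match="void"):
        fit = fit_lasso_cox(X, clinical, endpoint="OS", folds=5, seed=0)
    assert "density::void::TC-TLS" in fit.dropped_features
    assert "density::void::TC-TLS" not in fit.coefficients.index


def test_patients_with_missing_features_excluded_not_imputed():
    X, clinical = simulate_cohort(CohortSimConfig(seed=6, n_patients=80, n_decoy_features=10))
    X.iloc[:9, 0] = np.nan  # nine patients lack the TC-TLS compartment
    fit = fit_lasso_cox(X, clinical, endpoint="OS", folds=5, seed=0)
    assert fit.n_used == 71


def test_permuted_outcome_selects_near_empty_set():
    """Outcomes shuffled against features: selection collapses."""
    X, clinical = simulate_cohort(CohortSimConfig(seed=2, n_patients=150, n_decoy_features=40))
    rng = np.random.default_rng(3)
    counts = []
    for _ in range(5):
        perm = rng.permutation(len(clinical))
        out = pd.DataFrame(
            {
                "time": [clinical[j].endpoint_times["OS"] for j in perm],
                "event": [clinical[j].endpoint_events["OS"] for j in perm],
            },
            index=X.index,
        )
        fit = fit_lasso_cox(X, out, folds=5, seed=0, penalty_rule="1se")
        counts.append(len(fit.selected))
    assert np.median(counts) <= 2


def test_fit_deterministic_given_seed():
    X, clinical = simulate_cohort(CohortSimConfig(seed=4, n_patients=100, n_decoy_features=20))
    f1 = fit_lasso_cox(X, clinical, endpoint="OS", folds=5, seed=9)
    f2 = fit_lasso_cox(X, clinical, endpoint="OS", folds=5, seed=9)
    pd.testing.assert_series_equal(f1.coefficients, f2.coefficients)
    assert f1.alpha == f2.alpha


# ---------------------------------------------------------------------------
# optimal cutoff

def test_cutoff_perfect_separation():
    scores = pd.Series([1, 1, 1, 9, 9, 9], dtype=float)
    times = np.array([10, 11, 12, 1, 2, 3], dtype=float)
    events = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
    res = find_optimal_cutoff(scores, times, events, min_group_fraction=0.1)
    assert 1.0 < res.cutoff < 9.0
    assert res.n_high == 3 and res.n_low == 3


def test_cutoff_identical_scores_infeasible():
    scores = pd.Series([2.0] * 8)
    with pytest.raises(UnfittableError, match="identical"):
        find_optimal_cutoff(scores, np.arange(1.0, 9.0), np.ones(8, bool))


def test_cutoff_group_size_floor_enforced():
    # only the extreme split is available, but it leaves 1 patient < floor
    scores = pd.Series([1.0] + [5.0] * 9)
    with pytest.raises(UnfittableError, match="cutoff"):
        find_optimal_cutoff(scores, np.arange(1.0, 11.0), np.ones(10, bool),
                            min_group_fraction=0.2)


def test_cutoff_matches_exhaustive_scan_oracle():
    """60 simulated patients: the chosen cutoff equals a literal scan over
    every candidate midpoint using the log-rank statistic directly."""
    rng = np.random.default_rng(17)
    n = 60
    scores = pd.Series(rng.normal(0, 1, n))
    h = 0.08 * np.exp(0.8 * scores.to_numpy())
    t = rng.exponential(1 / h)
    cens = rng.exponential(20, n)
    times = np.minimum(t, cens)
    events = t <= cens
    res = find_optimal_cutoff(scores, times, events, min_group_fraction=0.1)

    uniq = np.unique(scores.to_numpy())
    best_stat, best_cut = -1.0, None
    floor = 6
    for c in (uniq[:-1] + uniq[1:]) / 2:
        hi = scores.to_numpy() > c
        if hi.sum() < floor or (~hi).sum() < floor:
            continue
        stat = logrank_test(times[hi], events[hi], times[~hi], events[~hi]).statistic
        if stat > best_stat:
            best_stat, best_cut = stat, c
    assert res.cutoff == pytest.approx(best_cut)
    assert res.statistic == pytest.approx(best_stat)
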