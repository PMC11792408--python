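"""The Density-and-Spatial-Score (DSS) risk model.

The DSS is a linear risk score over immune-cell features measured in the
TC-TLS compartment: three phenotype densities (cells/mm²) and two
effective scores, each weighted by a LASSO-Cox-derived coefficient,

    DSS = Σ_j  β_j · x_j        (no intercept),

with all published coefficients negative, so low DSS corresponds to
larger densities / effective scores — and to longer survival. Patients
are dichotomised at an optimal cutoff (maximally selected log-rank
statistic with a group-size floor) into high- and low-DSS groups.

Fitting: the candidate feature space (the 143-characteristic density +
spatial space in the original design) is screened by an L1-penalised Cox
model; the penalty is chosen by ten-fold cross-validated partial-
likelihood deviance. Features are standardised internally; coefficients
are reported on the original feature scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cellmap import ClinicalRecord
from .errors import AlignmentError, ConfigError, UnfittableError
from .stats import logrank_test

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class DSSModel:
    """An ordered list of (feature descriptor, coefficient) plus a cutoff."""

    terms: tuple[tuple[str, float], ...]
    cutoff: float | None = None

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.terms]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.terms], dtype=float)


def published_dss_model() -> DSSModel:
    """The published five-term DSS model (versioned package data)."""
    return load_dss_model(_DATA_DIR / "published_dss.yaml")


def load_dss_model(path: str | Path) -> DSSModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    terms = tuple((t["feature"], float(t["coefficient"])) for t in cfg["terms"])
    cutoff = cfg.get("cutoff")
    return DSSModel(terms=terms, cutoff=None if cutoff is None else float(cutoff))


def save_dss_model(model: DSSModel, path: str | Path) -> None:
    cfg = {
        "version": 1,
        "terms": [{"feature": f, "coefficient": float(c)} for f, c in model.terms],
        "cutoff": model.cutoff,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# feature assembly

def assemble_features(
    density_slice: pd.DataFrame,
    effscore_slice: pd.DataFrame | None = None,
    compartment: str | None = "TC-TLS",
) -> pd.DataFrame:
    """Concatenate density and effective-score feature slices.

    Both slices are patients × descriptors; they must share the patient
    set (disjoint sets raise :class:`AlignmentError`). By default only
    TC-TLS-compartment descriptors are kept. Per-feature missingness
    fractions are recorded in ``.attrs["missing_fraction"]``.
    """
    if effscore_slice is None or effscore_slice.shape[1] == 0:
        matrix = density_slice.copy()
    else:
        shared = density_slice.index.intersection(effscore_slice.index)
        if len(shared) == 0:
            raise AlignmentError("density and effective-score slices share no patients")
        if not (len(shared) == len(density_slice) == len(effscore_slice)):
            raise AlignmentError(
                "density and effective-score slices must cover the same patients "
                f"(density {len(density_slice)}, spatial {len(effscore_slice)}, "
                f"shared {len(shared)})"
            )
        matrix = pd.concat([density_slice, effscore_slice.loc[density_slice.index]], axis=1)
    if matrix.columns.duplicated().any():
        raise ConfigError("duplicate feature descriptors after assembly")
    if compartment is not None:
        keep = [c for c in matrix.columns if str(c).endswith(f"::{compartment}")]
        matrix = matrix[keep]
    matrix = matrix.sort_index(axis=0)
    matrix.attrs["missing_fraction"] = matrix.isna().mean().to_dict()
    return matrix


# ---------------------------------------------------------------------------
# scoring

def score_dss(features: pd.Series | pd.DataFrame, model: DSSModel) -> float | pd.Series:
    """DSS = Σ coefficient × feature value; missing terms propagate NaN.

    Accepts one patient's feature Series or a patients × features
    DataFrame (returns a Series of scores).
    """
    missing = [f for f in model.features if f not in (
        features.index if isinstance(features, pd.Series) else features.columns)]
    if missing:
        raise ConfigError(f"feature(s) absent from matrix: {missing}")
    coef = model.coefficients
    if isinstance(features, pd.Series):
        vals = features[model.features].to_numpy(float)
        return float(np.dot(coef, vals)) if np.isfinite(vals).all() else float("nan")
    vals = features[model.features].to_numpy(float)
    scores = vals @ coef
    scores[~np.isfinite(vals).all(axis=1)] = np.nan
    return pd.Series(scores, index=features.index, name="dss")


# ---------------------------------------------------------------------------
# LASSO-Cox fitting

@dataclass
class LassoCoxFit:
    """Result of a cross-validated L1 Cox fit."""

    coefficients: pd.Series        # original feature scale, all features
    alpha: float                   # chosen penalty
    alphas: np.ndarray             # penalty path
    cv_deviance: np.ndarray        # mean held-out deviance per alpha
    cv_deviance_se: np.ndarray
    n_used: int
    dropped_features: list[str] = field(default_factory=list)

    @property
    def selected(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]

    def to_model(self) -> DSSModel:
        sel = self.selected
        return DSSModel(terms=tuple(zip(sel.index, sel.to_numpy(float))))


def _neg_log_partial_likelihood(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow negative log partial likelihood of linear predictors."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp, time, event = lp[order], time[order], event[order]
    # cumulative log-sum-exp over the risk set (subjects with time >= t)
    m = lp.max()
    log_risk = np.log(np.cumsum(np.exp(lp - m))) + m
    # ties: every subject tied at time t shares the full risk set at t,
    # i.e. the cumsum up to the last index of its tied block
    _, inv = np.unique(time, return_inverse=True)
    tie_last = np.empty_like(inv)
    seen: dict[int, int] = {}
    for i, key in enumerate(inv):
        seen[int(key)] = i
    for i, key in enumerate(inv):
        tie_last[i] = seen[int(key)]
    ll = float(np.sum(event * (lp - log_risk[tie_last])))
    return -ll


def fit_lasso_cox(
    matrix: pd.DataFrame,
    outcomes: Sequence[ClinicalRecord] | pd.DataFrame,
    endpoint: str = "OS",
    folds: int = 10,
    seed: int = 0,
    alphas: np.ndarray | None = None,
    penalty_rule: str = "min",
    l1_ratio: float = 1.0,
) -> LassoCoxFit:
    """L1-penalised Cox regression with k-fold cross-validated penalty choice.

    Patients with any missing feature (e.g. lacking a TC-TLS region) are
    excluded from fitting, not imputed; all-missing feature columns are
    dropped with a warning. The penalty minimising mean held-out
    partial-likelihood deviance is chosen (``penalty_rule="1se"`` picks
    the sparsest model within one standard error). The fold assignment
    is seeded, so the fit is deterministic given ``seed``.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if isinstance(outcomes, pd.DataFrame):
        out_df = outcomes
    else:
        out_df = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in outcomes],
                "time": [r.endpoint_times[endpoint] for r in outcomes],
                "event": [r.endpoint_events[endpoint] for r in outcomes],
            }
        ).set_index("patient_id")

    dropped = [c for c in matrix.columns if matrix[c].isna().all()]
    if dropped:
        warnings.warn(f"dropping all-missing feature columns: {dropped}", stacklevel=2)
    X = matrix.drop(columns=dropped)
    shared = X.index.intersection(out_df.index)
    X = X.loc[shared].dropna(axis=0)
    y_df = out_df.loc[X.index]
    time = y_df["time"].to_numpy(float)
    event = y_df["event"].to_numpy(bool)
    if event.sum() < 2:
        raise UnfittableError(f"{int(event.sum())} events; at least 2 required")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).to_numpy(float)
    y = Surv.from_arrays(event=event, time=time)

    path_model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alpha_min_ratio=0.01,
                                        n_alphas=60, fit_baseline_model=False)
    if alphas is None:
        path_model.fit(Z, y)
        alphas = np.asarray(path_model.alphas_)
    alphas = np.asarray(alphas, dtype=float)

    rng_folds = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_dev = np.full((folds, len(alphas)), np.nan)
    for k, (tr, te) in enumerate(rng_folds.split(Z)):
        if event[te].sum() == 0 or event[tr].sum() < 2:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                   fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Z[tr], y[tr])
        fitted = np.asarray(m.alphas_)
        coefs = m.coef_  # (p, n_fitted)
        for a_idx, a in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - a)))
            lp = Z[te] @ coefs[:, j]
            # deviance = 2 * (saturated - model) log-likelihood; the
            # saturated term is constant over alphas, so the null-referenced
            # quantity below ranks penalties identically to glmnet's.
            fold_dev[k, a_idx] = 2.0 * _neg_log_partial_likelihood(lp, time[te], event[te])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_dev = np.nanmean(fold_dev, axis=0)
        se_dev = np.nanstd(fold_dev, axis=0, ddof=1) / math.sqrt(folds)

    best = int(np.nanargmin(mean_dev))
    if penalty_rule == "1se":
        limit = mean_dev[best] + se_dev[best]
        # alphas are decreasing: earlier = stronger penalty = sparser
        candidates = [i for i in range(len(alphas)) if mean_dev[i] <= limit]
        best = min(candidates, key=lambda i: -alphas[i])
    elif penalty_rule != "min":
        raise ConfigError(f"unknown penalty_rule {penalty_rule!r}")
    alpha = float(alphas[best])

    final = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[alpha],
                                   fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Z, y)
    beta_std = final.coef_[:, 0]
    beta_orig = beta_std / sd.to_numpy(float)
    return LassoCoxFit(
        coefficients=pd.Series(beta_orig, index=X.columns, name="coefficient"),
        alpha=alpha,
        alphas=alphas,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
        n_used=len(X),
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# optimal cutoff

@dataclass
class CutoffResult:
    cutoff: float
    statistic: float
    labels: pd.Series  # "high" (> cutoff) / "low" (≤ cutoff)
    n_high: int
    n_low: int


def find_optimal_cutoff(
    scores: pd.Series,
    times,
    events,
    min_group_fraction: float = 0.1,
) -> CutoffResult:
    """Maximally selected log-rank cutoff for survival dichotomisation.

    Candidate cutoffs are the midpoints of consecutive sorted unique
    scores; candidates leaving either group below
    ``min_group_fraction`` of patients are infeasible. The cutoff
    maximising the two-group log-rank statistic wins; ties break toward
    the smaller cutoff. Labels are "high" (> cutoff) and "low" (≤ cutoff).
    """
    s = pd.Series(scores).astype(float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if s.isna().any():
        raise ValueError("scores contain missing values; exclude those patients first")
    uniq = np.unique(s.to_numpy())
    if len(uniq) < 2:
        raise UnfittableError("all scores identical; no feasible cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(s)
    floor = max(1, math.ceil(min_group_fraction * n))
    best: tuple[float, float] | None = None  # (statistic, cutoff)
    for c in mids:
        high = s.to_numpy() > c
        if high.sum() < floor or (~high).sum() < floor:
            continue
        res = logrank_test(t[high], e[high], t[~high], e[~high])
        if best is None or res.statistic > best[0]:
            best = (res.statistic, float(c))
    if best is None:
        raise UnfittableError(
            f"no cutoff leaves ≥{floor} patients per group (n={n})"
        )
    stat, cutoff = best
    labels = pd.Series(np.where(s > cutoff, "high", "low"), index=s.index, name="dss_group")
    return CutoffResult(cutoff=cutoff, statistic=stat, labels=labels,
                        n_high=int((labels == "high").sum()),
                        n_low=int((labels == "low").sum()))
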