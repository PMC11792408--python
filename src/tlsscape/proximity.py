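"""The "effective score": a radius-based proximity statistic.

For a centre phenotype and a surrounding phenotype within one tissue
compartment, cells are paired when their nucleus-to-nucleus Euclidean
distance is at most a preselected radius (default 20 µm, boundary
inclusive). The score divides a pairing count by a centre-cell count:

* numerator — ``unique_surround`` (default): distinct surrounding cells
  with at least one paired centre; ``all_pairs``: number of
  (centre, surround) pairs;
* denominator — ``all_centres`` (default): all centre cells in the
  compartment; ``paired_centres``: centre cells with at least one pair.

Both conventions appear in the field's descriptions of the statistic;
all four combinations are first-class here. A high score indicates more
pronounced cell-by-cell encirclement. Under complete spatial randomness
with surround intensity λ (cells/µm²), the ``all_pairs``/``all_centres``
score tends to λ·π·r² as the observation window grows.

Pairing never crosses slides. Within a patient, region instances of one
compartment are pooled: counts are summed across regions and slides
before dividing. Cells satisfying both phenotypes count in both roles
but a cell never pairs with itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .cellmap import COMPARTMENTS, Dataset
from .errors import ConfigError

_DATA_DIR = Path(__file__).parent / "data"

NUMERATOR_MODES = ("unique_surround", "all_pairs")
DENOMINATOR_MODES = ("all_centres", "paired_centres")


@dataclass(frozen=True)
class EffectiveScoreSpec:
    """Centre phenotype, surround phenotype, compartment, radius and modes."""

    centre_phenotype: str
    surround_phenotype: str
    compartment: str
    radius_um: float = 20.0
    numerator_mode: str = "unique_surround"
    denominator_mode: str = "all_centres"

    def __post_init__(self):
        if not self.radius_um > 0:
            raise ConfigError("radius_um must be > 0")
        if self.numerator_mode not in NUMERATOR_MODES:
            raise ConfigError(f"numerator_mode must be one of {NUMERATOR_MODES}")
        if self.denominator_mode not in DENOMINATOR_MODES:
            raise ConfigError(f"denominator_mode must be one of {DENOMINATOR_MODES}")

    @property
    def feature_name(self) -> str:
        """Descriptor: ``effscore::<centre>::<surround>::<compartment>``."""
        return f"effscore::{self.centre_phenotype}::{self.surround_phenotype}::{self.compartment}"


@dataclass(frozen=True)
class EffectiveScoreResult:
    patient_id: str
    spec: EffectiveScoreSpec
    n_centres: int
    n_paired_surround: int
    n_pairs: int
    score: float | None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.score is None


def pair_cells(
    centres: pd.DataFrame,
    surrounds: pd.DataFrame,
    radius_um: float,
) -> set[tuple[str, str]]:
    """All (centre_id, surround_id) pairs within ``radius_um`` (inclusive).

    ``centres`` and ``surrounds`` need ``cell_id``, ``x_um``, ``y_um``
    columns with coordinates in micrometres on one slide. A cell id never
    pairs with itself even when it satisfies both phenotypes.
    """
    if len(centres) == 0 or len(surrounds) == 0:
        return set()
    c_ids = centres["cell_id"].to_numpy()
    s_ids = surrounds["cell_id"].to_numpy()
    c_xy = centres[["x_um", "y_um"]].to_numpy(float)
    s_xy = surrounds[["x_um", "y_um"]].to_numpy(float)
    tree = cKDTree(s_xy)
    neighbours = tree.query_ball_point(c_xy, r=radius_um)
    pairs: set[tuple[str, str]] = set()
    for i, hits in enumerate(neighbours):
        ci = c_ids[i]
        for j in hits:
            sj = s_ids[j]
            if ci != sj:
                pairs.add((ci, sj))
    return pairs


def _eroded_union(boundaries: Iterable[BaseGeometry], guard_um: float) -> BaseGeometry | None:
    geoms = [g for g in boundaries if g is not None]
    if not geoms:
        return None
    return unary_union(geoms).buffer(-guard_um)


def compute_effective_score(
    dataset: Dataset,
    spec: EffectiveScoreSpec,
    patient_id: str,
    guard_um: float = 0.0,
) -> EffectiveScoreResult:
    """Effective score for one patient under one spec.

    The score is restricted to cells inside regions of
    ``spec.compartment`` across the patient's slides and is missing
    (``score=None``) when the denominator is zero or the compartment is
    absent.

    ``guard_um`` enables a minus-sampling edge correction: centre cells
    closer than ``guard_um`` to the boundary of their compartment's
    region polygon are excluded from both counts (surrounding cells are
    kept everywhere). The default 0 is the uncorrected statistic; the
    correction makes the CSR expectation λπr² exact and requires region
    boundaries.
    """
    if spec.compartment not in COMPARTMENTS:
        raise ConfigError(f"unknown compartment {spec.compartment!r}")
    memberships = dataset.memberships
    if memberships is None:
        raise ConfigError("assign phenotypes before computing effective scores")
    for phen in (spec.centre_phenotype, spec.surround_phenotype):
        if phen not in memberships.columns:
            raise ConfigError(f"phenotype {phen!r} has no assigned memberships")

    regions = dataset.regions_of(patient_id, spec.compartment)
    if not regions:
        return EffectiveScoreResult(patient_id, spec, 0, 0, 0, None,
                                    reason=f"no {spec.compartment} region")

    cells = dataset.cells
    centre_member = memberships[spec.centre_phenotype].to_numpy()
    surround_member = memberships[spec.surround_phenotype].to_numpy()

    n_centres = 0
    paired_centres: set[str] = set()
    paired_surrounds: set[str] = set()
    n_pairs = 0
    for slide_id in sorted({r.slide_id for r in regions}):
        slide_regions = [r for r in regions if r.slide_id == slide_id]
        region_ids = {r.region_id for r in slide_regions}
        in_comp = (cells["slide_id"].to_numpy() == slide_id) & np.isin(
            cells["region_id"].to_numpy(), list(region_ids)
        )
        centres = cells.loc[in_comp & centre_member]
        surrounds = cells.loc[in_comp & surround_member]
        if guard_um > 0:
            interior = _eroded_union((r.boundary for r in slide_regions), guard_um)
            if interior is None:
                raise ConfigError("guard_um requires region boundaries")
            import shapely

            keep = shapely.contains_xy(
                interior, centres["x_um"].to_numpy(), centres["y_um"].to_numpy()
            )
            centres = centres.loc[keep]
        n_centres += len(centres)
        pairs = pair_cells(centres, surrounds, spec.radius_um)
        n_pairs += len(pairs)
        paired_centres.update(c for c, _ in pairs)
        paired_surrounds.update(s for _, s in pairs)

    numerator = len(paired_surrounds) if spec.numerator_mode == "unique_surround" else n_pairs
    denominator = n_centres if spec.denominator_mode == "all_centres" else len(paired_centres)
    if denominator == 0:
        return EffectiveScoreResult(patient_id, spec, n_centres, len(paired_surrounds),
                                    n_pairs, None, reason="zero denominator")
    return EffectiveScoreResult(
        patient_id, spec, n_centres, len(paired_surrounds), n_pairs,
        numerator / denominator,
    )


def effective_score_matrix(
    dataset: Dataset,
    specs: Sequence[EffectiveScoreSpec],
) -> pd.DataFrame:
    """Patients × specs table of effective scores (NaN where missing)."""
    patients = dataset.patients
    out = pd.DataFrame(
        np.nan,
        index=pd.Index(patients, name="patient_id"),
        columns=[s.feature_name for s in specs],
    )
    for pid in patients:
        for spec in specs:
            res = compute_effective_score(dataset, spec, pid)
            if not res.is_missing:
                out.loc[pid, spec.feature_name] = res.score
    return out


def effective_score_long_table(dataset: Dataset, specs: Sequence[EffectiveScoreSpec]) -> pd.DataFrame:
    rows = []
    for pid in dataset.patients:
        for spec in specs:
            res = compute_effective_score(dataset, spec, pid)
            rows.append(
                {
                    "patient_id": pid,
                    "centre_phenotype": spec.centre_phenotype,
                    "surround_phenotype": spec.surround_phenotype,
                    "compartment": spec.compartment,
                    "radius_um": spec.radius_um,
                    "n_centres": res.n_centres,
                    "n_paired_surround": res.n_paired_surround,
                    "score": np.nan if res.is_missing else res.score,
                }
            )
    return pd.DataFrame(rows)


def load_score_specs(path: str | Path | None = None) -> list[EffectiveScoreSpec]:
    """Load effective-score specs from YAML (default: the shipped list)."""
    path = Path(path) if path is not None else _DATA_DIR / "default_effective_scores.yaml"
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [
        EffectiveScoreSpec(
            centre_phenotype=e["centre"],
            surround_phenotype=e["surround"],
            compartment=e["compartment"],
            radius_um=float(e.get("radius_um", 20.0)),
            numerator_mode=e.get("numerator_mode", "unique_surround"),
            denominator_mode=e.get("denominator_mode", "all_centres"),
        )
        for e in entries
    ]
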