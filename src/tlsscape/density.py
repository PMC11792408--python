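"""Region-stratified phenotype densities.

Density of a phenotype in a tissue compartment is the count of member
cells over the compartment area:  density = ΣC_P / Area  (cells/mm²).
When a patient has several region instances of one compartment (possibly
across slides), the default pooling is the ratio of sums — total member
count over total area — with mean-of-ratios available as an alternative.
A compartment absent for a patient yields a *missing* value, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellmap import COMPARTMENTS, Dataset
from .errors import ConfigError


def feature_name(phenotype: str, compartment: str) -> str:
    """Descriptor of a density feature column: ``density::<phen>::<comp>``."""
    return f"density::{phenotype}::{compartment}"


@dataclass(frozen=True)
class DensityFeature:
    patient_id: str
    phenotype: str
    compartment: str
    density: float  # cells per mm²
    n_cells: int
    area_mm2: float


def compute_density(
    dataset: Dataset,
    phenotype: str,
    compartment: str,
    patient_id: str,
    mode: str = "pooled",
) -> DensityFeature:
    """Density of one phenotype in one compartment for one patient.

    ``mode="pooled"`` (default): summed member counts over summed areas
    across all region instances of the compartment on the patient's
    slides. ``mode="mean_of_ratios"``: unweighted mean of per-region
    densities.

    Raises :class:`ConfigError` for an unknown phenotype or compartment,
    ``ValueError`` if the patient has no region of the compartment or the
    total area is zero (density undefined — use :func:`density_matrix`
    for missing-tolerant tabulation).
    """
    if compartment not in COMPARTMENTS:
        raise ConfigError(f"unknown compartment {compartment!r}")
    if dataset.memberships is None or phenotype not in dataset.memberships.columns:
        raise ConfigError(f"phenotype {phenotype!r} has no assigned memberships")
    if mode not in ("pooled", "mean_of_ratios"):
        raise ConfigError(f"unknown pooling mode {mode!r}")

    regions = dataset.regions_of(patient_id, compartment)
    if not regions:
        raise ValueError(f"patient {patient_id!r} has no {compartment} region")

    member = dataset.memberships[phenotype].to_numpy()
    cells = dataset.cells
    counts, areas = [], []
    for r in regions:
        in_region = (cells["slide_id"].to_numpy() == r.slide_id) & (
            cells["region_id"].to_numpy() == r.region_id
        )
        counts.append(int((member & in_region).sum()))
        areas.append(r.area_mm2)
    total_area = float(sum(areas))
    total_count = int(sum(counts))
    if total_area <= 0:
        raise ValueError(f"zero total {compartment} area for patient {patient_id!r}")
    if mode == "pooled":
        density = total_count / total_area
    else:
        density = float(np.mean([c / a for c, a in zip(counts, areas) if a > 0]))
    return DensityFeature(patient_id, phenotype, compartment, density, total_count, total_area)


def density_matrix(
    dataset: Dataset,
    phenotypes: list[str] | None = None,
    compartments: list[str] | None = None,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Patients × (phenotype, compartment) density table.

    One row per patient; columns named by :func:`feature_name`. Missing
    compartments yield NaN, never zeros.
    """
    if dataset.memberships is None:
        raise ConfigError("assign phenotypes before computing densities")
    phenotypes = phenotypes or list(dataset.memberships.columns)
    compartments = compartments or list(COMPARTMENTS)
    patients = dataset.patients
    columns = [feature_name(p, c) for p in phenotypes for c in compartments]
    out = pd.DataFrame(np.nan, index=pd.Index(patients, name="patient_id"), columns=columns)
    for pid in patients:
        for comp in compartments:
            if not dataset.regions_of(pid, comp):
                continue
            for phen in phenotypes:
                feat = compute_density(dataset, phen, comp, pid, mode=mode)
                out.loc[pid, feature_name(phen, comp)] = feat.density
    return out


def density_long_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format export: patient_id, phenotype, compartment, density."""
    rows = []
    for pid, row in matrix.iterrows():
        for col, val in row.items():
            _, phen, comp = str(col).split("::")
            rows.append(
                {
                    "patient_id": pid,
                    "phenotype": phen,
                    "compartment": comp,
                    "density_cells_per_mm2": val,
                }
            )
    return pd.DataFrame(rows)
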