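"""Domain types, validation and I/O for cell maps, regions and clinical tables.

The on-disk formats mirror what whole-slide analysis software (QuPath and
kin) exports after cell segmentation and classifier-based tissue
annotation:

* **cell table** — CSV/TSV, one row per segmented cell:
  ``cell_id,slide_id,region_id,x_um,y_um,<MARKER>...`` with marker columns
  holding 0/1 positivity calls;
* **region table** — CSV, one row per annotated tissue compartment
  instance: ``region_id,slide_id,compartment,area_mm2[,wkt_boundary]``
  where the optional boundary is a well-known-text polygon in micrometre
  coordinates;
* **clinical table** — CSV, one row per patient:
  ``patient_id,<endpoint>_time_months,<endpoint>_event,...`` for the four
  survival endpoints, remaining columns treated as covariates.

Coordinates are micrometres in image convention (origin top-left, y
increasing downward). Only Euclidean distances are consumed downstream,
so the orientation is unobservable; it is documented for interoperability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely.wkt
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .errors import ParseError, SchemaError

#: The seven tissue compartments of the TC / IM / N region scheme: tumour
#: core split into tumour epithelium, stroma and tertiary lymphoid
#: structures (TLS); invasion margin (band ±1 mm around the tumour
#: boundary) and peri-tumoural normal tissue each split into TLS vs rest.
COMPARTMENTS = (
    "TC-Tumour",
    "TC-Stroma",
    "TC-TLS",
    "IM-TLS",
    "IM-non-TLS",
    "N-TLS",
    "N-non-TLS",
)

TLS_COMPARTMENTS = ("TC-TLS", "IM-TLS", "N-TLS")

#: Minimum maximum-caliper diameter for a region to qualify as a TLS (µm).
TLS_MIN_DIAMETER_UM = 200.0

ENDPOINTS = ("irOS", "irPFS", "OS", "PFS")

#: The seventeen-marker multiplex immunohistochemistry vocabulary used by
#: the default panel (T-cell lineage and exhaustion receptors, Treg and
#: checkpoint markers, macrophage markers, B-cell/follicular markers,
#: fibroblast and neutrophil markers).
DEFAULT_MARKERS = (
    "CD8", "PD-1", "TIM-3", "LAG-3",
    "CD4", "FoxP3", "CTLA-4", "PD-L1",
    "CD68", "CD163", "CD86", "STING",
    "CD20", "CD21", "CD3", "FAP", "CD66b",
)

CELL_BASE_COLUMNS = ("cell_id", "slide_id", "region_id", "x_um", "y_um")


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered marker vocabulary for one staining panel."""

    panel_id: str
    markers: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"panel {self.panel_id!r} has duplicate markers")

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


DEFAULT_PANEL = PanelDefinition("default", DEFAULT_MARKERS)


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: position, marker positivity calls, region."""

    cell_id: str
    slide_id: str
    region_id: str
    x_um: float
    y_um: float
    markers: Mapping[str, bool]


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled tissue compartment instance with its measured area.

    ``boundary`` is optional; region membership of cells is taken from the
    input label column, not recomputed from polygons (the compartments are
    pathologist/classifier assignments) — the polygon is used only for
    validation and for edge-corrected spatial statistics.
    """

    region_id: str
    slide_id: str
    compartment: str
    area_mm2: float
    boundary: BaseGeometry | None = None

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )

    @property
    def is_tls(self) -> bool:
        return self.compartment in TLS_COMPARTMENTS

    def caliper_diameter_um(self) -> float | None:
        """Maximum pairwise distance between boundary vertices (µm).

        A caliper approximation of the diameter; exact for convex
        aggregates, which TLS effectively are.
        """
        if self.boundary is None:
            return None
        hull = self.boundary.convex_hull
        coords = np.asarray(hull.exterior.coords) if hull.geom_type == "Polygon" else np.asarray(hull.coords)
        if len(coords) < 2:
            return 0.0
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient survival endpoints and baseline covariates.

    Endpoint semantics: ``irOS``/``irPFS`` are clocked from the initiation
    of immunotherapy (to death, or to progression/death, respectively);
    ``OS``/``PFS`` are clocked from diagnosis. Times are months.
    """

    patient_id: str
    endpoint_times: Mapping[str, float]
    endpoint_events: Mapping[str, bool]
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.endpoint_times:
            if name not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {name!r}; expected {ENDPOINTS}")
            if self.endpoint_times[name] < 0:
                raise ValueError(f"negative {name} time for {self.patient_id}")


@dataclass(frozen=True)
class TableDialect:
    """Delimiter and column-alias configuration for reading cell tables."""

    delimiter: str = ","
    aliases: Mapping[str, str] = field(default_factory=dict)  # file column -> canonical

    def canonical(self, column: str) -> str:
        return self.aliases.get(column, column)


@dataclass
class Dataset:
    """An in-memory study dataset: cells, regions, clinical, slide→patient map.

    ``cells`` is a DataFrame with the columns of :data:`CELL_BASE_COLUMNS`
    plus one 0/1 column per marker; ``memberships`` (cell × phenotype
    booleans) is attached by :func:`tlsscape.phenotyping.assign_phenotypes`.
    """

    cells: pd.DataFrame
    regions: list[RegionAnnotation]
    clinical: list[ClinicalRecord] = field(default_factory=list)
    slide_patients: dict[str, str] = field(default_factory=dict)
    memberships: pd.DataFrame | None = None

    @property
    def marker_columns(self) -> list[str]:
        return [c for c in self.cells.columns if c not in CELL_BASE_COLUMNS]

    def patient_of(self, slide_id: str) -> str:
        """Patient owning a slide; defaults to the slide id itself."""
        return self.slide_patients.get(slide_id, slide_id)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.clinical:
            seen.setdefault(rec.patient_id, None)
        for r in self.regions:
            seen.setdefault(self.patient_of(r.slide_id), None)
        for s in self.cells["slide_id"].unique():
            seen.setdefault(self.patient_of(s), None)
        return list(seen)

    def regions_of(self, patient_id: str, compartment: str | None = None) -> list[RegionAnnotation]:
        out = [r for r in self.regions if self.patient_of(r.slide_id) == patient_id]
        if compartment is not None:
            out = [r for r in out if r.compartment == compartment]
        return out


# ---------------------------------------------------------------------------
# cell table I/O

def cells_to_frame(cells: Iterable[CellRecord], markers: Sequence[str] | None = None) -> pd.DataFrame:
    cells = list(cells)
    if markers is None:
        markers = list(cells[0].markers) if cells else []
    rows = [
        {
            "cell_id": c.cell_id,
            "slide_id": c.slide_id,
            "region_id": c.region_id,
            "x_um": c.x_um,
            "y_um": c.y_um,
            **{m: int(bool(c.markers.get(m, False))) for m in markers},
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=list(CELL_BASE_COLUMNS) + list(markers))


def frame_to_cells(frame: pd.DataFrame) -> list[CellRecord]:
    markers = [c for c in frame.columns if c not in CELL_BASE_COLUMNS]
    marker_arrays = {m: frame[m].to_numpy() for m in markers}
    return [
        CellRecord(
            cell_id=str(frame["cell_id"].iat[i]),
            slide_id=str(frame["slide_id"].iat[i]),
            region_id=str(frame["region_id"].iat[i]),
            x_um=float(frame["x_um"].iat[i]),
            y_um=float(frame["y_um"].iat[i]),
            markers={m: bool(marker_arrays[m][i]) for m in markers},
        )
        for i in range(len(frame))
    ]


def read_cell_table(path: str | Path, dialect: TableDialect | None = None) -> list[CellRecord]:
    """Read a QuPath-style cell export into :class:`CellRecord` objects.

    Marker columns (everything beyond the five mandatory columns) are
    coerced to boolean; non-numeric coordinates raise a row-level
    :class:`~tlsscape.errors.ParseError` with the offending line number.
    """
    frame = read_cell_frame(path, dialect)
    return frame_to_cells(frame)


def read_cell_frame(path: str | Path, dialect: TableDialect | None = None) -> pd.DataFrame:
    dialect = dialect or TableDialect()
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    frame.columns = [dialect.canonical(c) for c in frame.columns]
    for col in CELL_BASE_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"non-numeric {col} value {frame[col][bad].iloc[0]!r}", line=line)
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ParseError(f"missing {col}", line=line)
        frame[col] = coerced.astype(float)
    marker_cols = [c for c in frame.columns if c not in CELL_BASE_COLUMNS]
    truthy = {"1", "true", "True", "TRUE", "1.0"}
    for col in marker_cols:
        frame[col] = frame[col].map(lambda v: int(str(v).strip() in truthy)).astype(np.int8)
    for col in ("cell_id", "slide_id", "region_id"):
        frame[col] = frame[col].astype(str)
    return frame.reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame | Iterable[CellRecord], path: str | Path,
                     dialect: TableDialect | None = None) -> None:
    dialect = dialect or TableDialect()
    frame = cells if isinstance(cells, pd.DataFrame) else cells_to_frame(cells)
    frame.to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# region table I/O

def read_region_table(path: str | Path) -> list[RegionAnnotation]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    for col in ("region_id", "slide_id", "compartment", "area_mm2"):
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            area = float(row.area_mm2)
        except ValueError as exc:
            raise ParseError(f"non-numeric area_mm2 {row.area_mm2!r}", line=i + 2) from exc
        boundary = None
        wkt = getattr(row, "wkt_boundary", None)
        if isinstance(wkt, str) and wkt.strip():
            boundary = shapely.wkt.loads(wkt)
        out.append(
            RegionAnnotation(
                region_id=str(row.region_id),
                slide_id=str(row.slide_id),
                compartment=str(row.compartment),
                area_mm2=area,
                boundary=boundary,
            )
        )
    return out


def write_region_table(regions: Iterable[RegionAnnotation], path: str | Path,
                       slide_patients: Mapping[str, str] | None = None) -> None:
    """Write regions as CSV; an optional ``patient_id`` column records the
    slide → patient mapping so multi-slide patients survive a round trip."""
    rows = []
    for r in regions:
        row = {
            "region_id": r.region_id,
            "slide_id": r.slide_id,
            "compartment": r.compartment,
            "area_mm2": repr(r.area_mm2),
            "wkt_boundary": r.boundary.wkt if r.boundary is not None else "",
        }
        if slide_patients is not None:
            row["patient_id"] = slide_patients.get(r.slide_id, r.slide_id)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_slide_patient_map(path: str | Path) -> dict[str, str]:
    """Slide → patient mapping from a region table's ``patient_id`` column
    (empty when the column is absent: slide ids then stand for patients)."""
    frame = pd.read_csv(path, dtype=str)
    if "patient_id" not in frame.columns:
        return {}
    pairs = frame[["slide_id", "patient_id"]].dropna().drop_duplicates()
    return dict(zip(pairs["slide_id"], pairs["patient_id"]))


# ---------------------------------------------------------------------------
# clinical table I/O

def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    frame = pd.read_csv(path)
    if "patient_id" not in frame.columns:
        raise SchemaError(f"{path.name}: missing mandatory column 'patient_id'")
    time_cols = {ep: f"{ep}_time_months" for ep in ENDPOINTS if f"{ep}_time_months" in frame.columns}
    event_cols = {ep: f"{ep}_event" for ep in ENDPOINTS if f"{ep}_event" in frame.columns}
    covar_cols = [
        c for c in frame.columns
        if c != "patient_id" and c not in time_cols.values() and c not in event_cols.values()
    ]
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        times = {ep: float(d[col]) for ep, col in time_cols.items() if pd.notna(d[col])}
        events = {ep: bool(int(d[col])) for ep, col in event_cols.items() if pd.notna(d[col])}
        out.append(
            ClinicalRecord(
                patient_id=str(d["patient_id"]),
                endpoint_times=times,
                endpoint_events=events,
                covariates={c: d[c] for c in covar_cols},
            )
        )
    return out


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id}
        for ep, t in rec.endpoint_times.items():
            row[f"{ep}_time_months"] = t
        for ep, e in rec.endpoint_events.items():
            row[f"{ep}_event"] = int(e)
        row.update(rec.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    rule: str
    identifier: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def passed(self) -> bool:
        return not self.violations

    def by_rule(self, rule: str) -> list[Violation]:
        return [v for v in self.violations if v.rule == rule]


def validate_dataset(
    cells: pd.DataFrame | Iterable[CellRecord],
    regions: Iterable[RegionAnnotation],
    panel: PanelDefinition | None = None,
) -> ValidationReport:
    """Check every type invariant; violations are report entries, not errors.

    Rules: finite coordinates; region references resolve on the same
    slide; positive areas; polygon/recorded-area agreement (1 % relative);
    TLS caliper diameter > 200 µm; cell containment in its region polygon
    when a boundary is present; marker names within the panel vocabulary
    when a panel is given.
    """
    frame = cells if isinstance(cells, pd.DataFrame) else cells_to_frame(cells)
    regions = list(regions)
    violations: list[Violation] = []

    region_index = {(r.slide_id, r.region_id): r for r in regions}
    for r in regions:
        if not (r.area_mm2 > 0):
            violations.append(Violation("positive-area", r.region_id, f"area_mm2 = {r.area_mm2}"))
        if r.boundary is not None:
            poly_mm2 = r.boundary.area / 1e6
            if r.area_mm2 > 0 and abs(poly_mm2 - r.area_mm2) > 0.01 * r.area_mm2:
                violations.append(
                    Violation(
                        "area-agreement", r.region_id,
                        f"polygon area {poly_mm2:.4f} mm2 vs recorded {r.area_mm2:.4f} mm2",
                    )
                )
            if r.is_tls:
                diam = r.caliper_diameter_um()
                if diam is not None and not (diam > TLS_MIN_DIAMETER_UM):
                    violations.append(
                        Violation(
                            "tls-diameter", r.region_id,
                            f"TLS diameter ≤ 200 µm (caliper {diam:.1f} µm)",
                        )
                    )

    if len(frame):
        finite = np.isfinite(frame["x_um"].to_numpy()) & np.isfinite(frame["y_um"].to_numpy())
        for cid in frame.loc[~finite, "cell_id"]:
            violations.append(Violation("finite-coordinates", str(cid), "non-finite coordinate"))

        marker_cols = [c for c in frame.columns if c not in CELL_BASE_COLUMNS]
        if panel is not None:
            for m in marker_cols:
                if m not in panel:
                    violations.append(
                        Violation("panel-vocabulary", m, f"marker {m!r} not in panel {panel.panel_id!r}")
                    )

        for row in frame.itertuples(index=False):
            region = region_index.get((row.slide_id, row.region_id))
            if region is None:
                violations.append(
                    Violation("region-resolves", str(row.cell_id),
                              f"region {row.region_id!r} unknown on slide {row.slide_id!r}")
                )
                continue
            if region.boundary is not None and math.isfinite(row.x_um) and math.isfinite(row.y_um):
                # covers() is boundary-inclusive; tiny buffer absorbs
                # floating-point jitter from WKT round-trips.
                if not region.boundary.buffer(1e-6).covers(Point(row.x_um, row.y_um)):
                    violations.append(
                        Violation("containment", str(row.cell_id),
                                  f"cell outside region {row.region_id!r}")
                    )

    return ValidationReport(violations)


def _replace_boundary(region: RegionAnnotation, boundary: BaseGeometry | None) -> RegionAnnotation:
    return replace(region, boundary=boundary)
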