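"""Synthetic slides and cohorts with the structure the analysis assumes.

Tissue generator
----------------
A slide is a square window (micrometre coordinates). A circular tumour
sits at its centre; the tumour boundary defines three zones — tumour
core (TC, the disc interior inside the invasion margin), invasion margin
(IM, the ±1 mm band around the boundary) and peri-tumoural normal tissue
(N, everything outside). TLS are non-overlapping discs with diameter
sampled above 200 µm, placed inside a chosen zone; the core outside TLS
is split into tumour epithelium and a stromal stripe lattice.

Cells are drawn from homogeneous Poisson processes per (population,
region) with intensity = base density × compartment enrichment.
Spatial attraction between two populations is Neyman–Scott-like:
selected centre-population cells receive a Poisson-distributed number of
surround-population daughters placed uniformly within a fixed radius —
this directly creates a controllable excess in the effective score. With
attraction 0, every population is completely spatially random, and the
all_pairs/all_centres effective score has expectation λπr².

Cohort generator
----------------
Feature matrices follow a correlated log-normal model (densities on a
cells/mm² scale, effective scores on an O(1) scale) or are measured from
simulated slides. Survival is exponential with hazard
``baseline_hazard × exp(Σ β_j · z_j)`` over standardised true features;
censoring is independent exponential. Progression is generated as a
first event (hazard multiplied by ``progression_hazard_ratio``, shared
frailty through the same linear predictor), so PFS ≤ OS per patient;
the immunotherapy-clock endpoints (irOS/irPFS) subtract a
diagnosis-to-immunotherapy delay. Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .cellmap import (
    DEFAULT_MARKERS,
    ClinicalRecord,
    Dataset,
    RegionAnnotation,
)
from .errors import PlacementError

_UM2_PER_MM2 = 1e6


# ---------------------------------------------------------------------------
# tissue simulation

@dataclass(frozen=True)
class CellPopulation:
    """A simulated cell population: marker signature and placement rates."""

    name: str
    positive_markers: tuple[str, ...]
    base_density_per_mm2: float
    #: compartment -> multiplicative enrichment of the base density
    enrichment: Mapping[str, float] = field(default_factory=dict)

    def intensity(self, compartment: str) -> float:
        """Cells per mm² in a compartment."""
        return self.base_density_per_mm2 * float(self.enrichment.get(compartment, 1.0))


def default_populations() -> list[CellPopulation]:
    """Populations emulating a gastric tumour microenvironment panel.

    Lymphocytes are strongly enriched in TLS compartments (T/B aggregates),
    fibroblasts in stroma, terminally exhausted T cells and M1-like
    macrophages outside TLS at the invasion margin. Densities are in the
    tens-to-hundreds of cells/mm² range typical of immune infiltrates.
    """
    tls5 = {"TC-TLS": 5.0, "IM-TLS": 5.0, "N-TLS": 5.0}
    tls10 = {"TC-TLS": 10.0, "IM-TLS": 10.0, "N-TLS": 10.0}
    return [
        CellPopulation("cd8", ("CD3", "CD8"), 60.0, tls5),
        CellPopulation("cd8_pd1", ("CD3", "CD8", "PD-1"), 40.0, tls5),
        CellPopulation("cd8_tim3", ("CD3", "CD8", "TIM-3"), 15.0, {"TC-TLS": 2.0}),
        CellPopulation("cd8_pd1_tim3", ("CD3", "CD8", "PD-1", "TIM-3"), 15.0, {}),
        CellPopulation("cd8_lag3", ("CD3", "CD8", "LAG-3"), 10.0, {}),
        CellPopulation("cd8_exhausted", ("CD3", "CD8", "PD-1", "TIM-3", "LAG-3"),
                       10.0, {"IM-non-TLS": 2.0, "N-TLS": 2.0}),
        CellPopulation("cd4", ("CD3", "CD4"), 50.0, tls5),
        CellPopulation("treg", ("CD3", "CD4", "FoxP3", "CTLA-4"), 20.0, {"TC-TLS": 2.0}),
        CellPopulation("cd4_ctla4_pdl1", ("CD3", "CD4", "CTLA-4", "PD-L1"), 10.0, {}),
        CellPopulation("cd4_pdl1", ("CD3", "CD4", "PD-L1"), 15.0, {"TC-TLS": 3.0}),
        CellPopulation("b_cell", ("CD20",), 30.0, tls10),
        CellPopulation("fdc", ("CD21",), 10.0, tls10),
        CellPopulation("mac_m1", ("CD68", "CD86", "STING"), 25.0, {"IM-non-TLS": 2.0}),
        CellPopulation("mac_m2", ("CD68", "CD163"), 25.0, {"N-non-TLS": 2.0}),
        CellPopulation("fibroblast", ("FAP",), 30.0, {"TC-Stroma": 3.0}),
        CellPopulation("neutrophil", ("CD66b",), 20.0, {"N-non-TLS": 1.5}),
    ]


@dataclass(frozen=True)
class TissueSimConfig:
    """Geometry and intensity parameters of one simulated slide."""

    seed: int = 0
    slide_extent_um: tuple[float, float] = (6000.0, 6000.0)
    tumour_radius_um: float = 2000.0
    im_band_halfwidth_um: float = 1000.0
    #: zone -> number of TLS discs ("TC", "IM", "N")
    n_tls: Mapping[str, int] = field(default_factory=lambda: {"TC": 2, "IM": 2, "N": 2})
    tls_diameter_um: tuple[float, float] = (250.0, 450.0)
    stroma_period_um: float = 600.0
    stroma_width_um: float = 250.0
    populations: tuple[CellPopulation, ...] = field(
        default_factory=lambda: tuple(default_populations())
    )
    #: (centre population, surround population) -> mean daughters per centre
    attraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    attraction_radius_um: float = 20.0
    max_placement_retries: int = 200

    def __post_init__(self):
        lo, hi = self.tls_diameter_um
        if not lo > 200.0:
            raise ValueError("tls_diameter_um minimum must exceed 200 µm")
        if hi < lo:
            raise ValueError("tls_diameter_um range inverted")
        if not self.im_band_halfwidth_um > 0:
            raise ValueError("im_band_halfwidth_um must be positive")
        for pop in self.populations:
            if pop.base_density_per_mm2 < 0:
                raise ValueError(f"negative density for population {pop.name!r}")


def _sample_in_polygon(rng: np.random.Generator, geom: BaseGeometry, n: int,
                       max_batches: int = 1000) -> np.ndarray:
    """Uniform points in a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    out = []
    got = 0
    frac = max(geom.area / max(1e-12, (maxx - minx) * (maxy - miny)), 1e-4)
    for _ in range(max_batches):
        m = int((n - got) / frac * 1.2) + 8
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        out.append(pts)
        got += len(pts)
        if got >= n:
            break
    pts = np.concatenate(out)
    if len(pts) < n:  # pragma: no cover - pathological geometry
        raise PlacementError("rejection sampling failed to fill polygon")
    return pts[:n]


def _place_tls(rng: np.random.Generator, host: BaseGeometry, n: int,
               diam_range: tuple[float, float], existing: list[BaseGeometry],
               retries: int) -> list[BaseGeometry]:
    discs = []
    for _ in range(n):
        placed = False
        for _ in range(retries):
            d = rng.uniform(*diam_range)
            r = d / 2.0
            inner = host.buffer(-r)
            if inner.is_empty:
                continue
            (x, y), = _sample_in_polygon(rng, inner, 1)
            disc = Point(x, y).buffer(r, quad_segs=64)
            if all(not disc.intersects(e) for e in existing + discs):
                discs.append(disc)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {n} non-overlapping TLS discs in host zone"
            )
    return discs


def simulate_slide(config: TissueSimConfig, slide_id: str = "S1",
                   patient_id: str | None = None) -> Dataset:
    """Simulate one slide: region geometry plus a Poisson cell map.

    Returns a :class:`~tlsscape.cellmap.Dataset` whose regions carry
    polygon boundaries and whose recorded areas equal the polygon areas,
    so the result passes :func:`~tlsscape.cellmap.validate_dataset` with
    zero violations. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.slide_extent_um
    window = box(0.0, 0.0, w, h)
    cx, cy = w / 2.0, h / 2.0
    r_b = config.tumour_radius_um
    half = config.im_band_halfwidth_um

    tumour_disc = Point(cx, cy).buffer(r_b, quad_segs=128)
    core = Point(cx, cy).buffer(max(r_b - half, 0.0), quad_segs=128) & window
    im_band = (Point(cx, cy).buffer(r_b + half, quad_segs=128)
               - Point(cx, cy).buffer(max(r_b - half, 0.0), quad_segs=128)) & window
    normal = window - Point(cx, cy).buffer(r_b + half, quad_segs=128)

    hosts = {"TC": core, "IM": im_band, "N": normal}
    tls_by_zone: dict[str, list[BaseGeometry]] = {}
    existing: list[BaseGeometry] = []
    for zone in ("TC", "IM", "N"):
        n = int(config.n_tls.get(zone, 0))
        discs = _place_tls(rng, hosts[zone], n, config.tls_diameter_um,
                           existing, config.max_placement_retries)
        tls_by_zone[zone] = discs
        existing.extend(discs)

    core_free = core - unary_union(tls_by_zone["TC"]) if tls_by_zone["TC"] else core
    stripes = []
    x0 = config.stroma_period_um / 2.0
    while x0 < w:
        stripes.append(box(x0, 0.0, min(x0 + config.stroma_width_um, w), h))
        x0 += config.stroma_period_um
    stroma = core_free & unary_union(stripes)
    tumour_epi = core_free - stroma

    def _band_minus(zone: str, geomzone: BaseGeometry) -> BaseGeometry:
        discs = tls_by_zone[zone]
        return geomzone - unary_union(discs) if discs else geomzone

    regions: list[RegionAnnotation] = []
    geoms: list[tuple[str, BaseGeometry]] = [
        ("TC-Tumour", tumour_epi),
        ("TC-Stroma", stroma),
        ("IM-non-TLS", _band_minus("IM", im_band)),
        ("N-non-TLS", _band_minus("N", normal)),
    ]
    for zone, comp in (("TC", "TC-TLS"), ("IM", "IM-TLS"), ("N", "N-TLS")):
        for disc in tls_by_zone[zone]:
            geoms.append((comp, disc))
    k = 0
    for comp, geom in geoms:
        if geom.is_empty or geom.area <= 0:
            continue
        k += 1
        regions.append(
            RegionAnnotation(
                region_id=f"{slide_id}_r{k}",
                slide_id=slide_id,
                compartment=comp,
                area_mm2=geom.area / _UM2_PER_MM2,
                boundary=geom,
            )
        )

    # --- cells: homogeneous Poisson per (population, region)
    rows: list[dict] = []
    cell_counter = 0
    pop_index: dict[str, list[int]] = {p.name: [] for p in config.populations}
    for region in regions:
        area_um2 = region.boundary.area
        for pop in config.populations:
            lam = pop.intensity(region.compartment) / _UM2_PER_MM2 * area_um2
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            pts = _sample_in_polygon(rng, region.boundary, n)
            for x, y in pts:
                pop_index[pop.name].append(len(rows))
                rows.append(
                    {
                        "cell_id": f"{slide_id}_c{cell_counter}",
                        "slide_id": slide_id,
                        "region_id": region.region_id,
                        "x_um": float(x),
                        "y_um": float(y),
                        "_pop": pop.name,
                        "_region": region,
                    }
                )
                cell_counter += 1

    # --- Neyman–Scott attraction: daughters around centre-population cells
    for (centre_pop, surround_pop), mu in sorted(config.attraction.items()):
        if mu <= 0:
            continue
        for i in list(pop_index.get(centre_pop, [])):
            parent = rows[i]
            region: RegionAnnotation = parent["_region"]
            n_d = int(rng.poisson(mu))
            for _ in range(n_d):
                for _ in range(config.max_placement_retries):
                    rho = config.attraction_radius_um * math.sqrt(rng.uniform())
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    x = parent["x_um"] + rho * math.cos(theta)
                    y = parent["y_um"] + rho * math.sin(theta)
                    if region.boundary.covers(Point(x, y)):
                        pop_index[surround_pop].append(len(rows))
                        rows.append(
                            {
                                "cell_id": f"{slide_id}_c{cell_counter}",
                                "slide_id": slide_id,
                                "region_id": region.region_id,
                                "x_um": x,
                                "y_um": y,
                                "_pop": surround_pop,
                                "_region": region,
                            }
                        )
                        cell_counter += 1
                        break

    pop_by_name = {p.name: p for p in config.populations}
    markers = DEFAULT_MARKERS
    records = []
    for row in rows:
        pop = pop_by_name[row["_pop"]]
        rec = {k: v for k, v in row.items() if not k.startswith("_")}
        for m in markers:
            rec[m] = int(m in pop.positive_markers)
        records.append(rec)
    cells = pd.DataFrame(
        records,
        columns=["cell_id", "slide_id", "region_id", "x_um", "y_um", *markers],
    )
    if len(cells) == 0:
        cells = pd.DataFrame(
            columns=["cell_id", "slide_id", "region_id", "x_um", "y_um", *markers]
        )
    pid = patient_id if patient_id is not None else slide_id
    return Dataset(cells=cells, regions=regions, slide_patients={slide_id: pid})


def merge_datasets(datasets: Sequence[Dataset]) -> Dataset:
    """Concatenate per-slide datasets into one cohort dataset."""
    cells = pd.concat([d.cells for d in datasets], ignore_index=True)
    regions = [r for d in datasets for r in d.regions]
    slide_patients: dict[str, str] = {}
    clinical = []
    for d in datasets:
        slide_patients.update(d.slide_patients)
        clinical.extend(d.clinical)
    return Dataset(cells=cells, regions=regions, clinical=clinical,
                   slide_patients=slide_patients)


# ---------------------------------------------------------------------------
# cohort simulation

def _default_true_terms() -> tuple[tuple[str, float], ...]:
    # the five-feature structure of the DSS: three TC-TLS densities and
    # two TC-TLS effective scores, each protective (negative coefficient
    # on the standardised scale; |beta| = 0.5 => HR ~ 0.61 per SD)
    return (
        ("density::CD8+LAG-3+::TC-TLS", -0.5),
        ("density::CD4+FoxP3+CTLA-4+::TC-TLS", -0.5),
        ("density::CD4+CTLA-4+PD-L1+::TC-TLS", -0.5),
        ("effscore::CD8+LAG-3-PD-1-TIM-3-::CD8+LAG-3-PD-1-TIM-3+::TC-TLS", -0.5),
        ("effscore::CD8+LAG-3-PD-1+TIM-3-::CD8+LAG-3-PD-1+TIM-3+::TC-TLS", -0.5),
    )


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the synthetic patient cohort.

    ``true_terms`` are (feature descriptor, coefficient on the
    standardised feature scale); ``baseline_hazard`` and
    ``censoring_rate`` are exponential rates per month. The default
    censoring rate gives roughly 30 % censoring under the default
    effects. Decoy features share an equicorrelated Gaussian copula with
    correlation ``decoy_correlation``.
    """

    seed: int = 0
    n_patients: int = 300
    true_terms: tuple[tuple[str, float], ...] = field(default_factory=_default_true_terms)
    baseline_hazard: float = 0.03
    censoring_rate: float = 0.0075
    n_decoy_features: int = 138
    decoy_correlation: float = 0.2
    progression_hazard_ratio: float = 2.0
    immunotherapy_delay_months: tuple[float, float] = (1.0, 6.0)

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not (self.baseline_hazard > 0 and self.censoring_rate > 0):
            raise ValueError("rates must be positive")
        if not (0.0 <= self.decoy_correlation < 1.0):
            raise ValueError("decoy_correlation must be in [0, 1)")


def _lognormal_features(rng: np.random.Generator, n: int, names: list[str],
                        rho: float) -> pd.DataFrame:
    """Correlated log-normal features on domain-typical scales."""
    p = len(names)
    shared = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, p))
    z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps
    cols = {}
    for j, name in enumerate(names):
        if name.startswith("effscore::"):
            cols[name] = np.exp(math.log(0.8) + 0.6 * z[:, j])
        else:
            cols[name] = np.exp(math.log(150.0) + 0.8 * z[:, j])
    idx = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="patient_id")
    return pd.DataFrame(cols, index=idx)


def simulate_cohort(
    config: CohortSimConfig,
    dataset: Dataset | None = None,
    feature_matrix: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[ClinicalRecord]]:
    """Simulate a patient cohort: feature matrix plus survival outcomes.

    Features are drawn from the correlated log-normal model unless a
    measured ``feature_matrix`` (e.g. from simulated slides) is passed.
    Survival: OS time exponential with hazard
    ``baseline_hazard × exp(lp)``; progression as a competing first event
    with ``progression_hazard_ratio`` times that hazard sharing the same
    linear predictor, so PFS ≤ OS; independent exponential censoring;
    irOS/irPFS subtract a uniform diagnosis-to-immunotherapy delay.
    """
    rng = np.random.default_rng(config.seed)
    true_names = [f for f, _ in config.true_terms]
    if feature_matrix is None:
        decoys = [f"density::synthetic-feature-{i + 1:03d}::TC-TLS"
                  for i in range(config.n_decoy_features)]
        X = _lognormal_features(rng, config.n_patients, true_names + decoys,
                                config.decoy_correlation)
    else:
        X = feature_matrix.copy()

    usable = [f for f in true_names if f in X.columns]
    lp = np.zeros(len(X))
    betas = dict(config.true_terms)
    for f in usable:
        col = X[f].to_numpy(float)
        filled = np.where(np.isfinite(col), col, np.nanmean(col))
        sd = filled.std() or 1.0
        lp += betas[f] * (filled - filled.mean()) / sd

    h = config.baseline_hazard * np.exp(lp)
    t_death = rng.exponential(1.0 / h)
    t_prog = rng.exponential(1.0 / (config.progression_hazard_ratio * h))
    t_pfs = np.minimum(t_prog, t_death)
    cens = rng.exponential(1.0 / config.censoring_rate, size=len(X))
    delay = rng.uniform(*config.immunotherapy_delay_months, size=len(X))

    os_time = np.minimum(t_death, cens)
    os_event = t_death <= cens
    pfs_time = np.minimum(t_pfs, cens)
    pfs_event = t_pfs <= cens
    # floor at a small positive follow-up, never beyond the diagnosis-clock time
    eps = 0.05
    iros_time = np.maximum(os_time - delay, np.minimum(eps, os_time))
    irpfs_time = np.maximum(pfs_time - delay, np.minimum(eps, pfs_time))

    age = rng.integers(35, 85, size=len(X))
    sex = rng.choice(["Male", "Female"], p=[0.7, 0.3], size=len(X))
    clinical = [
        ClinicalRecord(
            patient_id=str(pid),
            endpoint_times={
                "OS": float(os_time[i]),
                "PFS": float(pfs_time[i]),
                "irOS": float(iros_time[i]),
                "irPFS": float(irpfs_time[i]),
            },
            endpoint_events={
                "OS": bool(os_event[i]),
                "PFS": bool(pfs_event[i]),
                "irOS": bool(os_event[i]),
                "irPFS": bool(pfs_event[i]),
            },
            covariates={"age": int(age[i]), "sex": str(sex[i])},
        )
        for i, pid in enumerate(X.index)
    ]
    return X, clinical


def simulate_cohort_slides(
    tissue_config: TissueSimConfig,
    n_patients: int,
    seed: int = 0,
) -> Dataset:
    """Simulate one slide per patient and merge into a cohort dataset.

    Per-patient seeds are derived from ``seed`` via a seeded sequence, so
    the cohort is reproducible and slides are mutually independent.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(n_patients)
    datasets = []
    for i, ss in enumerate(child_seeds):
        pid = f"P{i + 1:04d}"
        cfg = replace(tissue_config, seed=int(ss.generate_state(1)[0] % (2**31)))
        datasets.append(simulate_slide(cfg, slide_id=f"{pid}_s1", patient_id=pid))
    return merge_datasets(datasets)
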