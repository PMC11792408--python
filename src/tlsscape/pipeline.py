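"""End-to-end pipeline: read → phenotype → densities → effective scores
→ DSS → survival statistics, with a reproducible run manifest.

Stages are pure functions over files: each stage's outputs are written
before the next starts, and a rerun with identical config and inputs
reproduces identical output checksums. All randomness flows from the
single run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cellmap import (
    Dataset,
    read_cell_frame,
    read_clinical_table,
    read_region_table,
    read_slide_patient_map,
    validate_dataset,
)
from .density import density_matrix
from .dss import (
    find_optimal_cutoff,
    load_dss_model,
    published_dss_model,
    score_dss,
)
from .errors import ConfigError, TlsscapeError, UnfittableError
from .phenotyping import assign_phenotypes, load_registry
from .proximity import effective_score_matrix, load_score_specs
from .stats import cox_hr, kaplan_meier, logrank_test

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see ``RunConfig.from_yaml``)."""

    cells_path: Path
    regions_path: Path
    clinical_path: Path | None
    output_dir: Path
    registry_path: Path | None = None     # None = shipped default registry
    score_specs_path: Path | None = None  # None = shipped default specs
    model: str | Path = "published"       # "published", "fit", or a model file
    endpoint: str = "OS"
    seed: int = 0
    density_mode: str = "pooled"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.endpoint not in ("irOS", "irPFS", "OS", "PFS"):
            raise ConfigError(f"unknown endpoint {self.endpoint!r}")
        for p in (self.cells_path, self.regions_path, self.clinical_path,
                  self.registry_path, self.score_specs_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if isinstance(self.model, (str, Path)) and str(self.model) not in ("published", "fit"):
            if not Path(self.model).exists():
                raise ConfigError(f"model path does not exist: {self.model}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        inputs = cfg.get("inputs", {})
        return cls(
            cells_path=Path(inputs["cells"]),
            regions_path=Path(inputs["regions"]),
            clinical_path=Path(inputs["clinical"]) if inputs.get("clinical") else None,
            output_dir=Path(cfg["output_dir"]),
            registry_path=Path(cfg["registry"]) if cfg.get("registry") else None,
            score_specs_path=Path(cfg["score_specs"]) if cfg.get("score_specs") else None,
            model=cfg.get("model", "published"),
            endpoint=cfg.get("endpoint", "OS"),
            seed=int(cfg.get("seed", 0)),
            density_mode=cfg.get("density_mode", "pooled"),
            log_level=cfg.get("log_level", "INFO"),
        )

    def digest(self) -> str:
        payload = {
            k: str(v) for k, v in vars(self).items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list[dict[str, Any]] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in dependency order; outputs land in
    ``config.output_dir`` and the manifest records checksums.

    On a stage failure the manifest marks the stage failed, downstream
    stages are skipped, and the manifest is still written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config_hash=config.digest(),
                           seed=config.seed)
    state: dict[str, Any] = {}

    def _record_output(path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    def stage(name):
        def deco(fn):
            return (name, fn)
        return deco

    @stage("read")
    def _read(st):
        cells = read_cell_frame(config.cells_path)
        regions = read_region_table(config.regions_path)
        clinical = (read_clinical_table(config.clinical_path)
                    if config.clinical_path else [])
        ds = Dataset(cells=cells, regions=regions, clinical=clinical,
                     slide_patients=read_slide_patient_map(config.regions_path))
        report = validate_dataset(cells, regions)
        st["dataset"] = ds
        return {"n_cells": len(cells), "n_regions": len(regions),
                "n_violations": len(report.violations)}

    @stage("phenotype")
    def _phenotype(st):
        ds: Dataset = st["dataset"]
        defs = load_registry(config.registry_path)
        ds.memberships = assign_phenotypes(ds.cells, defs)
        return {"n_phenotypes": len(defs)}

    @stage("density")
    def _density(st):
        ds: Dataset = st["dataset"]
        dm = density_matrix(ds, mode=config.density_mode)
        path = out / "densities.tsv"
        dm.to_csv(path, sep="\t")
        _record_output(path)
        st["density"] = dm
        return {"shape": list(dm.shape)}

    @stage("effective_score")
    def _effscore(st):
        ds: Dataset = st["dataset"]
        specs = load_score_specs(config.score_specs_path)
        em = effective_score_matrix(ds, specs)
        path = out / "effective_scores.tsv"
        em.to_csv(path, sep="\t")
        _record_output(path)
        st["effscore"] = em
        return {"shape": list(em.shape)}

    @stage("dss")
    def _dss(st):
        from .dss import assemble_features, fit_lasso_cox

        features = assemble_features(st["density"], st["effscore"])
        fpath = out / "features.tsv"
        features.to_csv(fpath, sep="\t")
        _record_output(fpath)

        if str(config.model) == "fit":
            ds: Dataset = st["dataset"]
            fit = fit_lasso_cox(features, ds.clinical, endpoint=config.endpoint,
                                seed=config.seed)
            model = fit.to_model()
        elif str(config.model) == "published":
            model = published_dss_model()
        else:
            model = load_dss_model(config.model)
        scores = score_dss(features, model)
        spath = out / "dss_scores.tsv"
        scores.to_frame().to_csv(spath, sep="\t")
        _record_output(spath)
        st["scores"] = scores
        st["model"] = model
        return {
            "model_terms": len(model.terms),
            "n_scored": int(scores.notna().sum()),
            "n_missing": int(scores.isna().sum()),
        }

    @stage("statistics")
    def _stats(st):
        ds: Dataset = st["dataset"]
        scores: pd.Series = st["scores"]
        results: dict[str, Any] = {}
        if ds.clinical:
            times = {r.patient_id: r.endpoint_times.get(config.endpoint) for r in ds.clinical}
            events = {r.patient_id: r.endpoint_events.get(config.endpoint) for r in ds.clinical}
            usable = [p for p in scores.index
                      if not math.isnan(scores[p]) and times.get(p) is not None]
            if len(usable) >= 4:
                s = scores[usable]
                t = pd.Series({p: times[p] for p in usable})
                e = pd.Series({p: bool(events[p]) for p in usable})
                try:
                    cut = find_optimal_cutoff(s, t.to_numpy(), e.to_numpy())
                    hi = cut.labels == "high"
                    lr = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
                    km_hi = kaplan_meier(t[hi], e[hi])
                    km_lo = kaplan_meier(t[~hi], e[~hi])
                    # boolean indicator: True = "high" is the second level,
                    # so hr.hr is hazard of high relative to low
                    hr = cox_hr(hi.to_numpy(), t.to_numpy(), e.to_numpy())
                    results = {
                        "endpoint": config.endpoint,
                        "cutoff": cut.cutoff,
                        "n_high": cut.n_high,
                        "n_low": cut.n_low,
                        "median_high": km_hi.median_label,
                        "median_low": km_lo.median_label,
                        "logrank_p": lr.p_value,
                        "hr_high_vs_low": hr.hr,
                        "hr_ci": [hr.ci_lower, hr.ci_upper],
                    }
                except UnfittableError as exc:
                    results = {"endpoint": config.endpoint, "note": str(exc)}
        path = out / "survival_stats.json"
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _record_output(path)
        return {"computed": bool(results)}

    stages = [_read, _phenotype, _density, _effscore, _dss, _stats]
    failed = False
    for name, fn in stages:
        if failed:
            manifest.stages.append({"name": name, "status": "skipped"})
            continue
        try:
            info = fn(state)
            manifest.stages.append({"name": name, "status": "ok", **(info or {})})
            log.info("stage %s ok", name)
        except TlsscapeError as exc:
            manifest.stages.append({"name": name, "status": "failed", "error": str(exc)})
            log.error("stage %s failed: %s", name, exc)
            failed = True
    manifest.write(out / "manifest.json")
    return manifest
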