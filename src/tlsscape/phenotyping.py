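"""Phenotype gating: boolean marker-combination definitions over cells.

A phenotype is a conjunction of required-positive and required-negative
markers, e.g. ``CD8+LAG-3-PD-1+TIM-3-`` (an exhaustion-marker
combination on CD8 T cells). Gating is a pure function of the marker
vector; coordinates never matter. "Relative intensity" gradations are
collapsed to binary positivity calls — the thresholding happens in the
upstream imaging software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .cellmap import CELL_BASE_COLUMNS, DEFAULT_PANEL, PanelDefinition, cells_to_frame
from .errors import ConfigError

log = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named conjunction of required-positive / required-negative markers."""

    requires_positive: frozenset[str]
    requires_negative: frozenset[str]
    panel_id: str = "default"
    name: str = ""

    def __post_init__(self):
        overlap = self.requires_positive & self.requires_negative
        if overlap:
            raise ConfigError(f"markers required both positive and negative: {sorted(overlap)}")
        if not self.name:
            object.__setattr__(self, "name", self.canonical_name())

    def canonical_name(self, panel: PanelDefinition | None = None) -> str:
        """Name reconstructed from the two sets, ordered by the panel's markers.

        Sign suffixes are ASCII ``+`` / ``-`` (``CD8+LAG-3-PD-1+TIM-3-``).
        """
        panel = panel or DEFAULT_PANEL
        order = {m: i for i, m in enumerate(panel.markers)}
        referenced = sorted(
            self.requires_positive | self.requires_negative,
            key=lambda m: order.get(m, len(order)),
        )
        return "".join(f"{m}{'+' if m in self.requires_positive else '-'}" for m in referenced)

    def referenced_markers(self) -> frozenset[str]:
        return self.requires_positive | self.requires_negative


def make_phenotype(positive: Iterable[str], negative: Iterable[str] = (),
                   panel: PanelDefinition | None = None, name: str | None = None) -> PhenotypeDefinition:
    panel = panel or DEFAULT_PANEL
    pos, neg = frozenset(positive), frozenset(negative)
    for m in pos | neg:
        if m not in panel:
            raise ConfigError(f"marker {m!r} not in panel {panel.panel_id!r}")
    d = PhenotypeDefinition(pos, neg, panel_id=panel.panel_id, name=name or "")
    return d


def assign_phenotypes(
    cells: pd.DataFrame | Iterable,
    defs: Sequence[PhenotypeDefinition],
) -> pd.DataFrame:
    """Evaluate phenotype definitions over cells.

    Returns a boolean DataFrame indexed like ``cells`` (one row per cell,
    ``cell_id`` index) with one column per phenotype name. A cell is a
    member iff every required-positive marker is positive and every
    required-negative marker negative; one cell may satisfy several
    definitions. Cells whose table lacks a referenced marker column
    entirely trigger a :class:`~tlsscape.errors.ConfigError`; cells with a
    missing (NaN) call for a referenced marker are skipped for that
    definition (counted False) with a logged count — this is how cells
    from other staining panels are handled.
    """
    frame = cells if isinstance(cells, pd.DataFrame) else cells_to_frame(list(cells))
    marker_cols = [c for c in frame.columns if c not in CELL_BASE_COLUMNS]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate phenotype names in definitions")

    out = pd.DataFrame(index=frame.index)
    for d in defs:
        missing = d.referenced_markers() - set(marker_cols)
        if missing:
            raise ConfigError(
                f"definition {d.name!r} references unknown marker(s) {sorted(missing)}"
            )
        sub = frame[list(d.referenced_markers())]
        unevaluable = sub.isna().any(axis=1)
        if unevaluable.any():
            log.info("%d cells lack calls for %s; skipped", int(unevaluable.sum()), d.name)
        member = pd.Series(True, index=frame.index)
        for m in d.requires_positive:
            member &= frame[m].fillna(0).astype(bool)
        for m in d.requires_negative:
            member &= ~frame[m].fillna(1).astype(bool)
        member &= ~unevaluable
        out[d.name] = member.to_numpy()
    out.index = pd.Index(frame["cell_id"], name="cell_id")
    return out


def expand_subtype_space(
    panel: PanelDefinition,
    anchor: str | Iterable[str],
    conditional: Iterable[str],
) -> list[PhenotypeDefinition]:
    """All 2^k sign assignments over ``conditional`` markers, anchored positive.

    E.g. anchor ``CD8`` with conditional ``{LAG-3, PD-1, TIM-3}`` yields
    the eight exhaustion-combination subtypes. Refuses k > 6 as a
    combinatorial guard.
    """
    anchors = (anchor,) if isinstance(anchor, str) else tuple(anchor)
    conditional = sorted(set(conditional), key=lambda m: panel.markers.index(m) if m in panel.markers else -1)
    for m in (*anchors, *conditional):
        if m not in panel:
            raise ConfigError(f"marker {m!r} not in panel {panel.panel_id!r}")
    if len(conditional) > 6:
        raise ConfigError(f"refusing to expand {len(conditional)} conditional markers (limit 6)")
    out = []
    for signs in product((True, False), repeat=len(conditional)):
        pos = set(anchors) | {m for m, s in zip(conditional, signs) if s}
        neg = {m for m, s in zip(conditional, signs) if not s}
        out.append(make_phenotype(pos, neg, panel=panel))
    return out


# ---------------------------------------------------------------------------
# registry files

def load_registry(path: str | Path | None = None,
                  panel: PanelDefinition | None = None) -> list[PhenotypeDefinition]:
    """Load a phenotype registry (YAML list of {name, positive, negative}).

    With no path, loads the shipped default registry: the T-cell
    exhaustion combinations, CD4/Treg combinations, macrophage
    CD68/CD163/CD86/STING combinations, CD20/CD21/CD3 lymphoid markers,
    FAP fibroblasts and CD66b neutrophils commonly profiled in gastric
    tumour microenvironment panels. The registry is user-extensible; the
    full modelled feature space is produced by configuration, not
    hard-coded here.
    """
    panel = panel or DEFAULT_PANEL
    path = Path(path) if path is not None else _DATA_DIR / "default_phenotypes.yaml"
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    defs = []
    for e in entries:
        defs.append(
            make_phenotype(
                e.get("positive", []),
                e.get("negative", []),
                panel=panel,
                name=e.get("name"),
            )
        )
    return defs


def save_registry(defs: Sequence[PhenotypeDefinition], path: str | Path) -> None:
    entries = [
        {
            "name": d.name,
            "positive": sorted(d.requires_positive),
            "negative": sorted(d.requires_negative),
            "panel": d.panel_id,
        }
        for d in defs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False, allow_unicode=True)
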