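"""Planning-unit × feature incidence and representation targets.

A *planning unit* is one valid grid cell; a *feature* is either a
(species, change-class, scenario) combination or a species' full-model
suitable area. The solver selects units so that each feature is represented
by at least its target number of incident units — the stratification that
lets a monitoring network separate gain, maintain and loss areas per
species.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ChangeClassMap
from .grids import BinaryMap

__all__ = [
    "Feature",
    "FeatureIncidence",
    "TargetTable",
    "build_incidence",
    "build_targets",
    "coverage_report",
    "write_marxan_inputs",
    "STATUS_BASE_TARGETS",
    "LEVEL_MULTIPLIER",
]

CLASS_KINDS = ("G", "M", "L")
_CLASS_LABEL = {"G": "gain", "M": "maintain", "L": "loss"}

#: Base (level-1) per-feature occurrence target by conservation status:
#: least-concern species get 3 stations per stratum, data-deficient 5.
STATUS_BASE_TARGETS = {"LC": 3, "DD": 5}
#: Levels double then double again as volunteer commitment grows.
LEVEL_MULTIPLIER = {"MN1": 1, "MN2": 2, "MN3": 4}


@dataclass(frozen=True)
class Feature:
    """One representable attribute: change stratum or full-model area."""

    species_id: str
    kind: str  # "G", "M", "L", "Full", or evaluation kinds "CurClim"/"CurFull"
    scenario_id: str = "none"

    def __post_init__(self) -> None:
        if self.kind == "Full" and self.scenario_id != "none":
            raise ValueError("Full features carry no scenario")

    @property
    def name(self) -> str:
        if self.scenario_id == "none":
            return f"{self.species_id}:{self.kind}"
        return f"{self.species_id}:{self.kind}:{self.scenario_id}"


@dataclass
class FeatureIncidence:
    """Boolean units × features matrix with stable orderings.

    ``units`` holds flat cell indices of every valid cell (including cells
    incident to no feature — they remain selectable, just useless).
    """

    units: np.ndarray  # (n_units,) flat cell indices
    features: list[Feature]
    incidence: np.ndarray  # (n_units, n_features) bool

    def __post_init__(self) -> None:
        if len({f.name for f in self.features}) != len(self.features):
            raise ValueError("duplicate features")
        if self.incidence.shape != (len(self.units), len(self.features)):
            raise ValueError("incidence shape mismatch")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature_index(self, f: Feature) -> int:
        return [g.name for g in self.features].index(f.name)

    def incident_counts(self) -> np.ndarray:
        """Number of incident units per feature (attainable maxima)."""
        return self.incidence.sum(axis=0).astype(int)

    def representation(self, selected_unit_pos) -> np.ndarray:
        """Per-feature count of selected units, by unit *position* index."""
        sel = np.asarray(sorted(selected_unit_pos), dtype=int)
        if sel.size == 0:
            return np.zeros(self.n_features, dtype=int)
        return self.incidence[sel].sum(axis=0).astype(int)


@dataclass
class TargetTable:
    """Minimum occurrence target per feature for one network level."""

    targets: dict[str, int]  # feature name -> target
    level: str = "MN1"

    def target_vector(self, features: list[Feature]) -> np.ndarray:
        return np.array([self.targets[f.name] for f in features], dtype=int)


def build_incidence(
    class_maps: dict[tuple[str, str], ChangeClassMap],
    full_bins: dict[str, BinaryMap],
    scenario_mode: str = "per_scenario",
) -> FeatureIncidence:
    """Assemble the incidence matrix from class maps and full-model maps.

    ``class_maps`` is keyed by (species_id, scenario_id). With
    ``scenario_mode='per_scenario'`` each scenario contributes its own G/M/L
    features (the stricter design: the network supports the shift hypothesis
    under either scenario); with ``'union'`` a cell is incident to a class
    feature if it carries that class under any scenario.
    """
    if scenario_mode not in ("per_scenario", "union"):
        raise ValueError(f"unknown scenario_mode {scenario_mode!r}")
    some = next(iter(class_maps.values()))
    shape = some.grid.shape
    mask = some.valid_mask
    for cm in class_maps.values():
        if cm.grid.shape != shape or not np.array_equal(cm.valid_mask, mask):
            raise ValueError("class maps on different grids/masks")
    for bm in full_bins.values():
        if bm.grid.shape != shape or not np.array_equal(bm.valid_mask, mask):
            raise ValueError("full-model maps on different grids/masks")

    units = np.flatnonzero(mask.ravel())
    unit_pos = {u: i for i, u in enumerate(units)}

    species = sorted({sp for sp, _ in class_maps})
    scenarios = sorted({sc for _, sc in class_maps})

    features: list[Feature] = []
    columns: list[np.ndarray] = []

    def col_from_cells(cells: np.ndarray) -> np.ndarray:
        col = np.zeros(len(units), dtype=bool)
        col[[unit_pos[c] for c in cells]] = True
        return col

    for sp in species:
        for kind in CLASS_KINDS:
            label = _CLASS_LABEL[kind]
            if scenario_mode == "per_scenario":
                for sc in scenarios:
                    cm = class_maps[(sp, sc)]
                    features.append(Feature(sp, kind, sc))
                    columns.append(col_from_cells(cm.cells_of(label)))
            else:
                cells = np.unique(
                    np.concatenate(
                        [class_maps[(sp, sc)].cells_of(label) for sc in scenarios]
                    )
                ) if scenarios else np.array([], dtype=int)
                features.append(Feature(sp, kind, "union"))
                columns.append(col_from_cells(cells))
        features.append(Feature(sp, "Full", "none"))
        columns.append(col_from_cells(full_bins[sp].present_cells()))

    inc = np.column_stack(columns) if columns else np.zeros((len(units), 0), bool)
    return FeatureIncidence(units=units, features=features, incidence=inc)


def build_targets(
    statuses: dict[str, str],
    level: str,
    features: list[Feature] | None = None,
    scenarios: tuple[str, ...] = ("A2a", "B2a"),
    scenario_mode: str = "per_scenario",
) -> TargetTable:
    """Targets per feature for one network level.

    Every stratum of a species (G, M, L per scenario, and Full) carries the
    same status-dependent target: LC 3/6/12 and DD 5/10/20 stations for
    levels MN1/MN2/MN3.
    """
    if level not in LEVEL_MULTIPLIER:
        raise ValueError(f"unknown network level {level!r}")
    mult = LEVEL_MULTIPLIER[level]
    targets: dict[str, int] = {}
    if features is None:
        features = []
        scen_list = list(scenarios) if scenario_mode == "per_scenario" else ["union"]
        for sp in statuses:
            for kind in CLASS_KINDS:
                for sc in scen_list:
                    features.append(Feature(sp, kind, sc))
            features.append(Feature(sp, "Full", "none"))
    for f in features:
        status = statuses.get(f.species_id)
        if status is None:
            raise KeyError(f"no status for species {f.species_id!r}")
        if status not in STATUS_BASE_TARGETS:
            raise ValueError(f"unknown status code {status!r}")
        targets[f.name] = STATUS_BASE_TARGETS[status] * mult
    return TargetTable(targets=targets, level=level)


def coverage_report(inc: FeatureIncidence, tt: TargetTable) -> pd.DataFrame:
    """Flag features whose incident-unit count cannot reach the target.

    The solver treats unattainable features as best-effort: the effective
    target is capped at the attainable maximum (otherwise a scarce stratum
    such as gain would make every solution look equally infeasible).
    """
    counts = inc.incident_counts()
    tvec = tt.target_vector(inc.features)
    return pd.DataFrame(
        {
            "feature": [f.name for f in inc.features],
            "species": [f.species_id for f in inc.features],
            "kind": [f.kind for f in inc.features],
            "scenario": [f.scenario_id for f in inc.features],
            "target": tvec,
            "max_attainable": counts,
            "attainable": counts >= tvec,
        }
    )


def write_marxan_inputs(
    inc: FeatureIncidence,
    tt: TargetTable,
    out_dir: str | Path,
    spf: float = 100.0,
    locked_in: set[int] | None = None,
) -> None:
    """Write pu.dat / spec.dat / puvspr.dat in the Marxan dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locked = locked_in or set()
    pu = pd.DataFrame(
        {
            "id": inc.units,
            "cost": 1,
            "status": [2 if int(u) in locked else 0 for u in inc.units],
        }
    )
    pu.to_csv(out_dir / "pu.dat", index=False)
    spec_df = pd.DataFrame(
        {
            "id": np.arange(1, inc.n_features + 1),
            "target": tt.target_vector(inc.features),
            "spf": spf,
            "name": [f.name for f in inc.features],
        }
    )
    spec_df.to_csv(out_dir / "spec.dat", index=False)
    rows_u, rows_f = np.nonzero(inc.incidence)
    puvspr = pd.DataFrame(
        {
            "species": rows_f + 1,
            "pu": inc.units[rows_u],
            "amount": 1,
        }
    ).sort_values(["pu", "species"])
    puvspr.to_csv(out_dir / "puvspr.dat", index=False)
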