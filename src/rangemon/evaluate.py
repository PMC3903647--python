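"""Comparison against distribution-only ("non-optimized") network designs.

The conventional way to place a monitoring network considers only where the
species currently occur. To quantify what that design misses, a comparison
network is solved with targets set only for each species' current climatic
and full-model suitable areas — target values copied from how many stations
of the matched optimized network fall in those areas — and its total size is
capped (via the cost threshold) at the optimized network's size. Every run
of the comparison ensemble is then scored against the original stratified
gain/maintain/loss/full targets; the fraction of targets unmet, overall and
by class, measures how poorly an occurrence-only design samples the strata
needed to detect range shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import MonitoringNetwork
from .features import Feature, FeatureIncidence, TargetTable
from .grids import BinaryMap
from .solver import EnsembleResult, SolverConfig, run_ensemble

__all__ = [
    "EvaluationReport",
    "distribution_only_targets",
    "build_current_incidence",
    "build_comparison_network",
    "evaluate_against_stratified_targets",
]


@dataclass
class EvaluationReport:
    """Unmet-target fractions over an ensemble of runs."""

    per_run_unmet_fraction: list[float]
    by_class: dict[str, dict[str, float]]  # kind -> {median,min,max}
    by_species_class: dict[str, dict[str, dict[str, float]]]
    n_runs: int
    tidy: pd.DataFrame  # run,feature,species,kind,scenario,target,representation,met

    def summary(self) -> dict:
        arr = np.asarray(self.per_run_unmet_fraction)
        return {
            "n_runs": self.n_runs,
            "overall": {
                "median": float(np.median(arr)),
                "min": float(arr.min()),
                "max": float(arr.max()),
            },
            "by_class": self.by_class,
            "by_species_class": self.by_species_class,
        }


def build_current_incidence(
    climatic_bins: dict[str, BinaryMap], full_bins: dict[str, BinaryMap]
) -> FeatureIncidence:
    """Incidence with only current-distribution features (2 per species)."""
    some = next(iter(climatic_bins.values()))
    mask = some.valid_mask
    units = np.flatnonzero(mask.ravel())
    unit_pos = {u: i for i, u in enumerate(units)}
    features: list[Feature] = []
    cols: list[np.ndarray] = []
    for sp in sorted(climatic_bins):
        for kind, bm in (("CurClim", climatic_bins[sp]), ("CurFull", full_bins[sp])):
            if not np.array_equal(bm.valid_mask, mask):
                raise ValueError("current-distribution maps on different masks")
            col = np.zeros(len(units), dtype=bool)
            col[[unit_pos[c] for c in bm.present_cells()]] = True
            features.append(Feature(sp, kind, "none"))
            cols.append(col)
    inc = np.column_stack(cols)
    return FeatureIncidence(units=units, features=features, incidence=inc)


def distribution_only_targets(
    net: MonitoringNetwork,
    inc: FeatureIncidence,
    climatic_bins: dict[str, BinaryMap],
    full_bins: dict[str, BinaryMap],
) -> TargetTable:
    """Targets for current-distribution features from the optimized network.

    Each species' target equals the number of the optimized network's
    stations lying inside its current suitable area, so the comparison
    network reproduces the occurrence coverage of the optimized one — just
    without any stratification by predicted change.
    """
    cells = net.station_cells(inc)
    targets: dict[str, int] = {}
    for sp in sorted(climatic_bins):
        flat_c = climatic_bins[sp].presence.ravel()
        flat_f = full_bins[sp].presence.ravel()
        targets[Feature(sp, "CurClim", "none").name] = int(flat_c[cells].sum())
        targets[Feature(sp, "CurFull", "none").name] = int(flat_f[cells].sum())
    return TargetTable(targets=targets, level=net.level)


def build_comparison_network(
    dist_targets: TargetTable,
    inc_current: FeatureIncidence,
    size_cap: int,
    cfg: SolverConfig,
) -> EnsembleResult:
    """Solve the occurrence-only problem with total size capped at the
    optimized network's station count; all runs are retained for scoring."""
    cap_cfg = replace(cfg, cost_threshold=float(size_cap) * cfg.unit_cost, locked_in=frozenset())
    return run_ensemble(inc_current, dist_targets, cap_cfg)


def _match_positions(inc_from: FeatureIncidence, inc_to: FeatureIncidence) -> np.ndarray:
    """Map unit positions of inc_from to positions in inc_to via cell index."""
    pos = {int(u): i for i, u in enumerate(inc_to.units)}
    return np.array([pos[int(u)] for u in inc_from.units], dtype=int)


def evaluate_against_stratified_targets(
    ens: EnsembleResult,
    inc: FeatureIncidence,
    tt: TargetTable,
    ens_incidence: FeatureIncidence | None = None,
) -> EvaluationReport:
    """Score every run of an ensemble against the stratified target table.

    A feature counts as unmet on any positive shortfall; targets are NOT
    capped to attainable maxima here — the comparison is against the
    original targets, scarce strata included. If the ensemble was solved on
    a different incidence (the current-distribution one), pass it as
    ``ens_incidence`` so unit positions can be matched by grid cell.
    """
    tvec = tt.target_vector(inc.features)
    posmap = (
        _match_positions(ens_incidence, inc) if ens_incidence is not None else None
    )
    rows = []
    per_run = []
    for sol in ens.per_run:
        sel = sorted(sol.selected)
        sel_in_inc = [int(posmap[u]) for u in sel] if posmap is not None else sel
        rep = inc.representation(sel_in_inc)
        unmet = rep < tvec
        per_run.append(float(unmet.sum() / len(tvec)))
        for j, f in enumerate(inc.features):
            rows.append(
                {
                    "run": sol.run_index,
                    "feature": f.name,
                    "species": f.species_id,
                    "kind": f.kind,
                    "scenario": f.scenario_id,
                    "target": int(tvec[j]),
                    "representation": int(rep[j]),
                    "met": bool(rep[j] >= tvec[j]),
                }
            )
    tidy = pd.DataFrame(rows)

    def _mmm(series_by_run: pd.Series) -> dict[str, float]:
        return {
            "median": float(series_by_run.median()),
            "min": float(series_by_run.min()),
            "max": float(series_by_run.max()),
        }

    by_class: dict[str, dict[str, float]] = {}
    for kind, g in tidy.groupby("kind"):
        frac = g.groupby("run")["met"].apply(lambda s: 1.0 - s.mean())
        by_class[str(kind)] = _mmm(frac)
    by_sp: dict[str, dict[str, dict[str, float]]] = {}
    for (sp, kind), g in tidy.groupby(["species", "kind"]):
        frac = g.groupby("run")["met"].apply(lambda s: 1.0 - s.mean())
        by_sp.setdefault(str(sp), {})[str(kind)] = _mmm(frac)
    return EvaluationReport(
        per_run_unmet_fraction=per_run,
        by_class=by_class,
        by_species_class=by_sp,
        n_runs=ens.n_runs,
        tidy=tidy,
    )
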