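"""Nested monitoring-network construction.

Three networks of growing size (MN1, MN2, MN3) share one solved incidence
problem with level-scaled targets. Nesting is enforced by lock-in: the best
MN1 solution's stations are forced into every MN2 run, and MN2's into MN3,
so the network can expand with volunteer commitment without abandoning
stations that already have a monitoring history.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import FeatureIncidence, TargetTable, build_targets
from .grids import BinaryMap
from .solver import EnsembleResult, SolverConfig, run_ensemble

__all__ = ["MonitoringNetwork", "design_nested", "quarter_check", "stations_frame"]

LEVELS = ("MN1", "MN2", "MN3")


@dataclass
class MonitoringNetwork:
    level: str
    stations: frozenset[int]  # unit positions into the incidence
    ensemble: EnsembleResult
    targets: TargetTable

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    def station_cells(self, inc: FeatureIncidence) -> np.ndarray:
        """Flat grid cell indices of the stations, sorted."""
        return np.sort(inc.units[list(self.stations)])


def design_nested(
    inc: FeatureIncidence,
    statuses: dict[str, str],
    cfg: SolverConfig,
) -> tuple[MonitoringNetwork, MonitoringNetwork, MonitoringNetwork]:
    """Solve MN1, then MN2 with MN1 locked in, then MN3 with MN2 locked in."""
    nets: list[MonitoringNetwork] = []
    locked: frozenset[int] = cfg.locked_in
    for i, level in enumerate(LEVELS):
        tt = build_targets(statuses, level, features=inc.features)
        level_cfg = replace(cfg, locked_in=locked, seed=cfg.seed + i)
        ens = run_ensemble(inc, tt, level_cfg)
        net = MonitoringNetwork(
            level=level, stations=ens.best.selected, ensemble=ens, targets=tt
        )
        nets.append(net)
        locked = net.stations
    return nets[0], nets[1], nets[2]


def quarter_check(
    net: MonitoringNetwork,
    inc: FeatureIncidence,
    full_bins: dict[str, BinaryMap],
    min_fraction: float = 0.25,
) -> dict:
    """Fraction of stations inside full-model-suitable areas.

    The habitat-aware ("full") model is the only surface carrying land-cover
    information; requiring a quarter of stations inside its suitable area
    keeps the network anchored to currently habitable ground. Reported per
    species and for the union across species; the union carries the pass
    flag.
    """
    cells = net.station_cells(inc)
    n = len(cells)
    per_species: dict[str, float] = {}
    union_mask = None
    for sp, bm in full_bins.items():
        flat = bm.presence.ravel()
        per_species[sp] = float(flat[cells].sum() / n) if n else 0.0
        union_mask = flat if union_mask is None else (union_mask | flat)
    union_frac = float(union_mask[cells].sum() / n) if n and union_mask is not None else 0.0
    return {
        "level": net.level,
        "n_stations": n,
        "per_species_fraction": per_species,
        "union_fraction": union_frac,
        "passes": union_frac >= min_fraction,
    }


def stations_frame(
    nets: tuple[MonitoringNetwork, ...],
    inc: FeatureIncidence,
    n_cols: int | None = None,
) -> pd.DataFrame:
    """Tidy station table: one row per station with the level it first entered.

    ``n_cols`` (grid width) adds 0-based row/col columns, row 0 at the top.
    """
    first_level: dict[int, str] = {}
    for net in nets:
        for u in sorted(net.stations):
            first_level.setdefault(int(u), net.level)
    rows = []
    for u in sorted(first_level):
        cell = int(inc.units[u])
        rec = {"unit_pos": u, "cell": cell, "level_first_selected": first_level[u]}
        if n_cols is not None:
            rec["row"], rec["col"] = divmod(cell, n_cols)
        rows.append(rec)
    df = pd.DataFrame(rows)
    for j, f in enumerate(inc.features):
        df[f.name] = inc.incidence[df["unit_pos"].to_numpy(), j]
    return df
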