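"""End-to-end pipeline: simulate → threshold → classify → assemble → design
→ evaluate → compare, with YAML configuration and a provenance manifest.

Each stage is an importable function so the command-line interface and the
test suite can run any slice of the pipeline; ``run_pipeline`` chains them
all and writes every artifact under one output directory.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ChangeClassMap, classify_change, threshold_from_presences, binarize, richness_delta, write_class_map
from .design import MonitoringNetwork, design_nested, quarter_check, stations_frame
from .evaluate import (
    build_comparison_network,
    build_current_incidence,
    distribution_only_targets,
    evaluate_against_stratified_targets,
)
from .features import FeatureIncidence, build_incidence, build_targets, coverage_report, write_marxan_inputs
from .grids import BinaryMap, GridSpec, read_ascii_grid
from .landscape import (
    DEFAULT_GRID,
    SpeciesScenarioSet,
    default_species_configs,
    generate_landscape,
    write_landscape,
)
from .niche import niche_breadth, percent_agreement, schoener_D
from .solver import SolverConfig

__all__ = ["PipelineConfig", "PreparedProblem", "prepare_problem", "run_pipeline", "load_landscape"]


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run.

    Solver defaults are the production configuration (100 runs, penalty
    factor 100, one million iterations, ten thousand temperature decreases,
    adaptive temperature, no compactness term); tests and the shipped demo
    scale iterations and runs down.
    """

    seed: int = 0
    out_dir: str = "rangemon_out"
    scenario_mode: str = "per_scenario"
    # synthetic landscape block (used when no input_dir is given)
    n_rows: int = DEFAULT_GRID.n_rows
    n_cols: int = DEFAULT_GRID.n_cols
    nodata_fraction: float = DEFAULT_GRID.nodata_fraction
    input_dir: str | None = None  # load a written landscape instead of simulating
    # solver block
    n_runs: int = 100
    n_iterations: int = 1_000_000
    n_temp_decreases: int = 10_000
    feature_penalty_factor: float = 100.0
    comparison_runs: int | None = None  # defaults to n_runs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def grid_spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, nodata_fraction=self.nodata_fraction)

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            n_runs=self.n_runs,
            n_iterations=self.n_iterations,
            n_temp_decreases=min(self.n_temp_decreases, self.n_iterations),
            feature_penalty_factor=self.feature_penalty_factor,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PreparedProblem:
    """Thresholded, classified and assembled inputs for the solver."""

    landscape: list[SpeciesScenarioSet]
    statuses: dict[str, str]
    climatic_bins: dict[str, BinaryMap]  # present, climatic model
    future_bins: dict[tuple[str, str], BinaryMap]
    full_bins: dict[str, BinaryMap]
    class_maps: dict[tuple[str, str], ChangeClassMap]
    incidence: FeatureIncidence
    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def scenarios(self) -> list[str]:
        return sorted({sc for _, sc in self.class_maps})


def prepare_problem(
    landscape: list[SpeciesScenarioSet], scenario_mode: str = "per_scenario"
) -> PreparedProblem:
    """Threshold every surface, classify change, and build the incidence.

    Thresholds are computed once per species per model (climatic and full
    separately) from the training presences, then applied to present and
    future projections of that model alike.
    """
    statuses = {s.species_id: s.status for s in landscape}
    climatic_bins: dict[str, BinaryMap] = {}
    future_bins: dict[tuple[str, str], BinaryMap] = {}
    full_bins: dict[str, BinaryMap] = {}
    class_maps: dict[tuple[str, str], ChangeClassMap] = {}
    thresholds: dict[tuple[str, str], float] = {}
    for s in landscape:
        th_clim = threshold_from_presences(s.present_climatic, s.presences)
        th_full = threshold_from_presences(s.present_full, s.presences)
        thresholds[(s.species_id, "climatic")] = th_clim.tau
        thresholds[(s.species_id, "full")] = th_full.tau
        present_bin = binarize(s.present_climatic, th_clim)
        climatic_bins[s.species_id] = present_bin
        full_bins[s.species_id] = binarize(s.present_full, th_full)
        for scen, fut in s.future_climatic.items():
            fut_bin = binarize(fut, th_clim)
            future_bins[(s.species_id, scen)] = fut_bin
            class_maps[(s.species_id, scen)] = classify_change(present_bin, fut_bin)
    inc = build_incidence(class_maps, full_bins, scenario_mode=scenario_mode)
    return PreparedProblem(
        landscape=landscape,
        statuses=statuses,
        climatic_bins=climatic_bins,
        future_bins=future_bins,
        full_bins=full_bins,
        class_maps=class_maps,
        incidence=inc,
        thresholds=thresholds,
    )


def load_landscape(input_dir: str | Path) -> list[SpeciesScenarioSet]:
    """Load a landscape previously written by ``write_landscape``."""
    input_dir = Path(input_dir)
    manifest = yaml.safe_load((input_dir / "manifest.yaml").read_text())
    pres = pd.read_csv(input_dir / "presences.csv")
    out: list[SpeciesScenarioSet] = []
    for entry in manifest["species"]:
        sp = entry["species_id"]
        grids = {name: read_ascii_grid(input_dir / name) for name in entry["rasters"]}
        for name, g in grids.items():
            g.provenance = entry["rasters"][name]
        present = grids[f"{sp}_climatic_present.asc"]
        full = grids[f"{sp}_full_present.asc"]
        futures = {
            prov.get("scenario"): g
            for name, g in grids.items()
            if (prov := g.provenance).get("period") == "future"
        }
        rows = pres[pres["species_id"] == sp]
        cells = (rows["row"].to_numpy() * present.grid.n_cols + rows["col"].to_numpy())
        out.append(
            SpeciesScenarioSet(
                species_id=sp,
                status=entry["status"],
                present_climatic=present,
                future_climatic=futures,
                present_full=full,
                presences=np.sort(cells),
            )
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts. Returns a result bundle.

    Identical config and seed give byte-identical station CSVs: every source
    of randomness derives from ``cfg.seed``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- landscape ---------------------------------------------------------
    if cfg.input_dir:
        landscape = load_landscape(cfg.input_dir)
    else:
        landscape = generate_landscape(cfg.grid_spec(), default_species_configs(), seed=cfg.seed)
        write_landscape(landscape, out / "landscape")
    prob = prepare_problem(landscape, scenario_mode=cfg.scenario_mode)
    n_cols = landscape[0].present_climatic.grid.n_cols

    for (sp, scen), cm in prob.class_maps.items():
        write_class_map(cm, out / f"classes_{sp}_{scen}.asc")
    for scen in prob.scenarios:
        maps = [cm for (sp, sc), cm in prob.class_maps.items() if sc == scen]
        delta = richness_delta(maps)
        np.savetxt(out / f"richness_delta_{scen}.csv", delta, fmt="%d", delimiter=",")

    # --- coverage + Marxan dialect export ----------------------------------
    tt1 = build_targets(prob.statuses, "MN1", features=prob.incidence.features)
    coverage_report(prob.incidence, tt1).to_csv(out / "coverage_MN1.csv", index=False)
    write_marxan_inputs(prob.incidence, tt1, out / "marxan_MN1")

    # --- nested design ------------------------------------------------------
    solver_cfg = cfg.solver_config()
    mn1, mn2, mn3 = design_nested(prob.incidence, prob.statuses, solver_cfg)
    nets = (mn1, mn2, mn3)
    sf = stations_frame(nets, prob.incidence, n_cols=n_cols)
    sf.to_csv(out / "stations.csv", index=False)
    quarter = {n.level: quarter_check(n, prob.incidence, prob.full_bins) for n in nets}

    freq = pd.DataFrame(
        {
            "cell": prob.incidence.units,
            **{
                f"count_{n.level}": n.ensemble.selection_frequency for n in nets
            },
        }
    )
    freq.to_csv(out / "selection_frequency.csv", index=False)

    # --- niche comparison ---------------------------------------------------
    niche_rows = []
    for s in landscape:
        stats = percent_agreement(prob.full_bins[s.species_id], prob.climatic_bins[s.species_id])
        niche_rows.append(
            {
                "species": s.species_id,
                "percent_agreement": stats.percent_agreement,
                "pct_only_full": stats.pct_only_a,
                "pct_only_climatic": stats.pct_only_b,
                "schoener_D": schoener_D(s.present_climatic, s.present_full),
                "breadth_climatic": niche_breadth(s.present_climatic),
                "breadth_full": niche_breadth(s.present_full),
            }
        )
    niche_df = pd.DataFrame(niche_rows)
    niche_df.to_csv(out / "niche_comparison.csv", index=False)

    # --- distribution-only comparison --------------------------------------
    inc_cur = build_current_incidence(prob.climatic_bins, prob.full_bins)
    comparison = {}
    comp_runs = cfg.comparison_runs or cfg.n_runs
    for net in nets:
        dist_tt = distribution_only_targets(net, prob.incidence, prob.climatic_bins, prob.full_bins)
        comp_cfg = SolverConfig(
            n_runs=comp_runs,
            n_iterations=solver_cfg.n_iterations,
            n_temp_decreases=solver_cfg.n_temp_decreases,
            feature_penalty_factor=solver_cfg.feature_penalty_factor,
            seed=cfg.seed + 1000 + {"MN1": 0, "MN2": 1, "MN3": 2}[net.level],
        )
        ens = build_comparison_network(dist_tt, inc_cur, net.n_stations, comp_cfg)
        tt = build_targets(prob.statuses, net.level, features=prob.incidence.features)
        report = evaluate_against_stratified_targets(
            ens, prob.incidence, tt, ens_incidence=inc_cur
        )
        report.tidy.to_csv(out / f"evaluation_{net.level}.csv", index=False)
        comparison[net.level] = report

    # --- summary + manifest -------------------------------------------------
    summary = {
        "stations": {n.level: n.n_stations for n in nets},
        "objectives": {n.level: n.ensemble.best.objective for n in nets},
        "quarter_check": quarter,
        "comparison": {lvl: rep.summary() for lvl, rep in comparison.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "rangemon_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "landscape": landscape,
        "problem": prob,
        "networks": nets,
        "quarter_check": quarter,
        "niche": niche_df,
        "comparison": comparison,
        "summary": summary,
    }
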