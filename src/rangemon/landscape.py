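"""Seeded synthetic multi-species suitability landscapes.

Generates, for each simulated species, a continuous climatic suitability
surface for the present, projections for two future scenarios, a
habitat-constrained "full model" surface, and training presence points —
the complete input set the monitoring-network pipeline expects from a
fitted distribution model, without requiring any real rasters.

The emulated geometry follows the study system this package is built for:
under future scenarios suitable space contracts strongly (loss of climatic
suitability for at least one species over much of the region) while newly
suitable space is scarce and spatially clustered in a fringe on one side of
the region. Suitability is a unimodal (Gaussian) niche response to a smooth
synthetic environmental field; future conditions translate the field
spatially and narrow the niche, so gain appears as a coherent band at the
leading edge and loss dominates the trailing bulk of the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, SuitabilityGrid, write_ascii_grid

__all__ = [
    "SpeciesConfig",
    "SpeciesScenarioSet",
    "default_species_configs",
    "generate_landscape",
    "sample_presences",
    "write_landscape",
    "DEFAULT_GRID",
    "SCENARIOS",
]

SCENARIOS = ("A2a", "B2a")

#: Demo grid: a reduced stand-in for a regional planning raster.
DEFAULT_GRID = GridSpec(n_rows=60, n_cols=60, cell_size=1.0, nodata_fraction=0.05)


@dataclass(frozen=True)
class SpeciesConfig:
    """Niche and climate-response parameters for one simulated species.

    ``niche_center``/``niche_width`` place a Gaussian response on the
    environmental field (field values are roughly in [0, 1]).
    ``shift`` maps scenario id to a (d_row, d_col) spatial translation of the
    environmental field, in cells; ``contraction`` maps scenario id to an
    exponent >= 1 applied to the future niche response. Raising a unimodal
    response to a power keeps the optimum fully suitable while narrowing the
    suitable band, so future range contraction does not simply erase the
    species.
    """

    species_id: str
    status: str  # "LC" or "DD"
    niche_center: float
    niche_width: float
    shift: dict = field(default_factory=dict)
    contraction: dict = field(default_factory=dict)
    n_presences: int = 30

    def __post_init__(self) -> None:
        if self.niche_width <= 0:
            raise ValueError("niche_width must be positive")
        if self.status not in ("LC", "DD"):
            raise ValueError(f"unknown conservation status {self.status!r}")


@dataclass
class SpeciesScenarioSet:
    """All surfaces and presences for one species on a shared grid."""

    species_id: str
    status: str
    present_climatic: SuitabilityGrid
    future_climatic: dict[str, SuitabilityGrid]
    present_full: SuitabilityGrid
    presences: np.ndarray  # flat cell indices


def default_species_configs() -> list[SpeciesConfig]:
    """Seven species, 3 LC + 4 DD, mirroring the demo community structure.

    Niche optima are staggered along the environmental gradient; every
    scenario shifts the field toward higher column index (so suitable bands
    migrate toward the western fringe, which gains) and contracts the niche,
    the A2a scenario more severely than B2a. The combination keeps newly
    suitable space scarce and clustered while loss of suitability for at
    least one species covers much of the region.
    """
    shifts = {"A2a": (0.0, 3.0), "B2a": (0.0, 4.0)}
    base = {"A2a": 3.5, "B2a": 2.5}
    # per-species climate sensitivity: species losing most of their range make
    # the maintain stratum scarce relative to their current distribution
    rows = [
        ("Mdau", "LC", 0.38, 2.2),
        ("Pkuh", "LC", 0.46, 1.0),
        ("Hsav", "DD", 0.42, 2.0),
        ("Nlei", "DD", 0.52, 1.8),
        ("Eser", "LC", 0.56, 1.0),
        ("Bbar", "DD", 0.35, 1.2),
        ("Tten", "DD", 0.60, 1.4),
    ]
    return [
        SpeciesConfig(
            species_id=sp,
            status=st,
            niche_center=c,
            niche_width=0.14,
            shift=dict(shifts),
            contraction={scen: g * scale for scen, g in base.items()},
        )
        for sp, st, c, scale in rows
    ]


def _environment_field(
    spec: GridSpec, rng: np.random.Generator, smooth_sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth environmental field on an enlarged canvas.

    Returns (field, canvas) where ``field`` is the spec-sized window and
    ``canvas`` the padded array from which shifted windows are cut, so a
    translated field stays spatially coherent at the grid edges.
    """
    pad = max(spec.n_rows, spec.n_cols)  # enough margin for any sane shift
    big = np.zeros((spec.n_rows + 2 * pad, spec.n_cols + 2 * pad))
    # planar gradient along columns plus low-frequency noise
    cols = np.arange(big.shape[1], dtype=float)
    gradient = (cols - pad) / max(spec.n_cols - 1, 1)
    big += gradient[None, :]
    noise = rng.standard_normal(big.shape)
    noise = gaussian_filter(noise, sigma=smooth_sigma, mode="reflect")
    noise /= max(noise.std(), 1e-12)
    big += 0.25 * noise
    window = big[pad : pad + spec.n_rows, pad : pad + spec.n_cols]
    return window, big


def _cut(canvas: np.ndarray, spec: GridSpec, d_row: float, d_col: float) -> np.ndarray:
    pad = max(spec.n_rows, spec.n_cols)
    r0 = pad + int(round(d_row))
    c0 = pad + int(round(d_col))
    return canvas[r0 : r0 + spec.n_rows, c0 : c0 + spec.n_cols]


def _niche_response(env: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((env - center) / width) ** 2)


def generate_landscape(
    spec: GridSpec = DEFAULT_GRID,
    species_configs: list[SpeciesConfig] | None = None,
    seed: int = 0,
    smooth_sigma: float = 6.0,
) -> list[SpeciesScenarioSet]:
    """Generate a deterministic multi-species landscape.

    One environmental canvas and one nodata mask are shared by every grid of
    the landscape; per-species surfaces differ only through their niche
    parameters and scenario shifts, so identical arguments give bit-identical
    output.
    """
    if species_configs is None:
        species_configs = default_species_configs()
    if not species_configs:
        raise ValueError("at least one species config is required")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A5D]))
    env_now, canvas = _environment_field(spec, rng, smooth_sigma)

    # shared nodata mask
    valid = np.ones(spec.shape, dtype=bool)
    n_nodata = int(round(spec.nodata_fraction * spec.n_cells))
    if n_nodata:
        drop = rng.choice(spec.n_cells, size=n_nodata, replace=False)
        valid.ravel()[drop] = False

    # shared habitat indicator: smoothed binary blob field in [0, 1]
    hab_noise = gaussian_filter(rng.standard_normal(spec.shape), sigma=5.0, mode="reflect")
    hab_bin = (hab_noise > np.quantile(hab_noise, 0.35)).astype(float)
    habitat = gaussian_filter(hab_bin, sigma=2.0, mode="reflect")
    habitat = np.clip(habitat, 0.0, 1.0)

    out: list[SpeciesScenarioSet] = []
    for cfg in species_configs:
        pres = _niche_response(env_now, cfg.niche_center, cfg.niche_width)
        present = SuitabilityGrid(
            values=np.where(valid, pres, 0.0),
            valid_mask=valid,
            grid=spec,
            provenance={"species": cfg.species_id, "model": "climatic", "period": "present"},
        )
        futures: dict[str, SuitabilityGrid] = {}
        for scen, (dr, dc) in cfg.shift.items():
            env_fut = _cut(canvas, spec, dr, dc)
            gamma = cfg.contraction.get(scen, 1.0)
            fut = _niche_response(env_fut, cfg.niche_center, cfg.niche_width) ** gamma
            futures[scen] = SuitabilityGrid(
                values=np.where(valid, fut, 0.0),
                valid_mask=valid,
                grid=spec,
                provenance={
                    "species": cfg.species_id,
                    "model": "climatic",
                    "period": "future",
                    "scenario": scen,
                },
            )
        full_vals = pres * habitat
        full = SuitabilityGrid(
            values=np.where(valid, full_vals, 0.0),
            valid_mask=valid,
            grid=spec,
            provenance={"species": cfg.species_id, "model": "full", "period": "present"},
        )
        presences = sample_presences(
            present,
            n=cfg.n_presences,
            seed=rng.integers(0, 2**31 - 1),
        )
        out.append(
            SpeciesScenarioSet(
                species_id=cfg.species_id,
                status=cfg.status,
                present_climatic=present,
                future_climatic=futures,
                present_full=full,
                presences=presences,
            )
        )
    return out


def sample_presences(grid: SuitabilityGrid, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` distinct cells with probability proportional to suitability.

    Emulates occurrence records: observations concentrate where the species
    is most likely present but any positive-suitability cell can be drawn.
    """
    if n < 1:
        raise ValueError("n must be positive")
    flat = np.where(grid.valid_mask.ravel(), grid.values.ravel(), 0.0)
    candidates = np.flatnonzero(flat > 0)
    if candidates.size < n:
        raise ValueError(
            f"requested {n} presences but only {candidates.size} cells have positive suitability"
        )
    rng = np.random.default_rng(seed)
    probs = flat[candidates] / flat[candidates].sum()
    chosen = rng.choice(candidates, size=n, replace=False, p=probs)
    return np.sort(chosen)


def write_landscape(landscape: list[SpeciesScenarioSet], out_dir: str | Path) -> None:
    """Write .asc rasters, a presence CSV and a YAML manifest for a landscape."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"species": []}
    pres_rows = ["species_id,row,col"]
    shape = landscape[0].present_climatic.grid.shape
    for sset in landscape:
        entry = {"species_id": sset.species_id, "status": sset.status, "rasters": {}}
        named = {
            f"{sset.species_id}_climatic_present.asc": sset.present_climatic,
            f"{sset.species_id}_full_present.asc": sset.present_full,
        }
        for scen, g in sset.future_climatic.items():
            named[f"{sset.species_id}_climatic_future_{scen}.asc"] = g
        for name, g in named.items():
            write_ascii_grid(g, out_dir / name)
            entry["rasters"][name] = g.provenance
        manifest["species"].append(entry)
        rows, cols = np.unravel_index(sset.presences, shape)
        for r, c in zip(rows, cols):
            pres_rows.append(f"{sset.species_id},{r},{c}")
    (out_dir / "presences.csv").write_text("\n".join(pres_rows) + "\n")
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
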