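"""Thresholding of suitability surfaces and change-class maps.

A continuous model output is reduced to presence/absence with the
10th-percentile-of-training-presence rule: the suitability cutoff is the
10th percentile of the model values at the training occurrence cells, so the
lowest tenth of the training records — assumed to carry positional or
identification error — fall below it. Cells at or above the cutoff are
deemed suitable.

Comparing the present binary map with a future projection yields a per-cell
change class: loss (suitable now, not in future), maintain (suitable in
both), gain (unsuitable now, suitable in future), or unsuitable (neither).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import BinaryMap, GridSpec, SuitabilityGrid, same_mask

__all__ = [
    "Threshold",
    "ChangeClassMap",
    "CLASS_CODES",
    "threshold_from_presences",
    "binarize",
    "classify_change",
    "richness_delta",
    "write_class_map",
]

#: Integer codes used when a class map is written as a raster.
CLASS_CODES = {"unsuitable": 0, "loss": 1, "maintain": 2, "gain": 3}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}
NODATA_CODE = -9999


@dataclass(frozen=True)
class Threshold:
    """A suitability cutoff derived from training-presence values."""

    tau: float
    n_presences: int
    percentile: float = 10.0


@dataclass
class ChangeClassMap:
    """Per-cell change class for one species under one scenario.

    ``classes`` is an int8 array of CLASS_CODES values; nodata cells hold an
    arbitrary code and are excluded through ``valid_mask``.
    """

    classes: np.ndarray
    valid_mask: np.ndarray
    grid: GridSpec
    species_id: str
    scenario_id: str

    def cells_of(self, label: str) -> np.ndarray:
        """Flat indices of valid cells carrying ``label``."""
        code = CLASS_CODES[label]
        hit = (self.classes == code) & self.valid_mask
        return np.flatnonzero(hit.ravel())

    def fraction_of(self, label: str) -> float:
        n_valid = int(self.valid_mask.sum())
        return len(self.cells_of(label)) / n_valid if n_valid else 0.0


def threshold_from_presences(grid: SuitabilityGrid, presences) -> Threshold:
    """10th percentile of the suitability values at the training presences.

    The percentile is taken with linear interpolation between order
    statistics (numpy's default quantile definition): for sorted values
    v_1..v_n and position p = 0.10 (n-1), tau interpolates between
    v_{floor(p)+1} and v_{floor(p)+2}.
    """
    presences = np.asarray(presences, dtype=int)
    if presences.size < 2:
        raise ValueError("need at least 2 presence cells to take a percentile")
    vals = grid.at_cells(presences)  # raises on nodata cells
    tau = float(np.quantile(vals, 0.10, method="linear"))
    return Threshold(tau=tau, n_presences=int(presences.size))


def binarize(grid: SuitabilityGrid, th: Threshold) -> BinaryMap:
    """Suitable iff value >= tau; nodata preserved.

    The cutoff itself counts as suitable, matching the usual reading of the
    10-percentile training-presence threshold where the threshold cell is in
    the predicted range.
    """
    if not 0.0 <= th.tau <= 1.0:
        raise ValueError("tau outside [0, 1]")
    presence = (grid.values >= th.tau) & grid.valid_mask
    return BinaryMap(
        presence=presence,
        valid_mask=grid.valid_mask,
        grid=grid.grid,
        provenance=dict(grid.provenance, tau=th.tau),
    )


def classify_change(present: BinaryMap, future: BinaryMap) -> ChangeClassMap:
    """Cross-tabulate present and future presence into change classes.

    present 1 / future 0 -> loss; 1/1 -> maintain; 0/1 -> gain;
    0/0 -> unsuitable.
    """
    if not same_mask(present, future):
        raise ValueError("present and future maps have different valid masks")
    p, f = present.presence, future.presence
    classes = np.zeros(p.shape, dtype=np.int8)  # unsuitable
    classes[p & ~f] = CLASS_CODES["loss"]
    classes[p & f] = CLASS_CODES["maintain"]
    classes[~p & f] = CLASS_CODES["gain"]
    return ChangeClassMap(
        classes=classes,
        valid_mask=present.valid_mask.copy(),
        grid=present.grid,
        species_id=str(present.provenance.get("species", "?")),
        scenario_id=str(future.provenance.get("scenario", "?")),
    )


def richness_delta(class_maps: list[ChangeClassMap]) -> np.ndarray:
    """Per-cell (species gaining) − (species losing) for one scenario.

    Positive values mark cells where climatic space is gained for more
    species than it is lost; range is [−S, +S] for S species.
    """
    if not class_maps:
        raise ValueError("no class maps given")
    scen = class_maps[0].scenario_id
    shape = class_maps[0].grid.shape
    delta = np.zeros(shape, dtype=int)
    for cm in class_maps:
        if cm.scenario_id != scen:
            raise ValueError("class maps mix scenarios")
        if cm.grid.shape != shape:
            raise ValueError("class maps on different grids")
        delta += (cm.classes == CLASS_CODES["gain"]).astype(int)
        delta -= (cm.classes == CLASS_CODES["loss"]).astype(int)
    return delta


def write_class_map(cm: ChangeClassMap, path: str | Path) -> None:
    """Write a class map as integer-coded .asc plus a JSON legend sidecar."""
    path = Path(path)
    out = np.where(cm.valid_mask, cm.classes.astype(int), NODATA_CODE)
    with open(path, "w") as fh:
        fh.write(f"ncols {cm.grid.n_cols}\n")
        fh.write(f"nrows {cm.grid.n_rows}\n")
        fh.write("xllcorner 0\nyllcorner 0\n")
        fh.write(f"cellsize {cm.grid.cell_size:g}\n")
        fh.write(f"NODATA_value {NODATA_CODE}\n")
        for row in out:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    legend = {str(code): label for label, code in CLASS_CODES.items()}
    legend[str(NODATA_CODE)] = "nodata"
    path.with_suffix(".legend.json").write_text(json.dumps(legend, indent=2))
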