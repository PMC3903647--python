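"""Grid containers and ESRI ASCII raster I/O.

All surfaces in the pipeline live on one shared rectangular grid with a common
nodata mask. Cells are addressed as 0-based ``(row, col)`` with row 0 at the
top, matching the ESRI ASCII raster order. A "cell index" is the flat index
``row * n_cols + col``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "SuitabilityGrid",
    "BinaryMap",
    "read_ascii_grid",
    "write_ascii_grid",
]

NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared planning grid.

    ``cell_size`` is in abstract length units; the pipeline never projects
    coordinates. ``nodata_fraction`` is the proportion of cells masked out
    when a synthetic landscape is generated.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    nodata_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 <= self.nodata_fraction < 1.0:
            raise ValueError("nodata_fraction must lie in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class SuitabilityGrid:
    """A continuous suitability surface in [0, 1] on a masked grid.

    ``values`` holds arbitrary numbers where ``valid_mask`` is False; all
    statistics ignore those cells.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.valid_mask.shape != self.grid.shape:
            raise ValueError("values/mask shape does not match GridSpec")
        vals = self.values[self.valid_mask]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("suitability values must lie in [0, 1] on valid cells")

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def at_cells(self, cells: Sequence[int]) -> np.ndarray:
        """Values at flat cell indices (must be valid cells)."""
        cells = np.asarray(cells, dtype=int)
        rows, cols = np.unravel_index(cells, self.grid.shape)
        if not self.valid_mask[rows, cols].all():
            raise ValueError("cell index on a nodata cell")
        return self.values[rows, cols]


@dataclass
class BinaryMap:
    """Binary presence/absence surface derived by thresholding."""

    presence: np.ndarray
    valid_mask: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.presence.shape != self.grid.shape:
            raise ValueError("presence shape does not match GridSpec")
        # presence is clipped to the valid mask so nodata never counts as suitable
        self.presence = self.presence & self.valid_mask

    @property
    def n_present(self) -> int:
        return int(self.presence.sum())

    def present_cells(self) -> np.ndarray:
        """Flat indices of present cells, sorted."""
        return np.flatnonzero(self.presence.ravel())


def same_mask(a, b) -> bool:
    return a.valid_mask.shape == b.valid_mask.shape and bool(
        np.array_equal(a.valid_mask, b.valid_mask)
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> SuitabilityGrid:
    """Read an ESRI ASCII grid (.asc) into a :class:`SuitabilityGrid`.

    The six header lines (ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value) are required, in any of the usual capitalizations.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: dict[str, float] = {}
    body_start = 0
    for i, ln in enumerate(lines):
        parts = ln.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"malformed ESRI ASCII header: missing {missing}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header["nodata_value"]
    data = np.loadtxt(io.StringIO("\n".join(lines[body_start:])), ndmin=2)
    if data.size != n_rows * n_cols:
        raise ValueError(
            f"grid body has {data.size} values, header promises {n_rows * n_cols}"
        )
    data = data.reshape(n_rows, n_cols)
    mask = ~np.isclose(data, nodata)
    values = np.where(mask, data, 0.0)
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=header["cellsize"])
    return SuitabilityGrid(values=values, valid_mask=mask, grid=spec)


def write_ascii_grid(
    grid_like,
    path: str | Path,
    nodata: float = NODATA_DEFAULT,
    fmt: str = "%.6g",
) -> None:
    """Write a SuitabilityGrid (or any values/valid_mask/grid object) as .asc."""
    values = np.asarray(grid_like.values if hasattr(grid_like, "values") else grid_like.presence)
    if values.dtype == bool:
        values = values.astype(float)
    mask = grid_like.valid_mask
    spec = grid_like.grid
    out = np.where(mask, values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write("xllcorner 0\n")
        fh.write("yllcorner 0\n")
        fh.write(f"cellsize {spec.cell_size:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")
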