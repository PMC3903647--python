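"""Niche-comparison statistics between model variants.

Used to justify projecting range shifts with the climatic-only model: if the
habitat-aware ("full") and climatic-only models agree cell-for-cell after
thresholding, overlap strongly as probability surfaces (Schoener's D), and
the climatic model's niche is at least as broad (standardized Levins' B),
then the climatic model captures essentially all conditions the full model
deems suitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BinaryMap, SuitabilityGrid, same_mask

__all__ = ["OverlapStats", "percent_agreement", "schoener_D", "niche_breadth"]


@dataclass(frozen=True)
class OverlapStats:
    percent_agreement: float
    pct_only_a: float
    pct_only_b: float


def percent_agreement(a: BinaryMap, b: BinaryMap) -> OverlapStats:
    """Percentage of valid cells where two binary predictions coincide."""
    if not same_mask(a, b):
        raise ValueError("maps have different valid masks")
    m = a.valid_mask
    n = int(m.sum())
    if n == 0:
        raise ValueError("no valid cells")
    pa, pb = a.presence[m], b.presence[m]
    agree = 100.0 * float(np.count_nonzero(pa == pb)) / n
    only_a = 100.0 * float(np.count_nonzero(pa & ~pb)) / n
    only_b = 100.0 * float(np.count_nonzero(~pa & pb)) / n
    return OverlapStats(percent_agreement=agree, pct_only_a=only_a, pct_only_b=only_b)


def _normalized(g: SuitabilityGrid) -> np.ndarray:
    v = g.valid_values().astype(float)
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero suitability surface")
    return v / total


def schoener_D(a: SuitabilityGrid, b: SuitabilityGrid) -> float:
    """Schoener's D niche overlap: 1 − ½·Σ|p − q| over normalized surfaces.

    Both surfaces are normalized to probability distributions over the
    shared valid cells, so D is symmetric, lies in [0, 1], and is invariant
    to uniform rescaling of either input.
    """
    if not same_mask(a, b):
        raise ValueError("grids have different valid masks")
    p, q = _normalized(a), _normalized(b)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def niche_breadth(a: SuitabilityGrid) -> float:
    """Standardized Levins' niche breadth, (1/Σp² − 1)/(n − 1) in [0, 1].

    1 for a uniform surface (maximal breadth), 0 when all suitability mass
    sits on a single cell.
    """
    p = _normalized(a)
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    return float((1.0 / np.square(p).sum() - 1.0) / (n - 1))
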