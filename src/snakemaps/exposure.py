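"""Snake-Human Overlap Index (SHOI) and summary rasters.

SHOI estimates where snake populations and people coincide: per-cell
habitat suitability multiplied by log-transformed human population
density.  The log damps the enormous right skew of settlement rasters
so that megacities do not swamp the index; ``ln(1 + pop)`` is used so
the index is zero (not undefined or negative) in unpopulated cells.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid, check_aligned


def shoi(suit: Grid, pop: Grid) -> Grid:
    """SHOI = suitability x ln(1 + population), per cell; nodata propagates."""
    check_aligned(suit, pop)
    if np.nanmin(pop.values) < 0:
        raise ValueError("population density must be non-negative")
    return Grid(suit.spec, suit.values * np.log1p(pop.values))


def group_summary(suits: list[Grid], mode: str = "max") -> Grid:
    """Combine per-species grids: cellwise ``max`` (species groups, whose
    members do not truly co-occur) or ``sum`` (cumulative suitability/SHOI)."""
    if len(suits) == 0:
        raise ValueError("need at least one grid to summarize")
    spec = check_aligned(*suits)
    stack = np.stack([g.values for g in suits], axis=0)
    if mode == "max":
        out = np.max(stack, axis=0)
    elif mode == "sum":
        out = np.sum(stack, axis=0)
    else:
        raise ValueError(f"unknown summary mode {mode!r}")
    return Grid(spec, out)


def richness(suits: list[Grid]) -> Grid:
    """Per-cell count of species with (thresholded) suitability > 0."""
    spec = check_aligned(*suits)
    stack = np.stack([np.nan_to_num(g.values, nan=0.0) for g in suits], axis=0)
    return Grid(spec, np.sum(stack > 0, axis=0).astype(float))
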