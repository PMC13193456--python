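"""Target-group background construction.

Presence-only models need background (pseudo-absence) samples; drawing
them from the records of the whole target group (here: all snakes)
cancels spatial sampling bias, because presences and background share
the same observer effort.  The background is cut to a buffer around the
modelling unit's occurrences sized to its geographic extent — a proxy
for the area plausibly accessible in its recent biogeographic history —
clamped between 1000 and 3000 km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import KM_PER_DEG, GridSpec
from .io import OccurrenceSet

BUFFER_MIN_KM = 1000.0
BUFFER_MAX_KM = 3000.0


@dataclass
class BackgroundSpec:
    mu_id: str
    buffer_km: float
    extent: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max
    cells: np.ndarray  # (n, 2) row/col of background cells
    pool_size: int

    def cell_centers(self, spec: GridSpec):
        lon, lat = spec.cell_center(self.cells[:, 0], self.cells[:, 1])
        return lon, lat


def compute_buffer(
    occs: OccurrenceSet,
    min_km: float = BUFFER_MIN_KM,
    max_km: float = BUFFER_MAX_KM,
) -> float:
    """Buffer width (km): the larger occurrence extent, clamped to [1000, 3000].

    The latitudinal extent converts at 111.195 km per degree; the
    longitudinal extent is measured along the parallel at the mean
    latitude (degrees shrink by cos(latitude) east-west).
    """
    if len(occs) == 0:
        raise ValueError("cannot size a buffer from an empty occurrence set")
    lat_extent_km = (occs.lat.max() - occs.lat.min()) * KM_PER_DEG
    mean_lat = occs.lat.mean()
    lon_extent_km = (
        (occs.lon.max() - occs.lon.min()) * KM_PER_DEG * np.cos(np.radians(mean_lat))
    )
    return float(np.clip(max(lat_extent_km, lon_extent_km), min_km, max_km))


def buffered_extent(occs: OccurrenceSet, width_km: float) -> tuple[float, float, float, float]:
    """Occurrence bounding box expanded by ``width_km`` on every side."""
    mean_lat = occs.lat.mean()
    dlat = width_km / KM_PER_DEG
    dlon = width_km / (KM_PER_DEG * max(np.cos(np.radians(mean_lat)), 1e-6))
    return (
        occs.lon.min() - dlon,
        max(occs.lat.min() - dlat, -90.0),
        occs.lon.max() + dlon,
        min(occs.lat.max() + dlat, 90.0),
    )


def build_background(
    pool: OccurrenceSet,
    mu_occs: OccurrenceSet,
    width_km: float,
    spec: GridSpec,
    mu_id: str | None = None,
) -> BackgroundSpec:
    """Unique cells of the target-group pool inside the buffered extent.

    The MU's own presence cells are part of the background (standard
    target-group practice).  Raises if no pool record falls inside the
    buffer — a degenerate background that cannot support a model.
    """
    if len(pool) == 0:
        raise ValueError("background pool is empty")
    lon_min, lat_min, lon_max, lat_max = buffered_extent(mu_occs, width_km)
    inside = (
        (pool.lon >= lon_min)
        & (pool.lon <= lon_max)
        & (pool.lat >= lat_min)
        & (pool.lat <= lat_max)
    )
    if not inside.any():
        raise ValueError("no pool record falls inside the buffered extent")
    i, j = spec.cell_of(pool.lon[inside], pool.lat[inside])
    cells = np.column_stack([i, j])
    mi, mj = spec.cell_of(mu_occs.lon, mu_occs.lat)
    cells = np.vstack([cells, np.column_stack([mi, mj])])
    cells = np.unique(cells, axis=0)
    # clip to grid
    ok = (
        (cells[:, 0] >= 0)
        & (cells[:, 0] < spec.n_rows)
        & (cells[:, 1] >= 0)
        & (cells[:, 1] < spec.n_cols)
    )
    cells = cells[ok]
    return BackgroundSpec(
        mu_id=mu_id or mu_occs.species,
        buffer_km=width_km,
        extent=(lon_min, lat_min, lon_max, lat_max),
        cells=cells,
        pool_size=int(inside.sum()),
    )
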