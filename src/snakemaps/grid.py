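"""Raster grid primitives on a fixed WGS84 lattice.

All rasters in the pipeline live on an axis-aligned lattice of square
cells in geographic coordinates (default 0.01 decimal degrees).  Cell
(0, 0) is the north-west corner cell; row index grows southward, column
index grows eastward.  A point maps to the cell whose half-open interval
[west, east) x (south, north] contains it, so cell_of(coord_of(i, j))
round-trips for every cell centre.

Nodata is represented internally as NaN; the ``nodata`` sentinel in
:class:`GridSpec` is only used when reading and writing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: metres per degree of latitude on the sphere used throughout (R = 6,371,000 m)
EARTH_RADIUS_M = 6_371_000.0
KM_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0 / 1000.0  # 111.195 km/degree


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the common lattice.

    ``origin_lon``/``origin_lat`` locate the north-west *corner* of cell
    (0, 0).  ``cell_size`` is in decimal degrees.
    """

    origin_lon: float
    origin_lat: float
    n_rows: int
    n_cols: int
    cell_size: float = 0.01
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- coordinate <-> index conventions ---------------------------------
    def cell_center(self, i, j):
        """Lon/lat of the centre of cell (i, j) (arrays allowed)."""
        lon = self.origin_lon + (np.asarray(j) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(i) + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon, lat):
        """Row/col of the cell containing a point ([west,east) x (south,north])."""
        j = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        # north edge belongs to the cell: use ceil on the southward offset
        i = np.ceil((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int) - 1
        i = np.where(np.asarray(lat) == self.origin_lat, 0, i)
        return i, j

    def contains(self, lon, lat):
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        east = self.origin_lon + self.n_cols * self.cell_size
        south = self.origin_lat - self.n_rows * self.cell_size
        return (lon >= self.origin_lon) & (lon < east) & (lat > south) & (lat <= self.origin_lat)

    def center_lonlats(self):
        """Meshgrid arrays (lon, lat) of all cell centres, shape (n_rows, n_cols)."""
        ii, jj = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        return self.cell_center(ii, jj)


@dataclass
class Grid:
    """A 2-D raster bound to a :class:`GridSpec`; NaN marks nodata."""

    spec: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match spec {self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell carries data."""
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(self.spec, np.asarray(values, dtype=float))

    def like(self, fill: float = np.nan) -> "Grid":
        return Grid(self.spec, np.full(self.spec.shape, fill, dtype=float))


def check_aligned(*grids: Grid) -> GridSpec:
    """Raise if the grids do not share one lattice; return the common spec."""
    spec = grids[0].spec
    for g in grids[1:]:
        if g.spec.shape != spec.shape or not (
            np.isclose(g.spec.origin_lon, spec.origin_lon)
            and np.isclose(g.spec.origin_lat, spec.origin_lat)
            and np.isclose(g.spec.cell_size, spec.cell_size)
        ):
            raise ValueError("grids are not on the same lattice")
    return spec


def spec_like(spec: GridSpec, **changes) -> GridSpec:
    return replace(spec, **changes)
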