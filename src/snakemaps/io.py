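"""Reading and writing the pipeline's file formats.

Rasters are stored as ESRI ASCII grids (``.asc``) — a plain-text,
GDAL/QGIS-readable format — with a WKT ``.prj`` sidecar pinning the CRS
to geographic WGS84.  Occurrence records travel as CSV with columns
``species, lon, lat, uncertainty_m``; polygons as GeoJSON.

Occurrence pre-filters follow standard presence-only practice: records
are snapped to the analysis lattice keeping one record per cell (the
most accurate one), and each species is optionally reduced to the 75%
of its records with the smallest positional uncertainty unless it has
fewer than 20 records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Grid, GridSpec

WGS84_WKT = (
    'GEOGCS["GCS_WGS_1984",DATUM["D_WGS_1984",SPHEROID["WGS_1984",6378137.0,'
    '298.257223563]],PRIMEM["Greenwich",0.0],UNIT["Degree",0.0174532925199433]]'
)

_WGS84_MARKERS = ("WGS_1984", "WGS 84", "WGS84", "4326")

OCC_COLUMNS = ("species", "lon", "lat", "uncertainty_m")


@dataclass
class OccurrenceSet:
    """Presence records for one species (or one modelling unit)."""

    species: str
    lon: np.ndarray
    lat: np.ndarray
    uncertainty_m: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.uncertainty_m = np.asarray(self.uncertainty_m, dtype=float)
        if not (len(self.lon) == len(self.lat) == len(self.uncertainty_m)):
            raise ValueError("lon, lat and uncertainty_m must have equal length")
        if len(self.lon) and (
            np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90)
        ):
            raise ValueError("coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return len(self.lon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "lon": self.lon,
                "lat": self.lat,
                "uncertainty_m": self.uncertainty_m,
            }
        )

    def cells(self, spec: GridSpec) -> np.ndarray:
        """(n, 2) array of (row, col) indices on ``spec``."""
        i, j = spec.cell_of(self.lon, self.lat)
        return np.column_stack([i, j])


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, grid: Grid) -> None:
    """Write an ESRI ASCII grid plus a WGS84 .prj sidecar.

    Values are written with 17 significant digits so that float64 values
    round-trip bit-exactly through the text representation.
    """
    path = Path(path)
    spec = grid.spec
    yll = spec.origin_lat - spec.n_rows * spec.cell_size
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_lon!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    vals = np.where(np.isnan(grid.values), spec.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")
    path.with_suffix(".prj").write_text(WGS84_WKT)


def read_raster(path: str | Path, nodata: float | None = None) -> Grid:
    """Read an ESRI ASCII grid; errors if a .prj sidecar names a non-WGS84 CRS."""
    path = Path(path)
    prj = path.with_suffix(".prj")
    if prj.exists():
        wkt = prj.read_text()
        if not any(marker in wkt for marker in _WGS84_MARKERS):
            name = wkt.split('"')[1] if '"' in wkt else wkt[:60]
            raise ValueError(f"raster CRS is not WGS84: {name!r}")
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid: missing {key} in {path}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + n_rows * cell
    else:  # cell-centre registration
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2 + n_rows * cell
    nd = header.get("nodata_value", nodata if nodata is not None else -9999.0)
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"malformed ASCII grid: data shape {data.shape} != header")
    spec = GridSpec(x0, y0, n_rows, n_cols, cell, nd)
    values = np.where(data == nd, np.nan, data)
    return Grid(spec, values)


def align_to_grid(raster: Grid, spec: GridSpec, mode: str = "mean") -> Grid:
    """Bring a raster onto the target lattice.

    Finer inputs are aggregated by block mean (``mode="mean"``, continuous
    layers) or block mode (``mode="mode"``, categorical layers); coarser
    inputs are resampled by nearest neighbour.  The input resolution must
    be an integer multiple or divisor of the target cell size.
    """
    src = raster.spec
    if src.shape == spec.shape and np.isclose(src.cell_size, spec.cell_size):
        return raster
    ratio = spec.cell_size / src.cell_size
    if ratio >= 1:  # aggregate fine -> coarse
        k = int(round(ratio))
        if not np.isclose(k, ratio, rtol=1e-9):
            raise ValueError("source and target resolutions are not commensurate")
        nr, nc = src.n_rows // k, src.n_cols // k
        blocks = raster.values[: nr * k, : nc * k].reshape(nr, k, nc, k)
        if mode == "mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out = np.nanmean(blocks, axis=(1, 3))
        elif mode == "mode":
            flat = blocks.transpose(0, 2, 1, 3).reshape(nr, nc, k * k)
            out = np.full((nr, nc), np.nan)
            for i in range(nr):
                for j in range(nc):
                    vals = flat[i, j][~np.isnan(flat[i, j])]
                    if len(vals):
                        uniq, counts = np.unique(vals, return_counts=True)
                        out[i, j] = uniq[np.argmax(counts)]
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
    else:  # resample coarse -> fine (nearest)
        inv = src.cell_size / spec.cell_size
        k = int(round(inv))
        if not np.isclose(k, inv, rtol=1e-9):
            raise ValueError("source and target resolutions are not commensurate")
        out = np.repeat(np.repeat(raster.values, k, axis=0), k, axis=1)
        out = out[: spec.n_rows, : spec.n_cols]
    return Grid(spec, out)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def write_occurrences(path: str | Path, occs: list[OccurrenceSet] | OccurrenceSet) -> None:
    if isinstance(occs, OccurrenceSet):
        occs = [occs]
    pd.concat([o.to_frame() for o in occs], ignore_index=True).to_csv(path, index=False)


def read_occurrences(path: str | Path, spec: GridSpec) -> dict[str, OccurrenceSet]:
    """Read a CSV of records and deduplicate to one record per grid cell.

    Within a cell the record with the smallest positional uncertainty is
    kept (ties: first in file).  Returns one OccurrenceSet per species.
    """
    df = pd.read_csv(path)
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"occurrence file {path} is empty")
        return {}
    out: dict[str, OccurrenceSet] = {}
    for species, sub in df.groupby("species", sort=True):
        out[str(species)] = dedup_per_cell(
            OccurrenceSet(
                str(species),
                sub["lon"].to_numpy(),
                sub["lat"].to_numpy(),
                sub["uncertainty_m"].to_numpy(),
            ),
            spec,
        )
    return out


def dedup_per_cell(occs: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Collapse records to one per grid cell, keeping the most accurate."""
    if len(occs) == 0:
        return occs
    i, j = spec.cell_of(occs.lon, occs.lat)
    df = pd.DataFrame(
        {"i": i, "j": j, "lon": occs.lon, "lat": occs.lat, "u": occs.uncertainty_m}
    )
    # stable sort on uncertainty keeps file order among ties
    df = df.sort_values("u", kind="stable").drop_duplicates(["i", "j"], keep="first")
    df = df.sort_index()
    return OccurrenceSet(occs.species, df["lon"].to_numpy(), df["lat"].to_numpy(), df["u"].to_numpy())


def filter_by_accuracy(occs: OccurrenceSet, frac: float = 0.75, min_records: int = 20) -> OccurrenceSet:
    """Keep the ``frac`` most accurate records; data-deficient species exempt.

    Species with fewer than ``min_records`` records keep everything; model
    accuracy degrades fastest below that count, so discarding records
    there costs more than the accuracy filter gains.  The cut keeps
    ``floor(frac * n)`` records; ties in uncertainty are broken by record
    order.
    """
    n = len(occs)
    if n < min_records:
        return occs
    keep = int(np.floor(frac * n))
    order = np.argsort(occs.uncertainty_m, kind="stable")[:keep]
    order = np.sort(order)
    return OccurrenceSet(
        occs.species, occs.lon[order], occs.lat[order], occs.uncertainty_m[order]
    )


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------

def write_geojson(path: str | Path, geoms, properties: list[dict] | None = None) -> None:
    from shapely.geometry import mapping

    try:
        iter(geoms)
    except TypeError:
        geoms = [geoms]
    geoms = list(geoms)
    props = properties or [{} for _ in geoms]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path):
    from shapely.geometry import shape

    fc = json.loads(Path(path).read_text())
    if fc.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in fc["features"]]
    if fc.get("type") == "Feature":
        return [shape(fc["geometry"])]
    return [shape(fc)]
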