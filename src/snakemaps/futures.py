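"""Climate-projection summaries, change metrics and range-shift vectors.

Future suitability is projected once per global climate model (GCM) and
summarized cellwise across the ensemble as the median (most likely),
10% quantile (minimum likely) and 90% quantile (maximum likely).
Changes between time steps are counted on thresholded grids (a cell is
"suitable" when its value is positive): range expansion is the number
of newly suitable cells, contraction the number of newly unsuitable
ones, and totals are sums over suitable cells.

Range shifts are summarized as a vector from the current to the future
distribution centroid (the plain mean of suitable cell-centre
coordinates): length D1 by the haversine great-circle distance on a
sphere of radius 6,371,000 m, direction D2 as the initial bearing in
degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_M, Grid, check_aligned


@dataclass
class GcmSummary:
    median: Grid
    q10: Grid
    q90: Grid
    n_gcms: int


@dataclass
class ChangeMetrics:
    range_size: int          # suitable cells in the future grid
    expansion: int           # newly suitable cells
    contraction: int         # newly unsuitable cells
    total_suitability: float
    total_shoi: float


@dataclass
class Centroid:
    lon: float
    lat: float


@dataclass
class ShiftVector:
    d1_m: float      # great-circle distance, metres
    d2_deg: float    # initial bearing, degrees in (-180, 180]


def summarize_gcms(grids: list[Grid]) -> GcmSummary:
    """Cellwise median / 10% / 90% quantiles across GCM projections."""
    if len(grids) < 2:
        raise ValueError("need at least 2 GCM grids to summarize")
    spec = check_aligned(*grids)
    stack = np.stack([g.values for g in grids], axis=0)
    q10, med, q90 = np.quantile(stack, [0.10, 0.50, 0.90], axis=0)
    return GcmSummary(Grid(spec, med), Grid(spec, q10), Grid(spec, q90), len(grids))


def change_metrics(
    current: Grid,
    future: Grid,
    shoi_current: Grid | None = None,
    shoi_future: Grid | None = None,
) -> ChangeMetrics:
    """Range and exposure change between two thresholded suitability grids."""
    check_aligned(current, future)
    cur = np.nan_to_num(current.values, nan=0.0) > 0
    fut = np.nan_to_num(future.values, nan=0.0) > 0
    total_shoi = 0.0
    if shoi_future is not None:
        total_shoi = float(np.nansum(np.where(fut, shoi_future.values, 0.0)))
    return ChangeMetrics(
        range_size=int(fut.sum()),
        expansion=int((fut & ~cur).sum()),
        contraction=int((cur & ~fut).sum()),
        total_suitability=float(np.nansum(np.where(fut, future.values, 0.0))),
        total_shoi=total_shoi,
    )


def centroid(suit: Grid) -> Centroid:
    """Unweighted mean of suitable cell-centre coordinates."""
    mask = np.nan_to_num(suit.values, nan=0.0) > 0
    if not mask.any():
        raise ValueError("no suitable cell; centroid undefined")
    i, j = np.nonzero(mask)
    lon, lat = suit.spec.cell_center(i, j)
    return Centroid(float(lon.mean()), float(lat.mean()))


def haversine_m(lat1_deg, lon1_deg, lat2_deg, lon2_deg, radius_m: float = EARTH_RADIUS_M):
    """Great-circle distance in metres (haversine on a 6,371 km sphere)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1_deg, lon1_deg, lat2_deg, lon2_deg))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return radius_m * 2 * np.arctan2(np.sqrt(a), np.sqrt(1 - a))


def initial_bearing_deg(lat1_deg, lon1_deg, lat2_deg, lon2_deg):
    """Initial great-circle bearing in degrees, in (-180, 180] (0 = north)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1_deg, lon1_deg, lat2_deg, lon2_deg))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x))


def shift_vector(c_now: Centroid, c_future: Centroid) -> ShiftVector:
    """Range-shift vector between two distribution centroids."""
    d1 = float(haversine_m(c_now.lat, c_now.lon, c_future.lat, c_future.lon))
    d2 = float(initial_bearing_deg(c_now.lat, c_now.lon, c_future.lat, c_future.lon))
    return ShiftVector(d1, d2)


def circular_median_deg(bearings_deg: np.ndarray) -> float:
    """Bearing minimizing the summed circular distance to the sample.

    The minimizer is searched over the observed bearings (for even
    samples the geometric circular median may lie between two points;
    restricting candidates to the data keeps the estimate well defined
    and matches the usual discrete definition).
    """
    b = np.asarray(bearings_deg, dtype=float) % 360.0
    if b.size == 0:
        raise ValueError("no bearings")
    # candidates: the observations plus shorter-arc midpoints of every pair
    signed = ((b[None, :] - b[:, None] + 180.0) % 360.0) - 180.0
    mids = (b[:, None] + signed / 2.0).ravel() % 360.0
    cands = np.unique(np.concatenate([b, mids]))
    d = np.abs(b[None, :] - cands[:, None]) % 360.0
    sums = np.minimum(d, 360.0 - d).sum(axis=1)
    tied = cands[sums <= sums.min() + 1e-9]
    # ties (even samples): prefer the candidate nearest the circular mean
    mean = np.degrees(
        np.arctan2(np.sin(np.radians(b)).sum(), np.cos(np.radians(b)).sum())
    ) % 360.0
    dm = np.abs(tied - mean) % 360.0
    out = tied[np.argmin(np.minimum(dm, 360.0 - dm))] % 360.0
    return float(out - 360.0 if out > 180.0 else out)


def regional_summary(vectors: pd.DataFrame, region_col: str = "region") -> pd.DataFrame:
    """Per-region median shift: circular median bearing + median length.

    ``vectors`` needs columns ``d1_m``, ``d2_deg`` and the region label;
    empty regions are skipped with a warning.
    """
    rows = []
    for region, sub in vectors.groupby(region_col, sort=True):
        if len(sub) == 0:
            warnings.warn(f"region {region!r} has no vectors; skipped")
            continue
        rows.append(
            {
                region_col: region,
                "n": len(sub),
                "d1_m": float(np.median(sub["d1_m"])),
                "d2_deg": circular_median_deg(sub["d2_deg"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)
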