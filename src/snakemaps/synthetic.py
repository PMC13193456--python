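"""Synthetic landscapes with known ground truth.

Every downstream stage of the pipeline — variable screening, niche
modelling, cost-distance restriction, exposure indices, projection and
validation — is exercised against data generated here, where the true
suitability surface, the sampling bias and the population field are all
known.  The generator emulates the statistical features the pipeline
must cope with: spatially autocorrelated environmental layers including
designed collinear pairs, presence points sampled proportional to
suitability times an observer-bias field, clustered lognormal human
population density, per-GCM future climate perturbations, and
expert-style range polygons traced from the truth surface.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Grid, GridSpec
from .io import OccurrenceSet


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian-filtered white noise (spatially autocorrelated)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (z - z.mean()) / z.std()


def gen_env_stack(
    spec: GridSpec,
    n_layers: int,
    corr_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
    sigma: float = 8.0,
    corr_noise_sd: float = 0.35,
) -> list[Grid]:
    """Generate ``n_layers`` autocorrelated environmental layers.

    For each ``(i, j)`` in ``corr_pairs``, layer ``j`` is rebuilt as layer
    ``i`` plus independent smoothed noise of standard deviation
    ``corr_noise_sd``, giving an empirical Pearson |r| of roughly
    1/sqrt(1 + sd^2) ~ 0.94 — comfortably above the 0.8 screening cut the
    collinearity filter applies.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = np.random.default_rng(seed)
    layers = [_smooth_field(rng, spec.shape, sigma) for _ in range(n_layers)]
    for i, j in corr_pairs or []:
        noise = _smooth_field(rng, spec.shape, sigma)
        mixed = layers[i] + corr_noise_sd * noise
        layers[j] = (mixed - mixed.mean()) / mixed.std()
    return [Grid(spec, lyr) for lyr in layers]


@dataclass
class TruthModel:
    """The known niche: logistic in linear and quadratic layer terms."""

    linear: np.ndarray  # coefficient per layer
    quadratic: np.ndarray = None
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        if self.quadratic is None:
            self.quadratic = np.zeros_like(self.linear)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        if self.quadratic.shape != self.linear.shape:
            raise ValueError("linear and quadratic coefficient counts differ")


def gen_true_suitability(stack: list[Grid], truth: TruthModel) -> Grid:
    """Evaluate the truth model over the stack: logistic(b0 + b.x + c.x^2)."""
    if len(stack) != len(truth.linear):
        raise ValueError(
            f"stack has {len(stack)} layers but truth has {len(truth.linear)} coefficients"
        )
    eta = np.full(stack[0].spec.shape, truth.intercept, dtype=float)
    for lyr, b, c in zip(stack, truth.linear, truth.quadratic):
        eta = eta + b * lyr.values + c * lyr.values**2
    return Grid(stack[0].spec, 1.0 / (1.0 + np.exp(-eta)))


def gen_bias_field(spec: GridSpec, kind: str = "gradient", seed: int = 0) -> Grid:
    """Observer-effort field; default is a smooth road-like west-east gradient."""
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        return Grid(spec, np.ones(spec.shape))
    if kind == "gradient":
        col = np.linspace(0.2, 1.0, spec.n_cols)
        base = np.tile(col, (spec.n_rows, 1))
        ripple = 0.15 * _smooth_field(rng, spec.shape, sigma=6.0)
        return Grid(spec, np.clip(base + ripple, 0.05, None))
    raise ValueError(f"unknown bias kind {kind!r}")


def gen_occurrences(
    truth_grid: Grid,
    n: int,
    bias_grid: Grid | None = None,
    seed: int = 0,
    species: str = "sp1",
    uncertainty_median_m: float = 100.0,
    uncertainty_sigma: float = 0.75,
) -> OccurrenceSet:
    """Sample presence points with probability proportional to truth x bias.

    Points are jittered uniformly within their cell; each record gets a
    lognormal positional uncertainty (median 100 m) so the accuracy
    filter has something to act on.
    """
    spec = truth_grid.spec
    rng = np.random.default_rng(seed)
    if n == 0:
        return OccurrenceSet(species, np.array([]), np.array([]), np.array([]))
    weights = np.nan_to_num(truth_grid.values, nan=0.0).ravel().copy()
    if bias_grid is not None:
        weights *= np.nan_to_num(bias_grid.values, nan=0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("sampling surface is all zero; cannot draw occurrences")
    idx = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    i, j = np.unravel_index(idx, spec.shape)
    lon = spec.origin_lon + (j + rng.uniform(0, 1, n)) * spec.cell_size
    lat = spec.origin_lat - (i + rng.uniform(0, 1, n)) * spec.cell_size
    unc = rng.lognormal(np.log(uncertainty_median_m), uncertainty_sigma, n)
    return OccurrenceSet(species, lon, lat, unc)


def gen_population(
    spec: GridSpec,
    n_clusters: int = 12,
    seed: int = 0,
    background_mean: float = 2.0,
    amp_median: float = 500.0,
    amp_sigma: float = 1.0,
    cluster_sigma_cells: float = 4.0,
) -> Grid:
    """Clustered human population density (people per grid cell).

    Lognormal-amplitude Gaussian hotspots over a thin exponential
    background — a crude stand-in for the strongly right-skewed, spatially
    clustered layout of real settlement rasters.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    rng = np.random.default_rng(seed)
    pop = rng.exponential(background_mean, spec.shape)
    bumps = np.zeros(spec.shape)
    for _ in range(n_clusters):
        ci = rng.uniform(0, spec.n_rows)
        cj = rng.uniform(0, spec.n_cols)
        amp = rng.lognormal(np.log(amp_median), amp_sigma)
        ii = np.arange(spec.n_rows)[:, None]
        jj = np.arange(spec.n_cols)[None, :]
        d2 = (ii - ci) ** 2 + (jj - cj) ** 2
        bumps += amp * np.exp(-d2 / (2 * cluster_sigma_cells**2))
    return Grid(spec, pop + bumps)


def gen_future_stacks(
    stack: list[Grid],
    deltas: dict[int, float],
    n_gcms: int = 7,
    seed: int = 0,
    noise_sd: float = 0.1,
    sigma: float = 8.0,
) -> list[list[Grid]]:
    """Per-GCM future stacks: designated climate layers shift, others are constant.

    ``deltas`` maps layer index -> mean change; each GCM adds its own
    smoothed noise realization (sd ``noise_sd``) on top of the shared
    shift, emulating inter-model disagreement.  Layers not named in
    ``deltas`` are carried over untouched, matching the projection design
    in which only climate varies between time steps.
    """
    if n_gcms < 1:
        raise ValueError("n_gcms must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_gcms):
        future = []
        for k, lyr in enumerate(stack):
            if k in deltas:
                noise = (
                    noise_sd * _smooth_field(rng, lyr.spec.shape, sigma)
                    if noise_sd > 0
                    else 0.0
                )
                future.append(Grid(lyr.spec, lyr.values + deltas[k] + noise))
            else:
                future.append(Grid(lyr.spec, lyr.values.copy()))
        out.append(future)
    return out


def gen_edr(truth_grid: Grid, cutoff: float):
    """Synthetic expert-derived range: polygons tracing cells with truth >= cutoff.

    A stand-in for hand-drawn expert polygons, built as the union of the
    cells whose true suitability reaches the cutoff.
    """
    import shapely
    from shapely.geometry import box

    if not (0.0 <= cutoff <= 1.01):
        raise ValueError("cutoff must lie in [0, 1.01]")
    spec = truth_grid.spec
    ii, jj = np.nonzero(np.nan_to_num(truth_grid.values, nan=-1.0) >= cutoff)
    if len(ii) == 0:
        return []
    west = spec.origin_lon + jj * spec.cell_size
    north = spec.origin_lat - ii * spec.cell_size
    boxes = shapely.box(west, north - spec.cell_size, west + spec.cell_size, north)
    merged = shapely.unary_union(boxes)
    if merged.geom_type == "Polygon":
        return [merged]
    return list(merged.geoms)
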