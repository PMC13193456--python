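"""Cost-distance range restriction and modelling-unit splitting.

Habitat suitability alone overpredicts: disconnected but climatically
suitable areas (islands, habitat beyond dispersal barriers) are not
occupied.  Accumulated cost distance from the known occurrences, with
per-cell resistance inverse to suitability, measures how hard a cell is
to reach through the habitat; areas beyond a cut-off (default 500 cost
distance units, CDU) are removed.  One CDU corresponds to one rook step
through perfect habitat (suitability 1).

Species modelled jointly in a multi-species modelling unit are separated
by assigning each cell to the species with the lowest cost distance,
with a fade-out in contact zones: where the two nearest species are both
within the overlap allowance, each is downweighted by the opposite
species' share of the summed cost distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import Grid, check_aligned
from .io import OccurrenceSet

DEFAULT_MAX_CDU = 500.0
DEFAULT_OVERLAP_CDU = 500.0
DEFAULT_FLOOR = 1e-6


@dataclass
class CostSurface:
    grid: Grid               # accumulated CDU; inf where unreachable, NaN nodata
    source_cells: np.ndarray  # (n, 2) row/col


def _lattice_graph(resistance: np.ndarray, valid: np.ndarray) -> coo_matrix:
    """8-connected sparse graph; edge cost = step length x mean resistance."""
    n_rows, n_cols = resistance.shape
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    rows, cols, costs = [], [], []
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    for di, dj, length in offsets:
        i0 = slice(max(0, -di), n_rows - max(0, di))
        j0 = slice(max(0, -dj), n_cols - max(0, dj))
        i1 = slice(max(0, di), n_rows - max(0, -di))
        j1 = slice(max(0, dj), n_cols - max(0, -dj))
        ok = valid[i0, j0] & valid[i1, j1]
        a = idx[i0, j0][ok]
        b = idx[i1, j1][ok]
        w = length * 0.5 * (resistance[i0, j0][ok] + resistance[i1, j1][ok])
        rows.append(a)
        cols.append(b)
        costs.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    costs = np.concatenate(costs)
    n = n_rows * n_cols
    return coo_matrix((costs, (rows, cols)), shape=(n, n))


def cost_distance(
    suit: Grid, occs: OccurrenceSet, floor: float = DEFAULT_FLOOR
) -> CostSurface:
    """Multi-source accumulated cost distance from the occurrence cells.

    Resistance per cell is ``1 / max(suitability, floor)``; an edge
    between neighbouring cells costs its step length (1 rook, sqrt(2)
    diagonal) times the mean of the two resistances.  Occurrence cells
    have cost 0.
    """
    spec = suit.spec
    vals = suit.values
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("suitability must lie in [0, 1]")
    valid = ~np.isnan(vals)
    resistance = 1.0 / np.maximum(np.nan_to_num(vals, nan=0.0), floor)
    i, j = spec.cell_of(occs.lon, occs.lat)
    inside = (i >= 0) & (i < spec.n_rows) & (j >= 0) & (j < spec.n_cols)
    i, j = i[inside], j[inside]
    on_data = valid[i, j]
    i, j = i[on_data], j[on_data]
    if len(i) == 0:
        raise ValueError("no occurrence falls on a data cell of the grid")
    sources = np.unique(np.column_stack([i, j]), axis=0)
    graph = _lattice_graph(resistance, valid)
    flat_sources = sources[:, 0] * spec.n_cols + sources[:, 1]
    dist = dijkstra(graph, directed=False, indices=flat_sources, min_only=True)
    dist = dist.reshape(spec.shape)
    dist = np.where(valid, dist, np.nan)
    return CostSurface(Grid(spec, dist), sources)


def clip_by_cdu(
    suit: Grid, cost: CostSurface, max_cdu: float = DEFAULT_MAX_CDU
) -> tuple[Grid, Grid]:
    """Zero suitability beyond ``max_cdu``; returns (clipped, raw copy).

    Cells at exactly the cut-off are kept.  The unrestricted raw grid is
    returned alongside, since both versions are published.
    """
    check_aligned(suit, cost.grid)
    raw = suit.copy_with(suit.values.copy())
    v = suit.values.copy()
    far = np.nan_to_num(cost.grid.values, nan=np.inf) > max_cdu
    v[far & ~np.isnan(v)] = 0.0
    return Grid(suit.spec, v), raw


def split_mu(
    mu_suit: Grid,
    costs: list[CostSurface],
    overlap_cdu: float = DEFAULT_OVERLAP_CDU,
    threshold: float = 0.0,
) -> list[Grid]:
    """Separate a multi-species MU surface into per-species surfaces.

    Each cell belongs to the species with the lowest cost distance.  In
    contact zones — where the two nearest species are both within
    ``overlap_cdu`` — both are kept but faded out proportional to the
    overlap ratio: ``w_s = cd_other / (cd_s + cd_other)`` (so two species
    at equal cost distance are each downweighted by 50%).  When more
    than two species fall within the allowance, the rule applies to the
    two nearest and the rest are excluded.  Downweighted cells that drop
    below the original model threshold are re-set to 0.
    """
    if len(costs) == 0:
        raise ValueError("need at least one species cost surface")
    for c in costs:
        check_aligned(mu_suit, c.grid)
    if len(costs) == 1:
        return [mu_suit.copy_with(mu_suit.values.copy())]
    cd = np.stack(
        [np.nan_to_num(c.grid.values, nan=np.inf) for c in costs], axis=0
    )
    order = np.argsort(cd, axis=0, kind="stable")
    first = order[0]          # argmin species index per cell
    second = order[1]
    cd_sorted = np.sort(cd, axis=0)
    cd1, cd2 = cd_sorted[0], cd_sorted[1]
    pairwise = cd2 < overlap_cdu  # the two nearest overlap here
    denom = cd1 + cd2
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(denom > 0, cd2 / denom, 0.5)
        w2 = np.where(denom > 0, cd1 / denom, 0.5)
    out = []
    for s in range(len(costs)):
        w = np.zeros(mu_suit.spec.shape)
        w = np.where((first == s) & ~pairwise, 1.0, w)
        w = np.where((first == s) & pairwise, w1, w)
        w = np.where((second == s) & pairwise, w2, w)
        v = w * mu_suit.values
        downweighted = (w < 1.0) & ~np.isnan(v)
        v = np.where(downweighted & (v < threshold), 0.0, v)
        out.append(Grid(mu_suit.spec, v))
    return out
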