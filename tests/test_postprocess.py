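import numpy as np
import pytest

from snakemaps.grid import Grid, GridSpec
from snakemaps.io import OccurrenceSet
from snakemaps.postprocess import CostSurface, clip_by_cdu, cost_distance, split_mu

from conftest import make_grid


def occ_at_cells(spec, cells, name="sp"):
    lon, lat = zip(*[spec.cell_center(i, j) for i, j in cells])
    return OccurrenceSet(name, np.asarray(lon), np.asarray(lat), np.full(len(cells), 10.0))


def networkx_cost_oracle(suit_values, sources, floor=1e-6):
    """Independent brute-force multi-source Dijkstra via networkx."""
    import networkx as nx

    n_rows, n_cols = suit_values.shape
    r = 1.0 / np.maximum(np.nan_to_num(suit_values, nan=0.0), floor)
    valid = ~np.isnan(suit_values)
    G = nx.Graph()
    for i in range(n_rows):
        for j in range(n_cols):
            if not valid[i, j]:
                continue
            for di, dj in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                ii, jj = i + di, j + dj
                if 0 <= ii < n_rows and 0 <= jj < n_cols and valid[ii, jj]:
                    length = np.sqrt(2) if di and dj else 1.0
                    G.add_edge((i, j), (ii, jj), weight=length * (r[i, j] + r[ii, jj]) / 2)
            G.add_node((i, j))
    dist = nx.multi_source_dijkstra_path_length(G, {tuple(s) for s in sources})
    out = np.full((n_rows, n_cols), np.inf)
    for (i, j), d in dist.items():
        out[i, j] = d
    out[~valid] = np.nan
    return out


class TestCostDistance:
    def test_source_cell_costs_zero(self):
        grid = make_grid(np.full((5, 5), 0.5))
        occs = occ_at_cells(grid.spec, [(2, 2)])
        cost = cost_distance(grid, occs)
        assert cost.grid.values[2, 2] == 0.0

    def test_uniform_half_suitability_strip(self):
        """Resistance 1/0.5 = 2: each rook step costs 2, ten steps cost 20."""
        grid = make_grid(np.full((1, 12), 0.5))
        occs = occ_at_cells(grid.spec, [(0, 0)])
        cost = cost_distance(grid, occs)
        assert cost.grid.values[0, 1] == pytest.approx(2.0)
        assert cost.grid.values[0, 10] == pytest.approx(20.0)

    def test_single_diagonal_step_through_perfect_habitat(self):
        grid = make_grid(np.ones((2, 2)))
        occs = occ_at_cells(grid.spec, [(0, 0)])
        cost = cost_distance(grid, occs)
        assert cost.grid.values[1, 1] == pytest.approx(np.sqrt(2))

    def test_matches_independent_dijkstra_on_random_grids(self, rng):
        for _ in range(10):
            vals = rng.uniform(0.05, 1.0, (15, 15))
            vals[rng.uniform(size=(15, 15)) < 0.1] = np.nan
            grid = make_grid(vals)
            sources = [(int(a), int(b)) for a, b in rng.integers(0, 15, (3, 2))]
            sources = [s for s in sources if not np.isnan(vals[s])]
            if not sources:
                continue
            cost = cost_distance(grid, occ_at_cells(grid.spec, sources))
            oracle = networkx_cost_oracle(vals, sources)
            np.testing.assert_allclose(cost.grid.values, oracle, rtol=1e-10)

    def test_all_occurrences_on_nodata_rejected(self):
        vals = np.full((4, 4), 0.5)
        vals[1, 1] = np.nan
        grid = make_grid(vals)
        with pytest.raises(ValueError):
            cost_distance(grid, occ_at_cells(grid.spec, [(1, 1)]))

    def test_out_of_range_suitability_rejected(self):
        grid = make_grid(np.full((3, 3), 1.5))
        with pytest.raises(ValueError):
            cost_distance(grid, occ_at_cells(grid.spec, [(0, 0)]))


class TestClipByCdu:
    def _strip(self):
        """Integer-cost strip: cell k costs exactly k CDU from the source."""
        grid = make_grid(np.ones((1, 600)))
        occs = occ_at_cells(grid.spec, [(0, 0)])
        return grid, cost_distance(grid, occs)

    def test_boundary_cell_kept_next_removed(self):
        grid, cost = self._strip()
        assert cost.grid.values[0, 500] == pytest.approx(500.0)
        clipped, raw = clip_by_cdu(grid, cost, 500.0)
        assert clipped.values[0, 500] == 1.0   # exactly 500 CDU: kept
        assert clipped.values[0, 501] == 0.0   # 501 CDU: removed
        assert np.max(np.nonzero(clipped.values[0])[0]) == 500
        assert raw.values[0, 501] == 1.0       # raw companion unrestricted

    def test_zero_cost_keeps_everything(self):
        grid = make_grid(np.ones((3, 3)))
        cost = CostSurface(make_grid(np.zeros((3, 3))), np.array([[0, 0]]))
        clipped, _ = clip_by_cdu(grid, cost, 500.0)
        np.testing.assert_array_equal(clipped.values, grid.values)

    def test_retained_count_monotone_in_max_cdu(self):
        grid, cost = self._strip()
        counts = [
            (clip_by_cdu(grid, cost, m)[0].values > 0).sum()
            for m in (100.0, 500.0, 1000.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestSplitMu:
    def _cost(self, values):
        return CostSurface(make_grid(np.asarray(values, float)), np.zeros((1, 2), int))

    def test_equal_cost_250_downweights_both_by_half(self):
        suit = make_grid([[0.8]])
        costs = [self._cost([[250.0]]), self._cost([[250.0]])]
        out = split_mu(suit, costs, overlap_cdu=500.0)
        assert out[0].values[0, 0] == pytest.approx(0.4)
        assert out[1].values[0, 0] == pytest.approx(0.4)

    def test_asymmetric_overlap_weights_by_cost_ratio(self):
        suit = make_grid([[1.0]])
        costs = [self._cost([[100.0]]), self._cost([[300.0]])]
        out = split_mu(suit, costs, overlap_cdu=500.0)
        assert out[0].values[0, 0] == pytest.approx(0.75)
        assert out[1].values[0, 0] == pytest.approx(0.25)

    def test_single_species_mu_is_identity(self, random_grid):
        zero_cost = CostSurface(
            random_grid.copy_with(np.zeros(random_grid.spec.shape)),
            np.zeros((1, 2), int),
        )
        out = split_mu(random_grid, [zero_cost])
        np.testing.assert_array_equal(out[0].values, random_grid.values)

    def test_distant_species_excluded_from_cell(self):
        suit = make_grid([[1.0]])
        costs = [self._cost([[100.0]]), self._cost([[900.0]])]
        out = split_mu(suit, costs, overlap_cdu=500.0)
        assert out[0].values[0, 0] == 1.0
        assert out[1].values[0, 0] == 0.0

    def test_third_species_excluded_in_three_way_overlap(self):
        suit = make_grid([[1.0]])
        costs = [self._cost([[100.0]]), self._cost([[200.0]]), self._cost([[400.0]])]
        out = split_mu(suit, costs, overlap_cdu=500.0)
        assert out[0].values[0, 0] == pytest.approx(200.0 / 300.0)
        assert out[1].values[0, 0] == pytest.approx(100.0 / 300.0)
        assert out[2].values[0, 0] == 0.0

    def test_rethreshold_zeroes_faded_low_cells(self):
        suit = make_grid([[0.4]])
        costs = [self._cost([[250.0]]), self._cost([[250.0]])]
        out = split_mu(suit, costs, overlap_cdu=500.0, threshold=0.3)
        # both faded to 0.2 < 0.3 -> re-set to 0
        assert out[0].values[0, 0] == 0.0
        assert out[1].values[0, 0] == 0.0

    def test_dominance_and_weight_conservation_on_random_fields(self, rng):
        suit = make_grid(rng.uniform(0.2, 1.0, (12, 12)))
        costs = [self._cost(rng.uniform(0, 800, (12, 12))) for _ in range(3)]
        out = split_mu(suit, costs, overlap_cdu=500.0)
        cd = np.stack([c.grid.values for c in costs])
        vals = np.stack([g.values for g in out])
        # the species with minimal cost distance always has maximal output
        winners = np.argmin(cd, axis=0)
        assert np.all(np.take_along_axis(vals, winners[None], 0)[0] == vals.max(axis=0))
        # in pairwise overlap zones the two shares sum to the MU suitability
        cd_sorted = np.sort(cd, axis=0)
        pairwise = cd_sorted[1] < 500.0
        np.testing.assert_allclose(
            vals.sum(axis=0)[pairwise], suit.values[pairwise]
        )
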