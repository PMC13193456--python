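import numpy as np
import pandas as pd
import pytest

from snakemaps.futures import (
    Centroid,
    centroid,
    change_metrics,
    circular_median_deg,
    haversine_m,
    initial_bearing_deg,
    regional_summary,
    shift_vector,
    summarize_gcms,
)
from snakemaps.grid import EARTH_RADIUS_M, GridSpec

from conftest import make_grid


class TestGcmSummary:
    def test_seven_gcms_give_three_summary_grids(self, rng):
        grids = [make_grid(rng.uniform(0, 1, (6, 6))) for _ in range(7)]
        s = summarize_gcms(grids)
        assert s.n_gcms == 7
        assert s.median.values.shape == (6, 6)

    def test_identical_grids_collapse(self, random_grid):
        s = summarize_gcms([random_grid] * 5)
        for g in (s.median, s.q10, s.q90):
            np.testing.assert_allclose(g.values, random_grid.values)

    def test_quantiles_match_sorting_oracle_and_order(self, rng):
        stack = rng.uniform(0, 1, (7, 5, 5))
        grids = [make_grid(v) for v in stack]
        s = summarize_gcms(grids)
        for i in range(5):
            for j in range(5):
                cell = np.sort(stack[:, i, j])
                np.testing.assert_allclose(
                    s.q10.values[i, j], np.quantile(cell, 0.1)
                )
        assert np.all(s.q10.values <= s.median.values + 1e-12)
        assert np.all(s.median.values <= s.q90.values + 1e-12)

    def test_single_grid_rejected(self, random_grid):
        with pytest.raises(ValueError):
            summarize_gcms([random_grid])


class TestChangeMetrics:
    def test_no_change(self, random_grid):
        m = change_metrics(random_grid, random_grid)
        assert m.expansion == 0 and m.contraction == 0

    def test_hand_counted_toy(self):
        cur = make_grid([[0.5, 0.5, 0.0, 0.0, 0.0, 0.3, 0.3, 0.0, 0.0, 0.0]])
        fut = make_grid([[0.5, 0.0, 0.4, 0.4, 0.4, 0.3, 0.0, 0.0, 0.0, 0.0]])
        m = change_metrics(cur, fut)
        assert m.expansion == 3
        assert m.contraction == 2
        assert m.range_size == (cur.values > 0).sum() + 3 - 2

    def test_total_loss(self, random_grid):
        empty = random_grid.copy_with(np.zeros(random_grid.spec.shape))
        m = change_metrics(random_grid, empty)
        assert m.total_suitability == 0
        assert m.contraction == (random_grid.values > 0).sum()

    def test_identity_future_equals_current_plus_net(self, rng):
        for _ in range(20):
            cur = make_grid((rng.uniform(0, 1, (8, 8)) > 0.5) * rng.uniform(0, 1, (8, 8)))
            fut = make_grid((rng.uniform(0, 1, (8, 8)) > 0.5) * rng.uniform(0, 1, (8, 8)))
            m = change_metrics(cur, fut)
            assert m.range_size == (cur.values > 0).sum() + m.expansion - m.contraction


class TestCentroid:
    def test_single_suitable_cell(self):
        vals = np.zeros((5, 5))
        vals[2, 3] = 0.8
        g = make_grid(vals)
        c = centroid(g)
        lon, lat = g.spec.cell_center(2, 3)
        assert (c.lon, c.lat) == (pytest.approx(lon), pytest.approx(lat))

    def test_symmetry_about_equator(self):
        spec = GridSpec(0.0, 0.02, 4, 1)  # rows straddle lat 0
        vals = np.zeros((4, 1))
        vals[0, 0] = vals[3, 0] = 1.0  # lat +0.015 and -0.015
        from snakemaps.grid import Grid

        c = centroid(Grid(spec, vals))
        assert c.lat == pytest.approx(0.0)

    def test_matches_coordinate_mean_loop(self, rng):
        vals = (rng.uniform(0, 1, (10, 10)) > 0.6).astype(float)
        if not vals.any():
            vals[0, 0] = 1.0
        g = make_grid(vals)
        c = centroid(g)
        lons, lats = [], []
        for i in range(10):
            for j in range(10):
                if vals[i, j] > 0:
                    lon, lat = g.spec.cell_center(i, j)
                    lons.append(lon)
                    lats.append(lat)
        assert c.lon == pytest.approx(np.mean(lons))
        assert c.lat == pytest.approx(np.mean(lats))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            centroid(make_grid(np.zeros((3, 3))))


class TestShiftVector:
    def test_no_shift(self):
        c = Centroid(10.0, 5.0)
        assert shift_vector(c, c).d1_m == 0.0

    def test_one_degree_east_at_equator(self):
        v = shift_vector(Centroid(0.0, 0.0), Centroid(1.0, 0.0))
        assert v.d1_m == pytest.approx(EARTH_RADIUS_M * np.pi / 180, rel=1e-9)
        assert v.d1_m == pytest.approx(111194.93, abs=0.01)
        assert v.d2_deg == pytest.approx(90.0)

    def test_one_degree_north_bears_zero(self):
        east = shift_vector(Centroid(0.0, 0.0), Centroid(1.0, 0.0))
        north = shift_vector(Centroid(0.0, 0.0), Centroid(0.0, 1.0))
        assert north.d2_deg == pytest.approx(0.0)
        assert north.d1_m == pytest.approx(east.d1_m, rel=1e-9)

    def test_agreement_with_independent_great_circle_oracle(self, rng):
        """Haversine and bearing vs an independently coded vector-geometry
        oracle (unit-sphere chords and cross products), 1000 random pairs."""
        lat1 = rng.uniform(-80, 80, 1000)
        lat2 = rng.uniform(-80, 80, 1000)
        lon1 = rng.uniform(-180, 180, 1000)
        lon2 = rng.uniform(-180, 180, 1000)

        def to_xyz(lat, lon):
            la, lo = np.radians(lat), np.radians(lon)
            return np.stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo),
                             np.sin(la)], axis=-1)

        a, b = to_xyz(lat1, lon1), to_xyz(lat2, lon2)
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        dot = np.sum(a * b, axis=1)
        oracle_d = EARTH_RADIUS_M * np.arctan2(cross, dot)
        d = haversine_m(lat1, lon1, lat2, lon2)
        np.testing.assert_allclose(d, oracle_d, rtol=1e-6)

        # bearing oracle: project the chord to b onto the local east/north
        # tangent basis at a
        z = np.array([0.0, 0.0, 1.0])
        east = np.cross(np.broadcast_to(z, a.shape), a)
        east /= np.linalg.norm(east, axis=1, keepdims=True)
        north_t = np.cross(a, east)
        chord = b - dot[:, None] * a
        oracle_bearing = np.degrees(
            np.arctan2(np.sum(chord * east, axis=1), np.sum(chord * north_t, axis=1))
        )
        bearing = initial_bearing_deg(lat1, lon1, lat2, lon2)
        diff = (bearing - oracle_bearing + 180) % 360 - 180
        np.testing.assert_allclose(diff, 0.0, atol=1e-6)


class TestRegionalSummary:
    def test_constant_bearings(self):
        assert circular_median_deg(np.full(5, 45.0)) == pytest.approx(45.0)

    def test_wraparound_median(self):
        """Bearings 350 and 10 degrees straddle north; the median is 0."""
        assert circular_median_deg(np.array([350.0, 10.0])) == pytest.approx(0.0)

    def test_median_matches_brute_force_minimization(self, rng):
        b = rng.uniform(0, 360, 7)
        med = circular_median_deg(b)
        grid = np.linspace(0, 360, 72001)
        d = np.abs(b[None, :] - grid[:, None]) % 360
        sums = np.minimum(d, 360 - d).sum(axis=1)
        assert sums.min() >= _circ_sum(b, med) - 1e-6


    def test_per_region_output(self, rng):
        df = pd.DataFrame(
            {
                "region": ["a"] * 4 + ["b"] * 3,
                "d1_m": rng.uniform(0, 1e5, 7),
                "d2_deg": rng.uniform(0, 360, 7),
            }
        )
        out = regional_summary(df)
        assert list(out["region"]) == ["a", "b"]
        assert out.loc[0, "d1_m"] == np.median(df.loc[df.region == "a", "d1_m"])

    def test_empty_input_gives_no_rows(self):
        out = regional_summary(pd.DataFrame(columns=["region", "d1_m", "d2_deg"]))
        assert len(out) == 0


def _circ_sum(bearings, m):
    d = np.abs(bearings - m) % 360
    return np.minimum(d, 360 - d).sum()
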