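import numpy as np
import pytest

from krillscape.grids import GridSpec
from krillscape.hotspots import (
    binned_hotspot_area,
    choose_neighborhood,
    cooccurrence_percent,
    correlogram,
    gi_star,
    hotspot_mask,
    morans_i,
    morans_i_moments,
    overlap_percentage,
    pooled_gi_star_by_year,
)
from krillscape.synthetic import simulate_matern_grf

from oracles import brute_gi_star, brute_morans_i


def rook_weights(n_side):
    n = n_side * n_side
    w = np.zeros((n, n))
    for i in range(n_side):
        for j in range(n_side):
            a = i * n_side + j
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n_side and 0 <= jj < n_side:
                    w[a, ii * n_side + jj] = 1.0
    return w


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        vals = np.array([[1.0, -1.0], [-1.0, 1.0]]).ravel()
        assert morans_i(vals, rook_weights(2)) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        vals = rng.normal(size=25)
        w = rook_weights(5)
        assert morans_i(vals, w) == pytest.approx(brute_morans_i(vals, w), abs=1e-12)

    def test_permutation_null_expectation(self, rng):
        n_side = 15
        vals = rng.normal(size=n_side * n_side)
        w = rook_weights(n_side)
        perms = np.array([morans_i(rng.permutation(vals), w) for _ in range(1000)])
        e_i = -1.0 / (vals.size - 1)
        se = perms.std(ddof=1) / np.sqrt(len(perms))
        assert abs(perms.mean() - e_i) < 3 * se

    def test_constant_field_raises(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(9), rook_weights(3))

    def test_null_moments_expectation(self):
        e_i, sd_i = morans_i_moments(rook_weights(4))
        assert e_i == pytest.approx(-1.0 / 15)
        assert sd_i > 0


class TestCorrelogram:
    def test_neighborhood_brackets_known_range(self):
        grid = GridSpec(0, 0, 3.0, 40, 40)
        coords = grid.cell_centers()
        bins = [0, 15, 30, 45, 60, 75, 90]
        chosen = []
        for seed in range(8):
            f = simulate_matern_grf(grid, 30.0, 1.0, seed=seed)
            rows = correlogram(f.values.ravel(), coords, bins)
            chosen.append(choose_neighborhood(rows))
        assert all(15 <= c <= 60 for c in chosen)

    def test_white_noise_first_band(self, rng):
        coords = GridSpec(0, 0, 1.0, 20, 20).cell_centers()
        rows = correlogram(rng.normal(size=400), coords, [0, 3, 6, 9])
        with pytest.warns(UserWarning):
            assert choose_neighborhood(rows) == pytest.approx(3.0)

    def test_smooth_field_decay_monotone_start(self):
        grid = GridSpec(0, 0, 2.0, 30, 30)
        f = simulate_matern_grf(grid, 40.0, 1.0, seed=5)
        rows = correlogram(f.values.ravel(), grid.cell_centers(), [0, 8, 16, 24, 32])
        i_vals = [r["i"] for r in rows[:3]]
        assert i_vals[0] >= i_vals[1] >= i_vals[2]

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            correlogram(np.arange(9.0), np.zeros((9, 2)), [5, 1])


class TestGiStar:
    def test_oracle_equivalence_random_fields(self, rng, small_grid):
        coords = small_grid.cell_centers()
        for _ in range(5):
            vals = rng.normal(size=400)
            z = gi_star(vals, coords, 2.5).z.ravel()
            np.testing.assert_allclose(z, brute_gi_star(vals, coords, 2.5), atol=1e-10)

    def test_planted_block_peaks_at_center(self, small_grid):
        vals = np.zeros((20, 20))
        vals[8:13, 8:13] = 5.0
        vals += 0.001 * np.arange(400).reshape(20, 20) / 400  # break ties
        z = gi_star(vals.ravel(), small_grid.cell_centers(), 3.0).z
        peak = np.unravel_index(np.argmax(z), (20, 20))
        assert peak == (10, 10)

    def test_scale_invariance(self, rng, small_grid):
        coords = small_grid.cell_centers()
        vals = rng.normal(size=400) + 5
        z1 = gi_star(vals, coords, 2.5).z
        z2 = gi_star(vals * 37.5, coords, 2.5).z
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_constant_data_raises(self, small_grid):
        with pytest.raises(ValueError):
            gi_star(np.ones(400), small_grid.cell_centers(), 2.5)

    def test_missing_values_get_nan(self, rng, small_grid):
        vals = rng.normal(size=400)
        vals[7] = np.nan
        z = gi_star(vals, small_grid.cell_centers(), 2.5).z
        assert np.isnan(z[7]) and np.isfinite(np.delete(z, 7)).all()


class TestPooledGiStar:
    def test_identical_years_identical_z(self, rng, small_grid):
        coords = small_grid.cell_centers()
        vals = rng.normal(size=400)
        zs = pooled_gi_star_by_year({2017: vals, 2018: vals.copy()}, coords, 2.5)
        np.testing.assert_allclose(zs[2017].z, zs[2018].z, atol=1e-12)

    def test_hot_year_dominates(self, rng, small_grid):
        coords = small_grid.cell_centers()
        base = rng.normal(size=400)
        hot = base + 0.0
        hot[:50] += 10.0
        zs = pooled_gi_star_by_year({2017: base, 2018: hot}, coords, 2.5)
        assert np.nanmax(zs[2018].z) > np.nanmax(zs[2017].z)

    def test_pooled_differs_from_per_year(self, rng, small_grid):
        coords = small_grid.cell_centers()
        y1 = rng.normal(0, 1, 400)
        y2 = rng.normal(0, 5, 400)
        pooled = pooled_gi_star_by_year({1: y1, 2: y2}, coords, 2.5)
        solo = gi_star(y2, coords, 2.5)
        assert not np.allclose(pooled[2].z, solo.z)

    def test_single_year_warns(self, rng, small_grid):
        with pytest.warns(UserWarning):
            pooled_gi_star_by_year({2018: rng.normal(size=400)}, small_grid.cell_centers(), 2.5)


class TestHotspotMask:
    def test_exact_count_on_distinct_values(self, rng):
        z = rng.permutation(np.linspace(-3, 3, 1000))
        m = hotspot_mask(z, 0.90)
        assert m.cells.sum() == 100

    def test_ceiling_rule_various_sizes(self, rng):
        for n in (10, 11, 15, 20, 57, 333):
            z = rng.permutation(np.arange(n, dtype=float))
            assert hotspot_mask(z, 0.90).cells.sum() == int(np.ceil(0.1 * n))

    def test_all_ties_flag_everything(self):
        with pytest.warns(UserWarning):
            m = hotspot_mask(np.ones(50), 0.90)
        assert m.cells.all()

    def test_area_on_3km_grid(self, rng):
        m = hotspot_mask(rng.normal(size=200), 0.90, cell_km=3.0)
        assert m.area_km2 == m.cells.sum() * 9

    def test_monotone_in_percentile(self, rng):
        z = rng.normal(size=500)
        m90 = hotspot_mask(z, 0.90).cells
        m95 = hotspot_mask(z, 0.95).cells
        assert (m95 <= m90).all()

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            hotspot_mask(np.arange(5.0), 0.90)


class TestOverlap:
    def test_identical_masks_100(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert overlap_percentage(m, m.copy()).pct_overlap == pytest.approx(100.0)

    def test_disjoint_masks_0(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert overlap_percentage(a, b).pct_overlap == 0.0

    def test_constructed_25_percent(self):
        a = np.zeros(300, bool)
        b = np.zeros(300, bool)
        a[:100] = True
        b[60:160] = True  # |A|=|B|=100, |A∩B|=40, union=160
        rep = overlap_percentage(a, b)
        assert rep.pct_overlap == pytest.approx(25.0)
        assert rep.area_both == 40 and rep.area_a_only == 60 and rep.area_b_only == 60

    def test_symmetry_and_additivity(self, rng):
        a = rng.random((12, 12)) < 0.3
        b = rng.random((12, 12)) < 0.3
        r1 = overlap_percentage(a, b)
        r2 = overlap_percentage(b, a)
        assert r1.pct_overlap == pytest.approx(r2.pct_overlap)
        union = (a | b).sum()
        assert r1.area_a_only + r1.area_b_only + r1.area_both == union

    def test_empty_masks_warn_zero(self):
        with pytest.warns(UserWarning):
            rep = overlap_percentage(np.zeros((5, 5), bool), np.zeros((5, 5), bool))
        assert rep.pct_overlap == 0.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            overlap_percentage(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestCooccurrence:
    def test_all_eight_hot_is_100(self):
        masks = [np.ones((4, 4), bool) for _ in range(8)]
        assert cooccurrence_percent(masks)[0, 0] == 100.0

    def test_six_of_eight_is_75(self):
        masks = [np.ones((2, 2), bool)] * 6 + [np.zeros((2, 2), bool)] * 2
        assert cooccurrence_percent(masks)[0, 0] == pytest.approx(75.0)

    def test_none_hot_is_0(self):
        masks = [np.zeros((3, 3), bool) for _ in range(4)]
        assert (cooccurrence_percent(masks) == 0).all()

    def test_species_order_invariant(self, rng):
        masks = [rng.random((6, 6)) < 0.4 for _ in range(5)]
        a = cooccurrence_percent(masks)
        b = cooccurrence_percent(masks[::-1])
        np.testing.assert_array_equal(a, b)

    def test_surveyed_restriction(self):
        masks = [np.ones((2, 2), bool)] * 2
        surveyed = [np.array([[True, False], [True, True]])] * 2
        pct = cooccurrence_percent(masks, surveyed)
        assert np.isnan(pct[0, 1]) and pct[0, 0] == 100.0

    def test_empty_list(self):
        with pytest.raises(ValueError):
            cooccurrence_percent([])


class TestBinnedArea:
    def test_single_bin_holds_everything(self):
        grid = GridSpec(0, 0, 1.0, 10, 10)
        y = grid.cell_centers()[:, 1]
        mask = np.zeros(100, bool)
        mask[:30] = True
        out = binned_hotspot_area(mask, y, cell_km=1.0, northing_bin_km=100.0)
        assert out["area_km2"][0] == 30.0 and out["area_km2"][1:].sum() == 0

    def test_partition_conservation_random_masks(self, rng):
        grid = GridSpec(0, 5400, 3.0, 20, 40)  # UTM-style northings
        y = grid.cell_centers()[:, 1]
        for _ in range(100):
            mask = rng.random(800) < 0.15
            out = binned_hotspot_area(mask, y, cell_km=3.0, northing_bin_km=100.0)
            assert out["area_km2"].sum() == pytest.approx(mask.sum() * 9.0)

    def test_north_south_mismatch_scenario(self):
        # prey in northern bins, predator in southern bins: no co-occurrence anywhere
        grid = GridSpec(0, 5300, 3.0, 20, 100)
        y = grid.cell_centers()[:, 1]
        prey = (y > 5500).reshape(100, 20)
        predator = (y < 5450).reshape(100, 20)
        rep = overlap_percentage(prey, predator)
        assert rep.pct_overlap < 10.0
        out = binned_hotspot_area(prey, y, cell_km=3.0, comask=predator)
        assert (out["co_area_km2"] == 0).all()
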