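import numpy as np
import pytest

from islandsdm import synth
from islandsdm.esm import (
    BlockCV,
    assign_blocks,
    count_eligible_cells,
    fit_esm,
    generate_pseudo_absences,
    median_autocorrelation_range,
    null_model_test,
)
from islandsdm.grid import LayerStack, RasterGrid, haversine_km

FAST_RF = {"n_estimators": 25, "min_samples_leaf": 5}


@pytest.fixture
def land_grid():
    return RasterGrid(np.ones((40, 40)), west=24.0, north=38.0, cell_km=1.0)


class TestPseudoAbsences:
    def test_min_distance_contract_by_bruteforce(self, land_grid):
        rng = np.random.default_rng(0)
        pres = np.column_stack([24.0 + rng.random(10) * 0.3, 37.7 + rng.random(10) * 0.25])
        sets = generate_pseudo_absences("sp", pres, land_grid, min_dist=5.5, n_sets=3, n_per_set=50, seed=1)
        assert len(sets) == 3
        for s in sets:
            for plon, plat in pres:
                d = haversine_km(s.points[:, 0], s.points[:, 1], plon, plat)
                assert np.all(d >= 5.5)

    def test_zero_min_dist_excludes_only_presence_cells(self, land_grid):
        lon, lat = land_grid.cell_center(np.array([10, 20]), np.array([10, 20]))
        pres = np.column_stack([lon, lat])
        assert count_eligible_cells(pres, land_grid, min_dist=0.0) == 40 * 40 - 2

    def test_isolated_presence_blocks_whole_island(self):
        # two islands; a presence at the small island's center with a large
        # min_dist leaves only the far island eligible
        data = np.zeros((40, 40))
        data[5:10, 5:10] = 1.0  # small island, ~5 km across
        data[25:38, 25:38] = 1.0
        grid = RasterGrid(data, west=24.0, north=38.0, cell_km=1.0)
        lon, lat = grid.cell_center(np.array([7]), np.array([7]))
        sets = generate_pseudo_absences("sp", np.column_stack([lon, lat]), grid, min_dist=8.0, n_sets=1, n_per_set=50, seed=0)
        rows, cols, _ = grid.index_of(sets[0].points[:, 0], sets[0].points[:, 1])
        assert np.all(rows >= 25) and np.all(cols >= 25)

    def test_insufficient_eligible_cells_rejected(self, land_grid):
        lon, lat = land_grid.cell_center(np.array([20]), np.array([20]))
        with pytest.raises(ValueError, match="reduce min_dist"):
            generate_pseudo_absences("sp", np.column_stack([lon, lat]), land_grid, min_dist=60.0, n_sets=1, n_per_set=10, seed=0)


class TestAutocorrelationRange:
    def test_white_noise_range_small(self):
        rng = np.random.default_rng(0)
        g = RasterGrid(rng.normal(size=(80, 80)), west=24.0, north=38.0, cell_km=1.0)
        r = median_autocorrelation_range(LayerStack({"wn": g}), seed=0)
        assert r <= 2.0

    def test_correlated_field_range_brackets_known_length(self):
        rng = np.random.default_rng(1)
        L = 8.0  # cells = km
        fld = synth.gaussian_random_field((100, 100), L, rng)
        g = RasterGrid(fld, west=24.0, north=38.0, cell_km=1.0)
        r = median_autocorrelation_range(LayerStack({"grf": g}), seed=0)
        assert 0.5 * L <= r <= 3.0 * L

    def test_flat_layer_skipped(self):
        rng = np.random.default_rng(2)
        flat = RasterGrid(np.ones((50, 50)), west=24.0, north=38.0, cell_km=1.0)
        noisy = RasterGrid(rng.normal(size=(50, 50)), west=24.0, north=38.0, cell_km=1.0)
        r = median_autocorrelation_range(LayerStack({"flat": flat, "wn": noisy}), seed=0)
        assert np.isfinite(r)
        with pytest.raises(ValueError):
            median_autocorrelation_range(LayerStack({"flat": flat}), seed=0)


class TestBlockCV:
    def test_same_block_never_split_and_deterministic(self, land_grid):
        rng = np.random.default_rng(0)
        pts = np.column_stack([24.0 + rng.random(200) * 0.4, 37.7 + rng.random(200) * 0.3])
        cv = assign_blocks(pts, land_grid, block_size=8.0, n_folds=5, seed=3)
        for b in np.unique(cv.block_of_point):
            assert np.unique(cv.assignment[cv.block_of_point == b]).size == 1
        cv2 = assign_blocks(pts, land_grid, block_size=8.0, n_folds=5, seed=3)
        np.testing.assert_array_equal(cv.assignment, cv2.assignment)

    def test_balanced_deal_of_equal_blocks(self, land_grid):
        # 25 blocks in a 5x5 lattice, 4 points each -> each fold gets 5 blocks
        xs, ys = np.meshgrid(np.arange(5), np.arange(5))
        pts, labels = [], []
        for bx, by in zip(xs.ravel(), ys.ravel()):
            for k in range(4):
                lon = 24.0 + (bx * 8.0 + 2.0 + k) / (111.195 * np.cos(np.radians(land_grid.ref_lat)))
                lat = 38.0 - (by * 8.0 + 2.0 + k) / 111.195
                pts.append((lon, lat))
                labels.append(1.0)
        cv = assign_blocks(np.array(pts), land_grid, block_size=8.0, n_folds=5, seed=0)
        counts = np.bincount(cv.assignment, minlength=5)
        assert counts.tolist() == [20] * 5

    def test_single_block_rejected(self, land_grid):
        pts = np.array([[24.01, 37.99], [24.011, 37.989]])
        with pytest.raises(ValueError):
            assign_blocks(pts, land_grid, block_size=500.0, n_folds=5, seed=0)

    def test_no_leakage_between_folds(self, land_grid):
        rng = np.random.default_rng(5)
        pts = np.column_stack([24.0 + rng.random(150) * 0.4, 37.7 + rng.random(150) * 0.3])
        cv = assign_blocks(pts, land_grid, block_size=10.0, n_folds=4, seed=1)
        for f, test in cv.folds():
            test_blocks = set(cv.block_of_point[test])
            train_blocks = set(cv.block_of_point[~test])
            assert not (test_blocks & train_blocks)


def _toy_training_stack(seed=0, shape=(60, 60)):
    rng = np.random.default_rng(seed)
    grid = RasterGrid(np.zeros(shape), west=24.0, north=38.0, cell_km=1.0)
    signal = synth.gaussian_random_field(shape, 6.0, rng)
    noise = synth.gaussian_random_field(shape, 6.0, rng)
    return LayerStack({"x": grid.like(signal), "z": grid.like(noise)}), grid


class TestFitEsm:
    def test_two_predictors_give_single_pair(self):
        stack, grid = _toy_training_stack()
        rng = np.random.default_rng(1)
        rows, cols = np.nonzero(stack["x"].data > 0.8)
        sel = rng.choice(rows.size, 30, replace=False)
        lon, lat = grid.cell_center(rows[sel], cols[sel])
        pres = np.column_stack([lon, lat])
        land = RasterGrid(np.ones(grid.shape), west=24.0, north=38.0, cell_km=1.0)
        pa = generate_pseudo_absences("sp", pres, land, 2.0, n_sets=2, n_per_set=100, seed=2)
        ens = fit_esm("sp", pres, pa, stack, block_size=10.0, n_folds=4, n_repeats=1, learner_params=FAST_RF, seed=3)
        assert len(ens.pairs) == 1
        assert ens.training_ranges["x"][0] <= stack["x"].data[rows[sel], cols[sel]].min()
        # the informative predictor is recoverable: skill above chance
        assert ens.ensemble_tss > 0.3

    def test_pair_count_is_n_choose_2(self):
        # 9 retained predictors -> 36 bivariate models
        from itertools import combinations

        assert len(list(combinations(range(9), 2))) == 36

    def test_ensemble_prediction_is_convex_combination(self):
        stack, grid = _toy_training_stack(seed=4)
        rng = np.random.default_rng(4)
        rows, cols = np.nonzero(stack["x"].data > 0.5)
        sel = rng.choice(rows.size, 40, replace=False)
        pres = np.column_stack(grid.cell_center(rows[sel], cols[sel]))
        land = RasterGrid(np.ones(grid.shape), west=24.0, north=38.0, cell_km=1.0)
        pa = generate_pseudo_absences("sp", pres, land, 2.0, n_sets=2, n_per_set=80, seed=5)
        ens = fit_esm("sp", pres, pa, stack, block_size=10.0, n_folds=4, n_repeats=1, learner_params=FAST_RF, seed=6)
        X = rng.random((50, 2))
        per_pair = np.column_stack([m.predict_proba(X[:, [i, j]])[:, 1] for (i, j), m in zip(ens.pair_columns(), ens.models)])
        mixed = ens.predict(X)
        active = ens.weights > 0
        assert np.all(mixed <= per_pair[:, active].max(axis=1) + 1e-12)
        assert np.all(mixed >= per_pair[:, active].min(axis=1) - 1e-12)
        # weight-scale invariance
        ens.weights = ens.weights * 7.0
        np.testing.assert_allclose(ens.predict(X), mixed, atol=1e-12)


class TestNullModelTest:
    def test_formula_bounds(self):
        assert null_model_test(-1.0, lambda rng: rng.random(), n_null=99, seed=0) == 1.0
        assert null_model_test(2.0, lambda rng: rng.random(), n_null=99, seed=0) == pytest.approx(0.01)

    def test_minimum_null_count_enforced(self):
        with pytest.raises(ValueError):
            null_model_test(0.5, lambda rng: 0.0, n_null=5, seed=0)
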