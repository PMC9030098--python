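import numpy as np
import pytest

from islandsdm import synth
from islandsdm.grid import LayerStack, RasterGrid
from islandsdm.predictors import (
    CollinearityReport,
    derive_bioclim,
    derive_envirem,
    derive_topographic,
    filter_collinear,
    heat_load_index,
)
from islandsdm.synth import ClimateSet


def climate_from_series(tmin, tmax, prec, shape=(3, 3)):
    """Spatially constant climate built from 12-month series."""
    grid = RasterGrid(np.zeros(shape), west=24.0, north=38.0, cell_km=1.0)
    mk = lambda s: np.tile(np.asarray(s, float)[:, None, None], (1,) + shape)
    return ClimateSet(tmin=mk(tmin), tmax=mk(tmax), prec=mk(prec), grid=grid)


class TestBioclim:
    def test_constant_climate(self):
        clim = climate_from_series([8] * 12, [12] * 12, [100] * 12)
        b = derive_bioclim(clim)
        c = (1, 1)
        assert b["bio1"].data[c] == 10.0
        assert b["bio4"].data[c] == 0.0
        assert b["bio7"].data[c] == b["bio5"].data[c] - b["bio6"].data[c] == 4.0
        assert b["bio12"].data[c] == 1200.0
        assert b["bio13"].data[c] == b["bio14"].data[c] == 100.0
        assert b["bio15"].data[c] == 0.0

    def test_toy_yearly_series_full_vector(self):
        # tmin 2..13, tmax 10..21, prec 10..120 -> values derived by hand
        # (wrap-around quarters: warmest/wettest = Oct-Dec, coldest/driest = Jan-Mar)
        m = np.arange(1, 13)
        b = derive_bioclim(climate_from_series(m + 1, m + 9, 10 * m))
        c = (1, 1)
        expected = {
            "bio1": 11.5,
            "bio2": 8.0,
            "bio3": 100 * 8 / 19,
            "bio4": 100 * np.sqrt(13),
            "bio5": 21.0,
            "bio6": 2.0,
            "bio7": 19.0,
            "bio8": 16.0,
            "bio9": 7.0,
            "bio10": 16.0,
            "bio11": 7.0,
            "bio12": 780.0,
            "bio13": 120.0,
            "bio14": 10.0,
            "bio15": 1000 * np.sqrt(13) / 66,
            "bio16": 330.0,
            "bio17": 60.0,
            "bio18": 330.0,
            "bio19": 60.0,
        }
        for name, val in expected.items():
            assert b[name].data[c] == pytest.approx(val, rel=1e-12), name

    def test_missing_month_rejected(self):
        clim = climate_from_series([0] * 12, [1] * 12, [1] * 12)
        clim.prec = clim.prec[:11]
        with pytest.raises(ValueError, match="prec"):
            derive_bioclim(clim)

    def test_quarter_selection_matches_bruteforce(self, small_clim):
        b = derive_bioclim(small_clim)
        tavg, prec = small_clim.tavg, small_clim.prec
        rng = np.random.default_rng(0)
        rows, cols = np.nonzero(np.isfinite(tavg).all(axis=0))
        sel = rng.choice(rows.size, 500, replace=False)
        for r, c in zip(rows[sel], cols[sel]):
            t = tavg[:, r, c]
            p = prec[:, r, c]
            qt = [np.mean([t[w], t[(w + 1) % 12], t[(w + 2) % 12]]) for w in range(12)]
            qp = [p[w] + p[(w + 1) % 12] + p[(w + 2) % 12] for w in range(12)]
            assert b["bio10"].data[r, c] == pytest.approx(max(qt), rel=1e-12)
            assert b["bio11"].data[r, c] == pytest.approx(min(qt), rel=1e-12)
            assert b["bio16"].data[r, c] == pytest.approx(max(qp), rel=1e-12)
            assert b["bio8"].data[r, c] == pytest.approx(qt[int(np.argmax(qp))], rel=1e-12)

    def test_additive_shift_property(self, small_clim):
        b0 = derive_bioclim(small_clim)
        shifted = ClimateSet(small_clim.tmin + 2.5, small_clim.tmax + 2.5, small_clim.prec, small_clim.grid)
        b1 = derive_bioclim(shifted)
        for name in ("bio1", "bio5", "bio6", "bio8", "bio9", "bio10", "bio11"):
            np.testing.assert_allclose(b1[name].data, b0[name].data + 2.5, atol=1e-9, equal_nan=True)
        for name in ("bio2", "bio4", "bio15"):
            np.testing.assert_allclose(b1[name].data, b0[name].data, atol=1e-9, equal_nan=True)


class TestEnvirem:
    def test_colder_cell_has_lower_annual_pet(self):
        warm = climate_from_series([10] * 12, [20] * 12, [50] * 12)
        cold = climate_from_series([5] * 12, [15] * 12, [50] * 12)
        pw = derive_envirem(warm)["annual_pet"].data[1, 1]
        pc = derive_envirem(cold)["annual_pet"].data[1, 1]
        assert pc < pw

    def test_pet_coldest_quarter_below_warmest(self, small_clim):
        e = derive_envirem(small_clim)
        cold = e["pet_coldest_quarter"].data
        warm = e["pet_warmest_quarter"].data
        ok = np.isfinite(cold)
        assert np.all(cold[ok] <= warm[ok] + 1e-9)

    def test_zero_precipitation_maximizes_aridity(self):
        m = np.arange(1, 13)
        dry = derive_envirem(climate_from_series(m, m + 8, [0] * 12))
        assert dry["aridity_thornthwaite"].data[1, 1] == pytest.approx(100.0)
        assert dry["climatic_moisture_index"].data[1, 1] == pytest.approx(-1.0)

    def test_latitude_out_of_range_rejected(self):
        clim = climate_from_series([0] * 12, [10] * 12, [10] * 12)
        bad_lat = clim.grid.like(np.full((3, 3), 95.0))
        with pytest.raises(ValueError):
            derive_envirem(clim, latitude=bad_lat)


class TestTopographic:
    def test_flat_dem(self):
        dem = RasterGrid(np.full((10, 10), 100.0), west=24.0, north=38.0, cell_km=1.0)
        t = derive_topographic(dem)
        inner = (slice(1, -1), slice(1, -1))
        assert np.all(t["slope"].data[inner] == 0)
        assert np.all(t["tpi"].data[inner] == 0)
        assert np.all(t["tri"].data[inner] == 0)
        assert np.isnan(t["slope"].data[0, 0])  # edges nodata

    def test_single_peak_tpi_tri(self):
        z = np.zeros((7, 7))
        z[3, 3] = 100.0
        t = derive_topographic(RasterGrid(z, west=24.0, north=38.0, cell_km=1.0))
        assert t["tpi"].data[3, 3] == pytest.approx(100.0)
        assert t["tri"].data[3, 3] == pytest.approx(100.0)

    def test_hli_matches_closed_formula(self):
        lat, slope, aspect = 40.0, 20.0, 225.0
        val = heat_load_index(lat, slope, aspect)
        lat_r, slope_r = np.radians(lat), np.radians(slope)
        fold_r = np.radians(abs(180.0 - abs(aspect - 225.0)))
        expected = np.exp(
            -1.467
            + 1.582 * np.cos(lat_r) * np.cos(slope_r)
            - 1.500 * np.cos(fold_r) * np.sin(slope_r) * np.cos(lat_r)
            - 0.262 * np.sin(lat_r) * np.sin(slope_r)
            + 0.607 * np.sin(fold_r) * np.sin(slope_r)
        )
        assert val == pytest.approx(expected, rel=1e-12)
        assert fold_r == pytest.approx(np.pi)  # aspect 225 folds to A' = 180

    def test_all_nodata_dem_rejected(self):
        with pytest.raises(ValueError):
            derive_topographic(RasterGrid(np.full((5, 5), np.nan), west=0, north=0))


class TestCollinearityFilter:
    @staticmethod
    def _stack_from_arrays(arrays):
        grid = RasterGrid(np.zeros(arrays[0].shape), west=24.0, north=38.0, cell_km=1.0)
        return LayerStack({f"L{i}": grid.like(a) for i, a in enumerate(arrays)})

    def test_exact_copy_dropped_with_rho_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(40, 50))
        rep = filter_collinear(self._stack_from_arrays([a, a.copy(), rng.normal(size=(40, 50))]), samples=1500, seed=0)
        assert len(rep.retained) == 2
        assert any("1.000" in reason for _, reason in rep.dropped)

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(1)
        arrays = [rng.normal(size=(100, 50)) for _ in range(6)]
        rep = filter_collinear(self._stack_from_arrays(arrays), samples=5000, seed=0)
        assert len(rep.retained) == 6
        assert rep.dropped == []

    def test_linear_combination_dropped_by_vif(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(100, 50))
        b = rng.normal(size=(100, 50))
        # L2 = L0 + L1 makes the triplet mutually determined: every member has
        # unbounded VIF while pairwise Spearman stays moderate; dropping any
        # one member restores independence
        rep = filter_collinear(self._stack_from_arrays([a, b, a + b]), samples=5000, seed=0)
        assert len(rep.dropped) == 1
        assert rep.dropped[0][1].startswith("VIF")
        assert len(rep.retained) == 2

    def test_zero_variance_layer_dropped(self):
        rng = np.random.default_rng(3)
        rep = filter_collinear(
            self._stack_from_arrays([rng.normal(size=(40, 50)), np.ones((40, 50)), rng.normal(size=(40, 50))]),
            samples=1000,
            seed=0,
        )
        assert ("L1", "zero variance") in rep.dropped

    def test_report_is_self_verifying(self, small_env):
        from scipy import stats as sps

        rep = filter_collinear(small_env, samples=3000, seed=0)
        assert sorted(rep.retained + [n for n, _ in rep.dropped]) == sorted(small_env.names)
        rows, cols, X = small_env.subset(rep.retained).to_matrix()
        rng = np.random.default_rng(0)
        sel = rng.choice(rows.size, 3000, replace=False)
        rho = np.abs(sps.spearmanr(X[sel]).statistic)
        np.fill_diagonal(rho, 0.0)
        assert rho.max() < rep.rho_max + 0.03  # sampling noise margin
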