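import numpy as np
import pytest

from islandsdm.grid import LayerStack, RasterGrid
from islandsdm.projection import (
    BinaryRangeMap,
    binarize,
    clamp,
    exdet,
    niche_truncation_index,
    range_change,
)
from islandsdm.scenario import BASELINE


def grid_of(data):
    return RasterGrid(np.asarray(data, float), west=24.0, north=38.0, cell_km=1.0)


class FakePairModel:
    """Minimal predict_proba stand-in returning a fixed column."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, float)

    def predict_proba(self, X):
        p = self.probs[: X.shape[0]]
        return np.column_stack([1 - p, p])


def make_fake_ensemble(names, pairs, probs_list, weights, ranges):
    from islandsdm.esm import EsmEnsemble

    return EsmEnsemble(
        species="fake",
        predictor_names=list(names),
        pairs=pairs,
        models=[FakePairModel(p) for p in probs_list],
        weights=np.asarray(weights, float),
        training_ranges=ranges,
        ensemble_tss=1.0,
        threshold=0.5,
        eval_report=None,
        n_presences=10,
    )


class TestProjectAndClamp:
    def _stack(self, shape=(4, 4)):
        rng = np.random.default_rng(0)
        g = grid_of(np.zeros(shape))
        return LayerStack({"a": g.like(rng.random(shape)), "b": g.like(rng.random(shape))})

    def test_single_pair_projection_equals_model_probability(self):
        from islandsdm.projection import project

        stack = self._stack()
        n = 16
        ens = make_fake_ensemble(["a", "b"], [("a", "b")], [np.linspace(0, 1, n)], [0.7], {"a": (0, 1), "b": (0, 1)})
        out = project(ens, stack)
        np.testing.assert_allclose(out.data.ravel(), np.linspace(0, 1, n))

    def test_equal_weights_average_two_pairs(self):
        from islandsdm.projection import project

        stack = self._stack()
        n = 16
        p1, p2 = np.zeros(n), np.ones(n)
        ens = make_fake_ensemble(["a", "b"], [("a", "b"), ("a", "b")], [p1, p2], [0.5, 0.5], {"a": (0, 1), "b": (0, 1)})
        np.testing.assert_allclose(project(ens, stack).data.ravel(), 0.5)

    def test_missing_predictor_named_in_error(self):
        from islandsdm.projection import project

        stack = LayerStack({"a": grid_of(np.zeros((3, 3)))})
        ens = make_fake_ensemble(["a", "q"], [("a", "q")], [np.zeros(9)], [1.0], {"a": (0, 1), "q": (0, 1)})
        with pytest.raises(KeyError, match="q"):
            project(ens, stack)

    def test_clamp_identity_on_training_range(self):
        stack = self._stack()
        suit = stack.template.like(np.full((4, 4), 0.6))
        ens = make_fake_ensemble(["a", "b"], [("a", "b")], [np.zeros(16)], [1.0], {"a": (-1, 2), "b": (-1, 2)})
        clamped, mask = clamp(ens, stack, suit)
        np.testing.assert_array_equal(clamped.data, suit.data)
        assert np.nansum(mask.data) == 0

    def test_clamp_nullifies_exactly_the_offending_cells(self):
        g = grid_of(np.zeros((3, 3)))
        a = np.full((3, 3), 0.5)
        a[0, :2] = 5.0  # outside training max in exactly 2 cells
        stack = LayerStack({"a": g.like(a), "b": g.like(np.full((3, 3), 0.5))})
        suit = g.like(np.full((3, 3), 0.9))
        ens = make_fake_ensemble(["a", "b"], [("a", "b")], [np.zeros(9)], [1.0], {"a": (0, 1), "b": (0, 1)})
        clamped, mask = clamp(ens, stack, suit)
        assert mask.data[0, 0] == 1 and mask.data[0, 1] == 1
        assert np.nansum(mask.data) == 2
        assert clamped.data[0, 0] == 0 and clamped.data[2, 2] == 0.9
        assert np.nanmax(mask.data) <= len(ens.predictor_names)
        assert np.all(clamped.data <= suit.data)

    def test_binarize_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        suit = grid_of(rng.random((10, 10)))
        low = binarize(suit, 0.3, "sp")
        high = binarize(suit, 0.6, "sp")
        assert high.cells <= low.cells
        assert np.all((high.presence.data == 1) <= (low.presence.data == 1))


class TestExdet:
    def test_reference_mean_is_perfectly_analogue(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(200, 4))
        rep = exdet(ref, ref.mean(axis=0, keepdims=True))
        assert rep.nt1[0] == 0.0
        assert rep.nt2[0] == pytest.approx(0.0, abs=1e-12)

    def test_projection_equal_reference_is_fully_analogue(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(300, 5))
        rep = exdet(ref, ref)
        assert rep.analogue_fraction == 100.0

    def test_ten_percent_below_range_gives_nt1_minus_point_one(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(0, 1, size=(500, 3))
        lo, hi = ref.min(axis=0), ref.max(axis=0)
        x = ref.mean(axis=0).copy()
        x[0] = lo[0] - 0.1 * (hi[0] - lo[0])
        rep = exdet(ref, x[None, :])
        assert rep.nt1[0] == pytest.approx(-0.1, abs=1e-9)

    def test_combined_field_matches_literal_reference_implementation(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(400, 5)) @ rng.normal(size=(5, 5)) + rng.normal(size=5)
        proj = rng.normal(size=(1000, 5)) @ rng.normal(size=(5, 5)) * 1.5
        rep = exdet(ref, proj)
        lo, hi = ref.min(axis=0), ref.max(axis=0)
        mean = ref.mean(axis=0)
        cov_inv = np.linalg.inv(np.cov(ref.T))
        d2_max = max(float((r - mean) @ cov_inv @ (r - mean)) for r in ref)
        for i in range(proj.shape[0]):
            x = proj[i]
            nt1 = sum(min(x[j] - lo[j], hi[j] - x[j], 0.0) / (hi[j] - lo[j]) for j in range(5))
            if nt1 < 0:
                expected = nt1
            else:
                expected = float((x - mean) @ cov_inv @ (x - mean)) / d2_max
            assert rep.exdet[i] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_pct_nearby_full_for_identical_sets(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(150, 3))
        rep = exdet(ref, ref.copy())
        assert np.all(rep.pct_nearby > 0)

    def test_singular_covariance_rejected(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=(100, 1))
        ref = np.hstack([col, col])
        with pytest.raises(ValueError):
            exdet(ref, ref)


class TestNicheTruncation:
    def test_identical_samples_give_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(400, 3))
        assert niche_truncation_index(x, x.copy()) < 0.05

    def test_disjoint_clusters_give_near_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(300, 3))
        b = rng.normal(size=(300, 3)) + 20.0
        assert niche_truncation_index(a, b) > 0.9

    def test_half_overlapping_uniform_densities(self):
        rng = np.random.default_rng(2)
        a = np.column_stack([rng.uniform(0, 1, 4000), rng.uniform(0, 1, 4000)])
        b = np.column_stack([rng.uniform(0.5, 1.5, 4000), rng.uniform(0, 1, 4000)])
        idx = niche_truncation_index(a, b, grid_bins=80)
        assert idx == pytest.approx(0.5, abs=0.08)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            niche_truncation_index(np.ones((20, 2)), np.ones((20, 2)))
        with pytest.raises(ValueError):
            niche_truncation_index(np.random.rand(5, 2), np.random.rand(50, 2))


class TestRangeChange:
    @staticmethod
    def _maps(cur, fut):
        g1 = grid_of(cur)
        g2 = grid_of(fut)
        return (
            BinaryRangeMap(g1, "sp", BASELINE, 0.5),
            BinaryRangeMap(g2, "sp", BASELINE, 0.5),
        )

    def test_identical_maps_no_change(self):
        arr = np.zeros((6, 6))
        arr[2:4, 2:4] = 1
        cur, fut = self._maps(arr, arr.copy())
        rc = range_change(cur, fut, "full")
        assert (rc.loss_cells, rc.gain_cells, rc.change_pct) == (0, 0, 0.0)

    def test_total_loss_is_minus_hundred(self):
        arr = np.zeros((6, 6))
        arr[1:3, 1:3] = 1
        cur, fut = self._maps(arr, np.zeros((6, 6)))
        assert range_change(cur, fut, "none").change_pct == -100.0

    def test_buffered_gain_arithmetic(self):
        # 100-cell range keeps 40 cells and gains 20 adjacent ones: -40%
        cur_arr = np.zeros((30, 30))
        cur_arr[0:10, 0:10] = 1
        fut_arr = np.zeros((30, 30))
        fut_arr[0:10, 0:4] = 1  # keeps 40
        fut_arr[0:10, 10:12] = 1  # gains 20 within 2 cells of current range
        cur, fut = self._maps(cur_arr, fut_arr)
        rc = range_change(cur, fut, "buffered", buffer_km=2.0)
        assert rc.stable_cells == 40 and rc.gain_cells == 20 and rc.loss_cells == 60
        assert rc.change_pct == pytest.approx(-40.0)

    def test_no_dispersal_blocks_all_gains(self):
        cur_arr = np.zeros((10, 10))
        cur_arr[0, 0] = 1
        fut_arr = np.zeros((10, 10))
        fut_arr[0, 0] = 1
        fut_arr[9, 9] = 1
        cur, fut = self._maps(cur_arr, fut_arr)
        assert range_change(cur, fut, "none").gain_cells == 0
        assert range_change(cur, fut, "full").gain_cells == 1
        assert range_change(cur, fut, "buffered", buffer_km=2.0).gain_cells == 0

    def test_empty_current_range_flagged(self):
        cur, fut = self._maps(np.zeros((5, 5)), np.ones((5, 5)))
        rc = range_change(cur, fut, "full")
        assert rc.flagged_empty and np.isnan(rc.change_pct)
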