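import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retoct.bscan import BScan
from retoct.phantom import PhantomParams, make_profile, render_bscan
from retoct.segmentation import (DEFAULT_VARIANTS, DEGENERATIVE_SCHEMA,
                                 NORMAL_SCHEMA, CostMap, Segmentation,
                                 SegmentationError, boundary_cost, dice_score,
                                 ensemble_median, segment,
                                 shortest_path_boundary, usage_rate)

from conftest import boundary_errors


def enumerate_min_cost(costs, max_step, row_band=None):
    """Brute-force oracle: minimum path cost by exhaustive enumeration."""
    n_rows, n_cols = costs.shape
    lo, hi = (0, n_rows - 1) if row_band is None else row_band
    rows = range(lo, hi + 1)
    best = np.inf
    for path in itertools.product(rows, repeat=n_cols):
        if any(abs(path[j + 1] - path[j]) > max_step for j in range(n_cols - 1)):
            continue
        best = min(best, sum(costs[r, j] for j, r in enumerate(path)))
    return best


class TestBoundaryCost:
    def _step_image(self, row=12, lo=10.0, hi=200.0, shape=(30, 8)):
        img = np.full(shape, lo)
        img[row:, :] = hi
        return BScan(data=img)

    def test_hard_step_cost_minimum_at_transition_row(self):
        cm = boundary_cost(self._step_image(), "dark-to-bright",
                           smoothing_sigma=0)
        assert np.all(np.argmin(cm.costs, axis=0) == 12)

    def test_inverted_polarity_no_minimum_at_step(self):
        cm = boundary_cost(self._step_image(), "bright-to-dark",
                           smoothing_sigma=0)
        # the step is the unique cost MAXIMUM for the wrong polarity
        assert np.all(np.argmax(cm.costs, axis=0) == 12)
        assert cm.costs.min() >= 0 and cm.costs.max() <= 1

    def test_smoothed_step_argmin_invariant(self):
        cm = boundary_cost(self._step_image(), "dark-to-bright",
                           smoothing_sigma=2.0)
        # brute-force per-column argmin stays at the step row
        for c in range(cm.costs.shape[1]):
            assert int(np.argmin(cm.costs[:, c])) == 12

    def test_constant_image_uniform_cost(self):
        cm = boundary_cost(BScan(data=np.full((20, 5), 3.0)), "dark-to-bright")
        assert np.allclose(cm.costs, cm.costs[0, 0])

    def test_costs_normalized(self):
        rng = np.random.default_rng(0)
        cm = boundary_cost(BScan(data=rng.uniform(1, 9, (40, 12))),
                           "dark-to-bright")
        assert cm.costs.min() >= 0.0 and cm.costs.max() <= 1.0


class TestShortestPath:
    def test_zero_cost_row_followed(self):
        costs = np.ones((20, 9))
        costs[12, :] = 0.0
        path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                      max_step=1)
        assert np.all(path == 12)

    def test_3x3_grid_against_enumeration(self):
        costs = np.array([[1, 9, 1], [9, 1, 9], [1, 9, 1]], dtype=float)
        path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                      max_step=1)
        assert list(path) == [0, 1, 0]
        total = costs[path, np.arange(3)].sum()
        assert total == 3.0
        assert total == enumerate_min_cost(costs, max_step=1)

    def test_max_step_zero_reduces_to_row_argmin(self):
        rng = np.random.default_rng(1)
        costs = rng.uniform(size=(10, 7))
        path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                      max_step=0)
        assert len(set(path)) == 1
        assert path[0] == int(np.argmin(costs.sum(axis=1)))

    def test_infeasible_band_raises(self):
        costs = np.ones((5, 5))
        with pytest.raises(ValueError):
            shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                   row_band=(4, 2))

    def test_band_respected(self):
        costs = np.ones((10, 6))
        costs[0, :] = 0.0  # attractive but outside the band
        path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                      row_band=(3, 8), max_step=2)
        assert path.min() >= 3 and path.max() <= 8

    @pytest.mark.parametrize("max_step", [0, 1, 2])
    def test_exactness_random_grids(self, max_step):
        rng = np.random.default_rng(42 + max_step)
        for _ in range(60):
            n_rows = rng.integers(2, 7)
            n_cols = rng.integers(2, 7)
            costs = rng.uniform(0, 1, size=(n_rows, n_cols))
            path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                          max_step=max_step)
            total = costs[path, np.arange(n_cols)].sum()
            assert total == pytest.approx(
                enumerate_min_cost(costs, max_step), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 2))
    def test_exactness_property(self, seed, max_step):
        rng = np.random.default_rng(seed)
        costs = rng.uniform(0, 1, size=(rng.integers(2, 7), rng.integers(2, 7)))
        path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                      max_step=max_step)
        steps = np.abs(np.diff(path))
        assert steps.size == 0 or steps.max() <= max_step
        total = costs[path, np.arange(costs.shape[1])].sum()
        assert total == pytest.approx(
            enumerate_min_cost(costs, max_step), abs=1e-12)

    def test_tie_break_toward_smaller_row(self):
        costs = np.zeros((4, 5))  # everything ties
        path = shortest_path_boundary(CostMap(costs, "dark-to-bright"),
                                      max_step=2)
        assert np.all(path == 0)


class TestSchemas:
    def test_normal_counts(self):
        assert NORMAL_SCHEMA.n_boundaries == 9
        assert NORMAL_SCHEMA.n_layers == 8

    def test_degenerative_counts(self):
        assert DEGENERATIVE_SCHEMA.n_boundaries == 8
        assert DEGENERATIVE_SCHEMA.n_layers == 7


class TestSegment:
    def test_noise_free_phantom_all_variants_within_half_pixel_rms(
            self, day0_noise_free):
        bscan, truth = day0_noise_free
        for variant in DEFAULT_VARIANTS:
            seg = segment(bscan, "normal", variant)
            for err in boundary_errors(seg, truth):
                assert np.sqrt((err**2).mean()) < 0.5

    def test_degenerative_schema_boundary_count(self, model):
        params = PhantomParams(speckle_shape=None)
        bscan, _ = render_bscan(make_profile(params, model, 20.0), params, seed=2)
        seg = segment(bscan, "degenerative")
        assert seg.boundaries.shape[0] == 8

    def test_all_zero_image_fails_loudly(self):
        with pytest.raises(SegmentationError):
            segment(BScan(data=np.zeros((512, 100))), "normal")

    def test_pure_noise_image_fails_loudly(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SegmentationError):
            segment(BScan(data=rng.uniform(39, 41, (512, 200))), "normal")

    def test_short_image_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SegmentationError):
            segment(BScan(data=rng.uniform(0, 1, (40, 100))), "normal")

    def test_ordering_invariant(self, day0_segmentation):
        assert day0_segmentation.check_ordering()

    def test_ordering_under_speckle(self, day0_speckled):
        bscan, _ = day0_speckled
        for variant in DEFAULT_VARIANTS[:2]:
            assert segment(bscan, "normal", variant).check_ordering()

    def test_recovery_under_default_noise(self, model):
        """Boundary MAE <= 1 px (choroid/sclera <= 2 px) over 20 seeds."""
        params = PhantomParams()
        errs = []
        for seed in range(20):
            day = [0.0, 3.0, 20.0][seed % 3]
            schema = "normal" if day < model.merge_day else "degenerative"
            bscan, truth = render_bscan(make_profile(params, model, day),
                                        params, seed=seed)
            seg = segment(bscan, schema)
            for name, err in zip(seg.schema.boundary_names,
                                 boundary_errors(seg, truth)):
                errs.append((name, np.abs(err).mean()))
        for name, mae in errs:
            limit = 2.0 if name == "choroid/sclera" else 1.0
            assert mae <= limit, (name, mae)


class TestEnsemble:
    def _seg(self, rows, width=6, schema=NORMAL_SCHEMA, valid=None):
        b = np.cumsum(np.ones((schema.n_boundaries, width)), axis=0) * 20
        b[0, :] = rows
        b = np.sort(b, axis=0)
        return Segmentation(schema=schema, boundaries=b, valid_mask=valid)

    def test_odd_count_median(self):
        segs = [self._seg(r) for r in (10, 12, 14)]
        out = ensemble_median(segs)
        assert np.all(out.boundaries[0] == 12)

    def test_even_count_mean_of_central(self):
        segs = [self._seg(r) for r in (10, 20)]
        out = ensemble_median(segs)
        assert np.all(out.boundaries[0] == 15)

    def test_idempotent_on_identical_inputs(self):
        segs = [self._seg(11) for _ in range(3)]
        out = ensemble_median(segs)
        np.testing.assert_array_equal(out.boundaries, segs[0].boundaries)

    def test_valid_mask_is_and(self):
        v1 = np.array([True, True, False, True, True, True])
        v2 = np.array([True, True, True, False, True, True])
        out = ensemble_median([self._seg(10, valid=v1), self._seg(10, valid=v2)])
        np.testing.assert_array_equal(out.valid_mask, v1 & v2)

    def test_mixed_schema_rejected(self):
        a = self._seg(10)
        b_bounds = np.cumsum(np.ones((8, 6)), axis=0) * 20
        b = Segmentation(schema=DEGENERATIVE_SCHEMA, boundaries=b_bounds)
        with pytest.raises(ValueError):
            ensemble_median([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_median([])

    def test_robust_to_one_corrupted_variant(self, day0_noise_free):
        """Median ensemble with one +10 px corrupted variant is no worse
        than the median of the best 3 variants' RMS."""
        bscan, truth = day0_noise_free
        segs = [segment(bscan, "normal", v) for v in DEFAULT_VARIANTS]

        def rms(seg):
            return float(np.sqrt(np.mean(
                np.square(boundary_errors(seg, truth)))))

        corrupted = Segmentation(schema=segs[0].schema,
                                 boundaries=segs[0].boundaries + 10.0,
                                 valid_mask=segs[0].valid_mask)
        ens = ensemble_median(segs[1:] + [corrupted])
        best3 = float(np.median(sorted(rms(s) for s in segs)[:3]))
        assert rms(ens) <= max(best3, 0.5)


class TestDice:
    def _flat_seg(self, offsets, width=10):
        b = np.tile(np.asarray(offsets, float)[:, None], (1, width))
        return Segmentation(schema=NORMAL_SCHEMA, boundaries=b)

    def test_identical_is_one(self, day0_segmentation):
        for layer in NORMAL_SCHEMA.layer_names:
            assert dice_score(day0_segmentation, day0_segmentation,
                              layer, 512) == 1.0

    def test_disjoint_is_zero(self):
        base = np.arange(9) * 10.0
        a = self._flat_seg(base)
        b = self._flat_seg(base + 200.0)
        assert dice_score(a, b, "NFL", 512) == 0.0

    def test_hand_counted_overlap(self):
        # layer NFL: a spans rows (0,4] (4 px), b spans (1,7] (6 px);
        # overlap rows (1,4] = 3 px -> dice = 2*3/(4+6) = 0.6
        base = np.arange(9) * 30.0 + 30.0
        a = self._flat_seg(np.concatenate([[0.0, 4.0], base[2:]]), width=1)
        b = self._flat_seg(np.concatenate([[1.0, 7.0], base[2:]]), width=1)
        assert dice_score(a, b, "NFL", 512) == pytest.approx(0.6)

    def test_both_empty_is_one(self):
        base = np.arange(9) * 10.0
        a = self._flat_seg(base)
        b = self._flat_seg(base)
        a.boundaries[1] = a.boundaries[0]  # zero-height NFL
        b.boundaries[1] = b.boundaries[0]
        assert dice_score(a, b, "NFL", 512) == 1.0


class TestUsageRate:
    def test_quarter(self):
        sel = ["X"] * 7 + ["Y"] * 21
        rates = usage_rate(sel, ["X", "Y"])
        assert rates["X"] == pytest.approx(0.25)

    def test_single_model_always(self):
        assert usage_rate(["m"] * 5, ["m"])["m"] == 1.0

    def test_direct_count_and_sum(self):
        rates = usage_rate(["A", "A", "B", "C"], ["A", "B", "C"])
        assert rates == {"A": 0.5, "B": 0.25, "C": 0.25}
        assert sum(rates.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            usage_rate([], ["A"])

    def test_unknown_selection_rejected(self):
        with pytest.raises(ValueError):
            usage_rate(["Z"], ["A"])
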