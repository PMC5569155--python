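"""Circular-ROI sweep, elasticity statistics, clamping and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import swequant as sq


def brute_force_sweep(emap, diameter_mm, min_valid_fraction=0.5):
    """Naive oracle: evaluate every full-footprint centre with a mask."""
    r_px = (diameter_mm / 2.0) / emap.pixel_spacing_mm
    rr = int(np.floor(r_px))
    h, w = emap.shape
    best = None
    n_off = sq.circular_offsets(diameter_mm, emap.pixel_spacing_mm).shape[0]
    for r in range(rr, h - rr):
        for c in range(rr, w - rr):
            ri, ci = np.mgrid[r - rr : r + rr + 1, c - rr : c + rr + 1]
            mask = (ri - r) ** 2 + (ci - c) ** 2 <= r_px * r_px + 1e-12
            sel_r, sel_c = ri[mask], ci[mask]
            ok = ~emap.missing[sel_r, sel_c]
            if ok.sum() < min_valid_fraction * n_off or not ok.any():
                continue
            vals = emap.values[sel_r[ok], sel_c[ok]]
            mean = np.mean(vals)
            if best is None or mean > best[0]:
                best = (mean, (r, c), np.max(vals), np.std(vals), int(ok.sum()))
    return best


class TestCircularOffsets:
    @pytest.mark.parametrize(
        "diameter,spacing,count",
        [(2.0, 3.0, 1), (2.0, 1.0, 5), (2.0, 0.1, 317)],
    )
    def test_counts_match_lattice_enumeration(self, diameter, spacing, count):
        offs = sq.circular_offsets(diameter, spacing)
        assert offs.shape[0] == count
        assert any((dr, dc) == (0, 0) for dr, dc in offs)

    def test_plus_shape_at_unit_radius(self):
        offs = {tuple(o) for o in sq.circular_offsets(2.0, 1.0)}
        assert offs == {(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sq.circular_offsets(0, 1)


class TestRoiStats:
    def _map(self, values):
        vals = np.asarray(values, dtype=float)
        return sq.ElasticityMap(vals, np.isnan(vals), 1.0, 300.0)

    def test_closed_form(self):
        emap = self._map([[10, 20, 30]])
        offs = np.array([(0, -1), (0, 0), (0, 1)])
        res = sq.roi_stats(emap, (0, 1), offs)
        assert res.e_mean == 20 and res.e_max == 30
        assert res.sd == pytest.approx(np.sqrt(200 / 3))

    def test_uniform_roi(self):
        emap = self._map(np.full((5, 5), 50.0))
        res = sq.roi_stats(emap, (2, 2), sq.circular_offsets(2.0, 1.0))
        assert (res.e_mean, res.e_max, res.sd) == (50, 50, 0)

    def test_missing_pixels_excluded(self):
        emap = self._map([[100, np.nan, 160]])
        offs = np.array([(0, -1), (0, 0), (0, 1)])
        res = sq.roi_stats(emap, (0, 1), offs)
        assert res.e_mean == 130 and res.e_max == 160 and res.n_pixels == 2

    def test_all_missing_raises(self):
        emap = self._map([[np.nan, np.nan]])
        with pytest.raises(sq.UncomputableROIError):
            sq.roi_stats(emap, (0, 0), np.array([(0, 0), (0, 1)]))

    def test_out_of_bounds_footprint(self):
        emap = self._map(np.ones((3, 3)))
        with pytest.raises(ValueError):
            sq.roi_stats(emap, (0, 0), np.array([(-1, 0), (0, 0)]))


class TestSweepRoi:
    def test_uniform_map_first_rowmajor_centre(self):
        emap = sq.ElasticityMap(np.full((9, 9), 42.0), None, 1.0, 300.0)
        res = sq.sweep_roi(emap, diameter_mm=2.0)
        assert res.centre_rc == (1, 1)  # first full-footprint centre
        assert res.e_mean == 42.0

    def test_single_hot_pixel_found(self):
        vals = np.zeros((15, 15))
        vals[7, 9] = 180.0
        emap = sq.ElasticityMap(vals, None, 1.0, 300.0)
        res = sq.sweep_roi(emap, diameter_mm=2.0)
        assert res.e_max == 180.0
        assert abs(res.centre_rc[0] - 7) <= 1 and abs(res.centre_rc[1] - 9) <= 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 180, (40, 40))
        miss = rng.random((40, 40)) < 0.05
        vals = np.where(miss, np.nan, vals)
        emap = sq.ElasticityMap(vals, miss, 0.25, 300.0)
        res = sq.sweep_roi(emap, diameter_mm=2.0)
        mean, centre, emax, sd, n = brute_force_sweep(emap, 2.0)
        assert res.centre_rc == centre
        assert res.e_mean == mean and res.e_max == emax and res.sd == sd
        assert res.n_pixels == n

    def test_exclusion_mask_disjoint_from_winner_is_noop(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 100, (30, 30))
        vals[14:17, 14:17] = 170.0
        emap = sq.ElasticityMap(vals, None, 1.0, 300.0)
        base = sq.sweep_roi(emap, diameter_mm=4.0)
        excl = np.zeros((30, 30), bool)
        excl[0:3, 0:3] = True  # far from the stiff patch
        res = sq.sweep_roi(emap, diameter_mm=4.0, exclusion=excl)
        assert res == base

    def test_exclusion_mask_removes_artefact(self):
        vals = np.zeros((20, 20))
        vals[5, 5] = 180.0  # artefact
        vals[14, 14] = 90.0
        emap = sq.ElasticityMap(vals, None, 1.0, 300.0)
        excl = np.zeros((20, 20), bool)
        excl[3:8, 3:8] = True
        res = sq.sweep_roi(emap, diameter_mm=2.0, exclusion=excl)
        assert res.e_max == 90.0

    @given(seed=st.integers(0, 100), bump=st.floats(1.0, 50.0))
    @settings(max_examples=15, deadline=None)
    def test_raising_a_pixel_never_lowers_winning_mean(self, seed, bump):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 120, (12, 12))
        emap = sq.ElasticityMap(vals, None, 1.0, 300.0)
        before = sq.sweep_roi(emap, diameter_mm=2.0).e_mean
        r, c = rng.integers(0, 12, 2)
        vals2 = vals.copy()
        vals2[r, c] = min(vals2[r, c] + bump, 300.0)
        after = sq.sweep_roi(
            sq.ElasticityMap(vals2, None, 1.0, 300.0), diameter_mm=2.0
        ).e_mean
        assert after >= before - 1e-12

    def test_map_smaller_than_footprint(self):
        emap = sq.ElasticityMap(np.ones((3, 3)), None, 0.1, 300.0)
        with pytest.raises(sq.UncomputableROIError):
            sq.sweep_roi(emap, diameter_mm=2.0)


class TestClamp:
    @pytest.mark.parametrize("value,expected", [(250, 180), (100, 100), (180, 180)])
    def test_examples(self, value, expected):
        assert sq.clamp_to_display(value) == expected

    def test_idempotent(self):
        vals = np.linspace(0, 300, 31)
        once = sq.clamp_to_display(vals)
        np.testing.assert_array_equal(sq.clamp_to_display(once), once)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sq.clamp_to_display(-1.0)


class TestAggregateLesion:
    @staticmethod
    def _roi(e_max, e_mean=50.0, sd=5.0):
        return sq.ROIResult((5, 5), 2.0, e_mean, e_max, sd, 9)

    def test_mean_of_four(self):
        rec = sq.aggregate_lesion(
            [self._roi(v) for v in (80, 90, 100, 110)], "L1", "malignant"
        )
        assert rec.e_max == 95.0

    def test_single_image_identity(self):
        with pytest.warns(UserWarning):
            rec = sq.aggregate_lesion([self._roi(77.0)], "L2", "benign")
        assert rec.e_max == 77.0

    def test_three_images_warns_and_averages(self):
        with pytest.warns(UserWarning, match="3"):
            rec = sq.aggregate_lesion(
                [self._roi(v) for v in (60, 70, 80)], "L3", "benign"
            )
        assert rec.e_max == 70.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sq.aggregate_lesion([], "L4", "benign")


class TestRenderRoiOverlay:
    def test_overlay_differs_on_circle(self, phantom_map):
        res = sq.sweep_roi(phantom_map, diameter_mm=2.0)
        img = sq.render_roi_overlay(phantom_map, res)
        assert img.shape == (*phantom_map.shape, 3)
        base = sq.render_roi_overlay(phantom_map, res)
        # at least the perimeter is drawn white
        assert (img == 255).all(axis=2).sum() >= 8

    def test_centre_recoverable_from_overlay(self, phantom_map):
        res = sq.sweep_roi(phantom_map, diameter_mm=2.0)
        img = sq.render_roi_overlay(phantom_map, res)
        ys, xs = np.where((img == 255).all(axis=2))
        assert abs(ys.mean() - res.centre_rc[0]) <= 1
        assert abs(xs.mean() - res.centre_rc[1]) <= 1

    def test_out_of_bounds_result_rejected(self, phantom_map):
        bad = sq.ROIResult((10_000, 5), 2.0, 10, 20, 1, 4)
        with pytest.raises(ValueError):
            sq.render_roi_overlay(phantom_map, bad)
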