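"""Ratio computation, calibration and equivolume depth binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from myelindev import maps, synthetic
from myelindev.maps import CalibrationRefs, EquivolumeColumn, RatioVolume


class TestComputeRatio:
    def test_identity_when_equal(self, rng):
        vol = rng.uniform(1, 2, (4, 4, 4))
        mask = np.ones_like(vol, dtype=bool)
        out = maps.compute_ratio(vol, vol, mask)
        np.testing.assert_allclose(out.values[mask], 1.0)

    def test_voxelwise_division(self):
        t1 = np.full((2, 2, 2), 2.0)
        t2 = np.full((2, 2, 2), 4.0)
        out = maps.compute_ratio(t1, t2, np.ones_like(t1, bool))
        np.testing.assert_allclose(out.values, 0.5)

    def test_zero_t2w_reports_offender_count(self):
        t1 = np.ones((3, 3, 1))
        t2 = np.ones((3, 3, 1))
        t2[0, :, 0] = 0.0
        with pytest.raises(ValueError, match="3 in-mask"):
            maps.compute_ratio(t1, t2, np.ones_like(t1, bool))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            maps.compute_ratio(np.ones((2, 2, 2)), np.ones((2, 2, 3)), np.ones((2, 2, 2), bool))

    def test_outside_mask_is_nan(self):
        t1 = np.ones((2, 2, 2))
        mask = np.zeros_like(t1, bool)
        mask[0, 0, 0] = True
        out = maps.compute_ratio(t1, t1, mask)
        assert np.isnan(out.values[~mask]).all()


class TestCalibrateRatio:
    def _vol(self, values):
        values = np.asarray(values, float)
        return RatioVolume(values, np.ones_like(values, bool))

    def test_two_point_line_arithmetic(self):
        # subject (0.5, 2.0) -> group (0.6, 1.8): a = 0.8, b = 0.2
        refs = CalibrationRefs(0.5, 2.0, 0.6, 1.8)
        out = maps.calibrate_ratio(self._vol([[[1.0]]]), refs)
        assert out.values[0, 0, 0] == pytest.approx(1.0)

    def test_anchors_map_exactly(self):
        refs = CalibrationRefs(0.4, 1.7, 0.6, 1.8)
        out = maps.calibrate_ratio(self._vol([[[0.4, 1.7]]]), refs)
        np.testing.assert_allclose(out.values[0, 0], [0.6, 1.8], rtol=1e-12)

    def test_identity_when_subject_equals_group(self, rng):
        vals = rng.uniform(0.5, 2.0, (3, 3, 3))
        refs = CalibrationRefs(0.6, 1.8, 0.6, 1.8)
        out = maps.calibrate_ratio(self._vol(vals), refs)
        np.testing.assert_allclose(out.values, vals, rtol=1e-12)

    def test_order_preserving_and_permutation_equivariant(self, rng):
        vals = rng.uniform(0.5, 2.0, (4, 4, 1))
        refs = CalibrationRefs(0.5, 2.0, 0.6, 1.8)
        out = maps.calibrate_ratio(self._vol(vals), refs).values
        perm = rng.permutation(16)
        out_perm = maps.calibrate_ratio(self._vol(vals.ravel()[perm].reshape(4, 4, 1)), refs)
        np.testing.assert_allclose(out_perm.values.ravel(), out.ravel()[perm])
        flat_in, flat_out = vals.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)

    def test_degenerate_refs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            CalibrationRefs(1.0, 1.0, 0.6, 1.8)


class TestEquivolumeRho:
    def test_flat_slab_identity(self):
        col = EquivolumeColumn(2.0, 2.0)
        a = np.linspace(0, 1, 11)
        np.testing.assert_allclose(maps.equivolume_rho(col, a), a)

    def test_annulus_like_half_volume(self):
        # equal-area annulus radius sqrt((1 + 4) / 2) with r_in=1, r_out=2
        col = EquivolumeColumn(1.0, 2.0)
        assert maps.equivolume_rho(col, 0.5) == pytest.approx(np.sqrt(2.5) - 1, abs=1e-12)

    def test_boundaries(self):
        col = EquivolumeColumn(0.7, 3.1)
        assert maps.equivolume_rho(col, 0.0) == 0.0
        assert maps.equivolume_rho(col, 1.0) == pytest.approx(1.0)

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(ValueError):
            maps.equivolume_rho(EquivolumeColumn(1, 2), 1.5)

    def test_matches_numerical_inversion_oracle(self):
        # brute force: invert the cumulative volume integral of the linear
        # area profile A(rho) = A_w + rho (A_p - A_w) for 100 random columns
        rng = np.random.default_rng(42)
        for _ in range(100):
            aw, ap = rng.uniform(0.2, 5.0, 2)
            alpha = rng.uniform(0.001, 0.999)
            col = EquivolumeColumn(aw, ap)
            total, _ = quad(lambda t: aw + t * (ap - aw), 0, 1)

            def cum(rho):
                v, _ = quad(lambda t: aw + t * (ap - aw), 0, rho)
                return v / total - alpha

            oracle = brentq(cum, 0.0, 1.0, xtol=1e-13)
            assert maps.equivolume_rho(col, alpha) == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        aw=st.floats(0.05, 10.0),
        ap=st.floats(0.05, 10.0),
        alpha=st.floats(0.0, 1.0),
    )
    def test_property_rho_bounded_monotone_and_invertible(self, aw, ap, alpha):
        col = EquivolumeColumn(aw, ap)
        rho = float(maps.equivolume_rho(col, alpha))
        assert -1e-12 <= rho <= 1 + 1e-9
        # invertibility
        back = float(maps.equivolume_alpha(col, min(max(rho, 0.0), 1.0)))
        assert back == pytest.approx(alpha, abs=1e-9)
        # monotonicity in alpha
        if alpha < 0.999:
            assert float(maps.equivolume_rho(col, min(alpha + 1e-3, 1.0))) >= rho

    def test_alpha_is_inverse_of_rho(self, rng):
        col = EquivolumeColumn(0.8, 2.4)
        a = rng.uniform(0, 1, 50)
        np.testing.assert_allclose(
            maps.equivolume_alpha(col, maps.equivolume_rho(col, a)), a, atol=1e-12
        )


class TestAssignDepthBins:
    def test_slab_equidistant_bins(self):
        r = synthetic.make_phantom_ribbon("slab", 0.0, 3.0, 0.1, grid_shape=(10, 10, 32))
        bins = maps.assign_depth_bins(r, 6)
        counts = np.bincount(bins[bins > 0], minlength=7)[1:]
        np.testing.assert_array_equal(counts, counts[0])

    def test_annulus_boundary_radius(self):
        r = synthetic.make_phantom_ribbon("annulus", 10.0, 12.0, 0.1)
        bins = maps.assign_depth_bins(r, 2)
        radius = r._coord()
        boundary = np.sqrt((10.0**2 + 12.0**2) / 2)  # sqrt(122)
        assert radius[bins == 1].max() <= boundary + 0.1
        assert radius[bins == 2].min() >= boundary - 0.1

    def test_seven_bins_trim_leaves_five(self):
        r = synthetic.make_phantom_ribbon("annulus", 10.0, 12.0, 0.1)
        bins = maps.assign_depth_bins(r, 7)
        ratio = RatioVolume(np.ones_like(bins, float), bins > 0)
        parcels = np.zeros_like(bins)
        table = maps.extract_depth_profiles(ratio, bins, parcels, trim_extremes=True)
        assert sorted(table["depth_bin"]) == [2, 3, 4, 5, 6]

    def test_bin_volumes_within_tolerance(self):
        r = synthetic.make_phantom_ribbon("annulus", 10.0, 12.0, 0.1)  # vox = thickness/20
        bins = maps.assign_depth_bins(r, 6)
        counts = np.bincount(bins[bins > 0], minlength=7)[1:]
        total = counts.sum()
        assert np.all(np.abs(counts - total / 6) <= 0.02 * total / 6)

    def test_general_ribbon_rho_through_column(self):
        # rho volume on a flat column is binned directly on alpha = rho
        rho = np.linspace(0, 0.999, 100).reshape(10, 10, 1)
        bins = maps.assign_depth_bins(rho, 4, column=EquivolumeColumn(2.0, 2.0))
        assert np.array_equal(np.unique(bins), [1, 2, 3, 4])

    def test_missing_depth_coordinate_is_background(self):
        rho = np.full((3, 3, 1), np.nan)
        rho[1, 1, 0] = 0.5
        bins = maps.assign_depth_bins(rho, 2)
        assert bins[1, 1, 0] == 2 and (bins == 0).sum() == 8


class TestExtractDepthProfiles:
    def _setup(self, K=3):
        r = synthetic.make_phantom_ribbon("slab", 0.0, 3.0, 0.25, grid_shape=(8, 8, 14))
        bins = maps.assign_depth_bins(r, K)
        parcels = np.zeros(r.label_volume.shape, dtype=int)
        parcels[4:] = 1
        return r, bins, parcels

    def test_constant_volume_gives_constant_cells(self):
        r, bins, parcels = self._setup()
        ratio = RatioVolume(np.full(bins.shape, 1.7), r.label_volume > 0)
        table = maps.extract_depth_profiles(ratio, bins, parcels)
        assert np.allclose(table["mean_ratio"], 1.7)

    def test_bin_index_volume_reproduces_index(self):
        r, bins, parcels = self._setup()
        ratio = RatioVolume(bins.astype(float), r.label_volume > 0)
        table = maps.extract_depth_profiles(ratio, bins, parcels)
        np.testing.assert_allclose(table["mean_ratio"], table["depth_bin"])

    def test_deep_gradient_monotone_means(self):
        r, bins, parcels = self._setup(K=5)
        alpha = r.alpha_volume()
        ratio = RatioVolume(2.0 - np.nan_to_num(alpha), r.label_volume > 0)
        table = maps.extract_depth_profiles(ratio, bins, parcels)
        for _, sub in table.groupby("parcel"):
            assert np.all(np.diff(sub.sort_values("depth_bin")["mean_ratio"]) < 0)

    def test_empty_cells_reported_not_dropped(self):
        r, bins, parcels = self._setup()
        mask = r.label_volume > 0
        mask[4:] = False  # parcel 1 fully masked out
        vals = np.ones(bins.shape)
        parcels_all = parcels.copy()
        parcels_all[~mask & (bins > 0)] = 1
        ratio = RatioVolume(vals, mask)
        table = maps.extract_depth_profiles(ratio, bins, parcels_all)
        empty = table[table["n_voxels"] == 0]
        assert len(empty) == 0 or empty["mean_ratio"].isna().all()
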