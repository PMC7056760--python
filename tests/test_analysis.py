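"""VOI fitting, recovery coefficients, dilation/convergence, crosstalk
arithmetic, line profiles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from duospect import analysis as A
from duospect import phantoms as pp
from duospect.recon import ActivityImage


@pytest.fixture(scope="module")
def nema_truth():
    """Coarse (resampled) truth: partial-volume at sphere boundaries."""
    ph = pp.make_nema_iq(voxel_mm=2.0, tc_background_kbq_ml=0.0).resample(4.0)
    img = ActivityImage(ph.activity_ho.astype(float), ph.voxel_mm,
                        meta={"config": ph.config})
    vois = A.nema_voi_layout(ph.config)
    return img, vois


@pytest.fixture(scope="module")
def nema_truth_fine():
    """Native 2-mm truth: sphere fill and VOI masks share the
    voxel-center-inside convention, so matched RCs are exact."""
    ph = pp.make_nema_iq(voxel_mm=2.0, tc_background_kbq_ml=0.0)
    img = ActivityImage(ph.activity_ho.astype(float), ph.voxel_mm,
                        meta={"config": ph.config})
    vois = A.nema_voi_layout(ph.config)
    return img, vois


class TestVOIFit:
    def test_unshifted_truth_fits_zero_offset(self, nema_truth):
        img, vois = nema_truth
        _, off = A.fit_voi_positions(img, vois, search_cm=0.9)
        assert np.abs(off).max() <= img.voxel_mm / 20.0  # half a voxel

    def test_known_shift_recovered_within_half_voxel(self, nema_truth):
        img, vois = nema_truth
        shift = (0.8, -0.4, 0.4)  # cm
        shifted = [v.__class__(v.sphere_id, v.diameter_mm,
                               tuple(np.subtract(v.center_cm, shift)),
                               v.dilation_mm) for v in vois]
        _, off = A.fit_voi_positions(img, shifted, search_cm=1.2)
        assert np.abs(np.subtract(off, shift)).max() < img.voxel_mm / 20.0

    def test_fit_value_at_least_truth_value(self, nema_truth):
        img, vois = nema_truth
        fitted, _ = A.fit_voi_positions(img, vois, search_cm=0.9)

        def total_mean(vs):
            return sum(float(img.values[A.voi_mask(
                img.values.shape, img.voxel_mm, v)].mean()) for v in vs)

        assert total_mean(fitted) >= total_mean(vois) - 1e-12

    def test_all_zero_image_rejected(self, nema_truth):
        _, vois = nema_truth
        zero = ActivityImage(np.zeros((8, 8, 8)), 4.0)
        with pytest.raises(ValueError):
            A.fit_voi_positions(zero, vois)


class TestRecoveryCoefficients:
    def test_truth_image_recovers_100_percent(self, nema_truth_fine):
        img, vois = nema_truth_fine
        rc = A.recovery_coefficients(img, vois, 0.8)
        np.testing.assert_allclose(rc.rc_percent, 100.0, atol=0.06)
        assert rc.shape[0] == 6

    def test_blurred_truth_rc_increases_with_diameter(self, nema_truth):
        img, vois = nema_truth
        blurred = ActivityImage(
            gaussian_filter(img.values, sigma=2.5), img.voxel_mm)
        rc = A.recovery_coefficients(blurred, vois, 0.8)
        ordered = rc.sort_values("diameter_mm").rc_percent.to_numpy()
        assert np.all(np.diff(ordered) > 0)

    def test_dilated_voi_captures_spillout_on_truth(self, nema_truth_fine):
        img, vois = nema_truth_fine
        dil = [v.dilated(20.0) for v in vois]
        rc = A.recovery_coefficients(img, dil, 0.8)
        # total activity vs the analytic sphere activity: only the 2-mm
        # voxelization error of the smallest sphere remains
        assert np.all(np.abs(rc.rc_percent - 100.0) < 3.0)
        assert set(rc.basis) == {"total_activity"}

    def test_rc_of_blurred_truth_dilated_vs_matched(self, nema_truth):
        img, vois = nema_truth
        blurred = ActivityImage(
            gaussian_filter(img.values, sigma=1.5), img.voxel_mm)
        matched = A.recovery_coefficients(blurred, vois, 0.8)
        dilated = A.recovery_coefficients(
            blurred, [v.dilated(20.0) for v in vois], 0.8)
        assert np.all(dilated.rc_percent.to_numpy()
                      >= matched.rc_percent.to_numpy())


class TestDilationSweep:
    def test_delta_zero_equals_matched(self, nema_truth):
        img, vois = nema_truth
        sweep = A.dilation_sweep(img, vois, deltas_mm=(0,),
                                 true_conc_mbq_ml=0.8)
        matched = A.recovery_coefficients(img, vois, 0.8)
        np.testing.assert_allclose(sweep.rc_percent, matched.rc_percent)

    def test_monotone_capture_on_blurred_truth(self, nema_truth):
        img, vois = nema_truth
        blurred = ActivityImage(
            gaussian_filter(img.values, sigma=1.5), img.voxel_mm)
        big = vois[-1:]  # the 37-mm sphere
        sweep = A.dilation_sweep(blurred, big, deltas_mm=(0, 10, 20, 30),
                                 true_conc_mbq_ml=0.8)
        # dilated entries use the total-activity basis; they must not
        # decrease as the VOI grows
        dil = sweep[sweep.dilation_mm > 0].sort_values("dilation_mm")
        assert np.all(np.diff(dil.rc_percent.to_numpy()) >= 0)

    def test_overlap_flagged_beyond_40mm(self, nema_truth):
        img, vois = nema_truth
        with pytest.raises(A.VOIOverlapError):
            A.dilation_sweep(img, vois, deltas_mm=(45,),
                             true_conc_mbq_ml=0.8)
        # the default +20 mm working dilation is safe on the standard ring
        A.dilation_sweep(img, vois, deltas_mm=(20,), true_conc_mbq_ml=0.8)
        # largest-vs-smallest neighbors touch right at the +40 mm bound
        with pytest.raises(A.VOIOverlapError):
            A.dilation_sweep(img, vois, deltas_mm=(40,),
                             true_conc_mbq_ml=0.8)


class TestConvergenceCurve:
    def test_uniform_initial_snapshot_rc(self, nema_truth):
        img, vois = nema_truth
        uniform = ActivityImage(np.full_like(img.values, 0.2),
                                img.voxel_mm, iteration=0)
        curve = A.convergence_curve([uniform], vois, 0.8)
        np.testing.assert_allclose(curve.rc_percent, 0.2 / 0.8 * 100,
                                   atol=0.11)

    def test_curve_indexes_iterations(self, nema_truth):
        img, vois = nema_truth
        snaps = [ActivityImage(img.values * f, img.voxel_mm, iteration=i)
                 for i, f in ((1, 0.5), (2, 1.0))]
        curve = A.convergence_curve(snaps, vois, 0.8)
        assert set(curve.iteration) == {1, 2}
        rc1 = curve[curve.iteration == 1].rc_percent.to_numpy()
        rc2 = curve[curve.iteration == 2].rc_percent.to_numpy()
        # RC is linear in the image up to the 0.1% report rounding
        np.testing.assert_allclose(rc1, rc2 / 2, atol=0.1)


class TestLineProfiles:
    def test_flat_projection_gives_flat_profile(self):
        prof = A.line_profile(np.ones((16, 12)))
        np.testing.assert_allclose(prof["proj"], 12.0)

    def test_box_validation(self):
        with pytest.raises(ValueError):
            A.line_profile(np.ones((16, 12)), box=(0, 20, 0, 12))

    def test_normalization_to_reference_window(self):
        profs = {"tc140": np.array([1.0, 3.0]), "ho81": np.array([2.0, 2.0])}
        out = A.normalize_profiles(profs)
        assert out["tc140"].sum() == pytest.approx(1.0)
        assert out["ho81"].sum() == pytest.approx(1.0)


class TestCrosstalkArithmetic:
    def test_published_factor_combination(self):
        # factors (2, 4) at the clinical 5:1 ratio
        assert A.crosstalk_ratios((2, 4), (5, 1)) == ((5, 2), (5, 4))

    def test_unit_factors_preserve_ratio(self):
        assert A.crosstalk_ratios((1, 1), (1, 1)) == ((1, 1), (1, 1))

    def test_reduction_to_lowest_terms(self):
        assert A.crosstalk_ratios((2, 4), (10, 1)) == ((5, 1), (5, 2))

    def test_invalid_factors(self):
        with pytest.raises(ValueError):
            A.crosstalk_ratios((0, 4), (5, 1))

    def test_factors_from_counts(self):
        c_ho = {"ho81": 100.0, "tc140": 50.0}
        c_tc = {"ho81": 400.0, "tc140": 400.0}
        f81, f140 = A.crosstalk_factors_from_counts(c_ho, c_tc, 1.0, 2.0)
        assert f81 == pytest.approx(2.0)
        assert f140 == pytest.approx(4.0)
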