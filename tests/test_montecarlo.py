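"""Monte Carlo simulator: scaling, reproducibility, scatter behavior."""

import numpy as np
import pytest

from duospect import phantoms as pp
from duospect.geometry import AcquisitionGeometry
from duospect.montecarlo import (
    simulate_downscatter,
    simulate_projections,
    window_count_ratio,
)
from duospect.physics import spectrum
from duospect.psf import CollimatorParams, generate_psf_table


def _point_phantom(conc=1.0, n=15, voxel=4.8, water_r=6, tc=True):
    act = np.zeros((n, n, n), np.float32)
    act[n // 2, n // 2, n // 2] = conc
    mats = np.zeros((n, n, n), np.uint8)
    r = np.linalg.norm(np.indices((n, n, n)) - n // 2, axis=0)
    mats[r < water_r] = 1
    zero = np.zeros_like(act)
    return pp.VoxelPhantom(voxel, zero if tc else act,
                           act if tc else zero, mats)


@pytest.fixture(scope="module")
def tiny_geom(request):
    windows = request.getfixturevalue("windows")
    return AcquisitionGeometry(n_angles=4, nu=32, nv=24,
                               windows=tuple(windows.values()))


class TestScalingAndDeterminism:
    def test_zero_activity_phantom_warns_and_returns_zeros(self, tiny_geom,
                                                           psf_tables):
        n = 9
        ph = pp.VoxelPhantom(4.8, np.zeros((n, n, n), np.float32),
                             np.zeros((n, n, n), np.float32),
                             np.zeros((n, n, n), np.uint8))
        with pytest.warns(UserWarning, match="no activity"):
            proj = simulate_projections(ph, psf_tables, tiny_geom,
                                        n_histories=100, seed=0)
        assert all(a.max() == 0.0 for a in proj.counts.values())

    def test_fixed_seed_bit_identical(self, tiny_geom, psf_tables):
        ph = _point_phantom()
        a = simulate_projections(ph, psf_tables, tiny_geom,
                                 n_histories=2000, seed=11)
        b = simulate_projections(ph, psf_tables, tiny_geom,
                                 n_histories=2000, seed=11)
        for lab in a.counts:
            np.testing.assert_array_equal(a.counts[lab], b.counts[lab])

    def test_counts_linear_in_acquisition_time(self, windows, psf_tables):
        ph = _point_phantom()
        g1 = AcquisitionGeometry(n_angles=4, nu=32, nv=24,
                                 windows=tuple(windows.values()),
                                 time_per_angle_s=10.0)
        g2 = AcquisitionGeometry(n_angles=4, nu=32, nv=24,
                                 windows=tuple(windows.values()),
                                 time_per_angle_s=20.0)
        p1 = simulate_projections(ph, psf_tables, g1, n_histories=2000,
                                  seed=7)
        p2 = simulate_projections(ph, psf_tables, g2, n_histories=2000,
                                  seed=7)
        assert p2.total("tc140") == pytest.approx(2 * p1.total("tc140"),
                                                  rel=1e-9)

    def test_counts_linear_in_activity(self, tiny_geom, psf_tables):
        p1 = simulate_projections(_point_phantom(conc=1.0), psf_tables,
                                  tiny_geom, n_histories=2000, seed=7)
        p2 = simulate_projections(_point_phantom(conc=2.0), psf_tables,
                                  tiny_geom, n_histories=2000, seed=7)
        assert p2.total("tc140") == pytest.approx(2 * p1.total("tc140"),
                                                  rel=1e-9)

    def test_poisson_mode_integer_counts(self, tiny_geom, psf_tables):
        proj = simulate_projections(_point_phantom(), psf_tables,
                                    tiny_geom, n_histories=2000, seed=7,
                                    poisson=True)
        arr = proj.counts["tc140"]
        np.testing.assert_array_equal(arr, np.round(arr))

    def test_detected_counts_bounded_by_emitted_photons(self, tiny_geom,
                                                        psf_tables):
        ph = _point_phantom()
        proj = simulate_projections(ph, psf_tables, tiny_geom,
                                    n_histories=2000, seed=7)
        emitted = (ph.total_tc_mbq * 1e6 * tiny_geom.time_per_angle_s
                   * spectrum("Tc99m").photons_per_decay)
        max_eff = max(a.sum() for t in psf_tables.values()
                      for a in list(t.indirect.values())
                      + list(t.direct.values()))
        bound = emitted * max_eff * tiny_geom.n_angles * 11
        assert sum(p.sum() for p in proj.counts.values()) < bound


class TestWindowPhysics:
    def test_pure_tc_point_no_pathway_to_81kev_without_scatter(
            self, windows, tiny_geom):
        # x-ray and penetration channels off, in-phantom scatter off:
        # nothing can reach 74.9-87.1 keV from a 140.5-keV emission
        params = CollimatorParams(xray_amplitude=0.0,
                                  penetration_amplitude=0.0)
        tabs = {lab: generate_psf_table(params, window=windows[lab])
                for lab in ("ho81", "tc140")}
        ph = _point_phantom(water_r=0)  # air: no scatter medium anyway
        proj = simulate_projections(ph, tabs, tiny_geom, n_histories=2000,
                                    seed=3, scatter=False)
        assert proj.total("ho81") == 0.0
        assert proj.total("tc140") > 0.0

    def test_identical_windows_ratio_is_one(self, tiny_geom, psf_tables):
        proj = simulate_projections(_point_phantom(), psf_tables,
                                    tiny_geom, n_histories=2000, seed=3)
        assert window_count_ratio(proj, "tc140", "tc140") == 1.0

    def test_disabling_scatter_decreases_c81_over_c140(self, tiny_geom,
                                                       psf_tables):
        ph = _point_phantom()
        with_s = simulate_projections(ph, psf_tables, tiny_geom,
                                      n_histories=4000, seed=3)
        without = simulate_projections(ph, psf_tables, tiny_geom,
                                       n_histories=4000, seed=3,
                                       scatter=False)
        assert window_count_ratio(without, "ho81", "tc140") \
            < window_count_ratio(with_s, "ho81", "tc140")

    def test_cylinder_counts_angle_invariant(self, windows, psf_tables):
        geom = AcquisitionGeometry(n_angles=8, nu=56, nv=56,
                                   windows=tuple(windows.values()))
        cyl = pp.make_cylinder(volume_l=2.0, tc_activity_mbq=20.0,
                               voxel_mm=4.0, diameter_cm=12.0)
        proj = simulate_projections(cyl, psf_tables, geom,
                                    n_histories=8000, seed=9)
        per_angle = proj.counts["tc140"].sum(axis=(1, 2))
        assert per_angle.std() / per_angle.mean() < 0.05

    def test_superposition_of_single_isotope_sims(self, tiny_geom,
                                                  psf_tables):
        n = 15
        ho = np.zeros((n, n, n), np.float32)
        tc = np.zeros((n, n, n), np.float32)
        ho[7, 7, 7] = 1.0
        tc[7, 9, 7] = 1.0
        mats = np.ones((n, n, n), np.uint8)
        both = pp.VoxelPhantom(4.8, ho, tc, mats)
        only_ho = pp.VoxelPhantom(4.8, ho, np.zeros_like(tc), mats)
        only_tc = pp.VoxelPhantom(4.8, np.zeros_like(ho), tc, mats)
        pb = simulate_projections(both, psf_tables, tiny_geom,
                                  n_histories=6000, seed=2)
        ph_ = simulate_projections(only_ho, psf_tables, tiny_geom,
                                   n_histories=6000, seed=2)
        pt = simulate_projections(only_tc, psf_tables, tiny_geom,
                                  n_histories=6000, seed=2)
        for lab in ("ho81", "tc140"):
            total = ph_.total(lab) + pt.total(lab)
            assert pb.total(lab) == pytest.approx(total, rel=0.10)


class TestDownscatter:
    def test_zero_tc_image_gives_exactly_zero(self, tiny_geom, psf_tables):
        n = 9
        est = simulate_downscatter(np.zeros((n, n, n)), 4.8,
                                   np.ones((n, n, n), np.uint8),
                                   psf_tables["ho81"], tiny_geom,
                                   n_histories=100, seed=0)
        assert est.counts.max() == 0.0

    def test_linear_in_tc_image(self, tiny_geom, psf_tables):
        n = 15
        img = np.zeros((n, n, n))
        img[7, 7, 7] = 1.0
        mats = np.ones((n, n, n), np.uint8)
        e1 = simulate_downscatter(img, 4.8, mats, psf_tables["ho81"],
                                  tiny_geom, n_histories=4000, seed=5)
        e2 = simulate_downscatter(2 * img, 4.8, mats, psf_tables["ho81"],
                                  tiny_geom, n_histories=4000, seed=5)
        np.testing.assert_allclose(e2.counts, 2 * e1.counts, rtol=1e-9)

    def test_downscatter_broader_than_photopeak(self, tiny_geom,
                                                psf_tables):
        ph = _point_phantom(water_r=7)
        proj = simulate_projections(ph, psf_tables, tiny_geom,
                                    n_histories=8000, seed=5)

        def second_moment(img2d):
            u = np.arange(img2d.shape[0])
            p = img2d.sum(axis=1)
            p = p / p.sum()
            m = (p * u).sum()
            return (p * (u - m) ** 2).sum()

        assert second_moment(proj.counts["ho81"][0]) \
            > second_moment(proj.counts["tc140"][0])
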