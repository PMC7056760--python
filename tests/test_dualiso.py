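"""Three-step dual-isotope pipeline: degeneracy, self-scatter, determinism."""

import numpy as np
import pytest

from duospect import phantoms as pp
from duospect.geometry import AcquisitionGeometry
from duospect.dualiso import (
    DualStudy,
    ho_self_scatter_estimate,
    reconstruct_dual,
    simulate_dual_study,
)
from duospect.montecarlo import ProjectionSet
from duospect.physics import spectrum
from duospect.recon import ReconConfig


def _ball_phantom(n=17, voxel=4.8, ho=0.5, tc=0.0):
    act_ho = np.zeros((n, n, n), np.float32)
    act_tc = np.zeros((n, n, n), np.float32)
    mats = np.zeros((n, n, n), np.uint8)
    r = np.linalg.norm(np.indices((n, n, n)) - n // 2, axis=0)
    mats[r < 7] = 1
    act_ho[r < 2.5] = ho
    act_tc[(r >= 2.5) & (r < 6)] = tc
    return pp.VoxelPhantom(voxel, act_ho, act_tc, mats)


@pytest.fixture(scope="module")
def study_geom(request):
    windows = request.getfixturevalue("windows")
    return AcquisitionGeometry(n_angles=8, nu=32, nv=24,
                               windows=tuple(windows.values()))


class TestDualStudyValidation:
    def test_missing_window_rejected(self, study_geom, psf_tables):
        n = 9
        counts = {lab: np.zeros((8, 32, 24))
                  for lab in ("ho81", "tc140", "sc170")}  # no sc118
        proj = ProjectionSet(counts, study_geom)
        with pytest.raises(ValueError, match="missing windows"):
            DualStudy(proj, np.zeros((n, n, n), np.uint8), 4.8,
                      psf_tables, study_geom)

    def test_missing_psf_table_rejected(self, study_geom, psf_tables):
        n = 9
        counts = {lab: np.zeros((8, 32, 24))
                  for lab in ("ho81", "sc118", "tc140", "sc170")}
        proj = ProjectionSet(counts, study_geom)
        with pytest.raises(ValueError, match="PSF table"):
            DualStudy(proj, np.zeros((n, n, n), np.uint8), 4.8,
                      {"ho81": psf_tables["ho81"]}, study_geom)


class TestPipelineDegeneracy:
    def test_zero_tc_study_equals_ho_only_reconstruction(self, study_geom,
                                                         psf_tables):
        """With no counts in the Tc windows, step 1 collapses to zero, the
        downscatter estimate is exactly zero, and the Ho image equals the
        Ho-only reconstruction bit for bit."""
        # a Ho source whose emissions stay below the Tc windows: the
        # 80.6-keV line only (in-phantom scatter cannot upscatter)
        phantom = _ball_phantom(tc=0.0)
        spectra = {"Ho166": spectrum("Ho166", continuum=False).truncate(
            hi=100), "Tc99m": spectrum("Tc99m")}
        cfg = ReconConfig(n_iterations=4)
        study = simulate_dual_study(phantom, psf_tables, study_geom,
                                    n_histories=4000, seed=21,
                                    tc_config=cfg, ho_config=cfg,
                                    spectra=spectra)
        # only a numerically negligible septal-penetration trickle of the
        # 81-keV line reaches the Tc windows; idealize it away so the
        # degenerate study records exactly nothing there
        assert study.projections.total("tc140") < 1e-6 \
            * study.projections.total("ho81")
        for lab in ("tc140", "sc170", "sc118"):
            study.projections.counts[lab][:] = 0.0
        res = reconstruct_dual(study, n_histories_downscatter=2000,
                               include_self_scatter=False)
        assert res.tc_image.values.max() == 0.0
        assert res.downscatter.counts.max() == 0.0

        from duospect.dualiso import _system_model
        from duospect.physics import AttenuationModel
        from duospect.recon import osem
        model_ho = _system_model(study, "ho", AttenuationModel())
        ho_only, _ = osem(study.projections, None, model_ho, cfg,
                          data_label="ho81")
        np.testing.assert_array_equal(res.ho_image.values, ho_only.values)

    def test_downscatter_concentrates_over_tc_region(self, study_geom,
                                                     psf_tables):
        phantom = _ball_phantom(ho=0.2, tc=0.1)
        cfg = ReconConfig(n_iterations=3)
        study = simulate_dual_study(phantom, psf_tables, study_geom,
                                    n_histories=6000, seed=22,
                                    tc_config=cfg, ho_config=cfg)
        res = reconstruct_dual(study, n_histories_downscatter=4000,
                               include_self_scatter=False)
        ds = res.downscatter.counts[0]
        assert ds.sum() > 0
        # counts concentrate in the central (source-projection) half
        nu = ds.shape[0]
        central = ds[nu // 4: 3 * nu // 4].sum()
        assert central / ds.sum() > 0.9


class TestSelfScatter:
    def test_truncated_spectrum_gives_phantom_scatter_only(self, study_geom,
                                                           psf_tables):
        phantom = _ball_phantom()
        img = phantom.activity_ho.astype(float)
        spec81 = spectrum("Ho166", continuum=False).truncate(hi=100)
        est = ho_self_scatter_estimate(
            img, phantom.voxel_mm, phantom.materials, psf_tables["ho81"],
            study_geom, spec=spec81, n_histories=4000, seed=3)
        assert est.counts.sum() > 0  # in-phantom scatter of the 81 line

    def test_high_energy_line_adds_counts(self, study_geom, psf_tables):
        phantom = _ball_phantom()
        img = phantom.activity_ho.astype(float)
        spec81 = spectrum("Ho166", continuum=False).truncate(hi=100)
        with_1379 = spectrum("Ho166", continuum=False).truncate(hi=1400)
        a = ho_self_scatter_estimate(
            img, phantom.voxel_mm, phantom.materials, psf_tables["ho81"],
            study_geom, spec=spec81, n_histories=4000, seed=3)
        b = ho_self_scatter_estimate(
            img, phantom.voxel_mm, phantom.materials, psf_tables["ho81"],
            study_geom, spec=with_1379, n_histories=4000, seed=3)
        assert b.counts.sum() > a.counts.sum()

    def test_linear_in_image(self, study_geom, psf_tables):
        phantom = _ball_phantom()
        img = phantom.activity_ho.astype(float)
        a = ho_self_scatter_estimate(img, phantom.voxel_mm,
                                     phantom.materials,
                                     psf_tables["ho81"], study_geom,
                                     n_histories=4000, seed=3)
        b = ho_self_scatter_estimate(3.0 * img, phantom.voxel_mm,
                                     phantom.materials,
                                     psf_tables["ho81"], study_geom,
                                     n_histories=4000, seed=3)
        # phantoms store concentrations in float32; linearity holds to
        # that precision
        np.testing.assert_allclose(b.counts, 3.0 * a.counts, rtol=1e-5)

    def test_zero_image_exact_zero(self, study_geom, psf_tables):
        est = ho_self_scatter_estimate(
            np.zeros((9, 9, 9)), 4.8, np.ones((9, 9, 9), np.uint8),
            psf_tables["ho81"], study_geom, n_histories=100, seed=0)
        assert est.counts.max() == 0.0


class TestDeterminism:
    def test_fixed_seed_identical_images(self, study_geom, psf_tables):
        phantom = _ball_phantom(ho=0.3, tc=0.05)
        cfg = ReconConfig(n_iterations=2)
        kw = dict(n_histories=3000, tc_config=cfg, ho_config=cfg)
        s1 = simulate_dual_study(phantom, psf_tables, study_geom,
                                 seed=9, **kw)
        s2 = simulate_dual_study(phantom, psf_tables, study_geom,
                                 seed=9, **kw)
        r1 = reconstruct_dual(s1, n_histories_downscatter=2000,
                              n_histories_self=2000)
        r2 = reconstruct_dual(s2, n_histories_downscatter=2000,
                              n_histories_self=2000)
        np.testing.assert_array_equal(r1.tc_image.values,
                                      r2.tc_image.values)
        np.testing.assert_array_equal(r1.ho_image.values,
                                      r2.ho_image.values)

    def test_tc_background_raises_raw_81kev_counts(self, study_geom,
                                                   psf_tables):
        cfg = ReconConfig(n_iterations=2)
        no_tc = simulate_dual_study(_ball_phantom(ho=0.3, tc=0.0),
                                    psf_tables, study_geom,
                                    n_histories=5000, seed=4,
                                    tc_config=cfg, ho_config=cfg)
        with_tc = simulate_dual_study(_ball_phantom(ho=0.3, tc=0.1),
                                      psf_tables, study_geom,
                                      n_histories=5000, seed=4,
                                      tc_config=cfg, ho_config=cfg)
        assert with_tc.projections.total("ho81") \
            > no_tc.projections.total("ho81")
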