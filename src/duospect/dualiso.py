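"""Three-step dual-isotope reconstruction.

Step 1 — Tc-99m OSEM on the 140-keV window, correcting Ho-166 crosstalk
with the upper (170-keV) scatter window scaled by the k-factor.

Step 2 — Monte Carlo simulation of Tc-99m downscatter into the 81-keV
Ho-166 photopeak window, using the step-1 image as the Tc source.

Step 3 — Ho-166 OSEM on the 81-keV window with the step-2 estimate as a
fixed additive scatter term, plus the Ho self-scatter estimate (the
simulated contribution of out-of-window Ho emissions — high-energy gammas
and bremsstrahlung continuum — into the 81-keV window), refreshed from the
current estimate every few iterations.

The 118-keV scatter window is ingested and validated but unused by
default; it is kept available as a second energy-window scatter source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry
from .montecarlo import (
    ProjectionSet,
    ScatterEstimate,
    simulate_downscatter,
    simulate_projections,
)
from .phantoms import VoxelPhantom
from .physics import (
    AttenuationModel,
    DetectorModel,
    EmissionSpectrum,
    spectrum,
)
from .projector import SystemModel
from .psf import PSFTable
from .recon import ActivityImage, ReconConfig, osem, tew_scatter_estimate

REQUIRED_WINDOWS = ("ho81", "sc118", "tc140", "sc170")

HO_LINE_KEV, HO_LINE_PPD = 80.574, 0.0671
TC_LINE_KEV, TC_LINE_PPD = 140.511, 0.885


@dataclass
class DualStudy:
    """A dual-isotope acquisition plus everything needed to reconstruct it."""

    projections: ProjectionSet
    materials: np.ndarray
    voxel_mm: float
    psf_tables: dict[str, PSFTable]  # needs 'ho81' and 'tc140'
    geom: AcquisitionGeometry
    tc_config: ReconConfig = field(default_factory=ReconConfig)
    ho_config: ReconConfig = field(default_factory=ReconConfig)
    det: DetectorModel = field(default_factory=DetectorModel)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [w for w in REQUIRED_WINDOWS
                   if w not in self.projections.counts]
        if missing:
            raise ValueError(f"study is missing windows: {missing}")
        for w in ("ho81", "tc140"):
            if w not in self.psf_tables:
                raise ValueError(f"study needs a PSF table for {w!r}")


@dataclass
class DualResult:
    tc_image: ActivityImage
    ho_image: ActivityImage
    downscatter: ScatterEstimate
    self_scatter: ScatterEstimate | None
    intermediates: dict = field(default_factory=dict)


def _system_model(study: DualStudy, which: str,
                  atten: AttenuationModel) -> SystemModel:
    if which == "tc":
        window = study.geom.window("tc140")
        line, ppd = TC_LINE_KEV, TC_LINE_PPD
        table = study.psf_tables["tc140"]
    else:
        window = study.geom.window("ho81")
        line, ppd = HO_LINE_KEV, HO_LINE_PPD
        table = study.psf_tables["ho81"]
    mu = atten.mu_by_label(window.center)[study.materials]
    return SystemModel(mu, study.voxel_mm / 10.0, study.geom, window,
                       line, ppd, psf=table, det=study.det)


def self_scatter_estimate(image: np.ndarray, isotope: str, voxel_mm: float,
                          materials: np.ndarray, psf_table: PSFTable,
                          geom: AcquisitionGeometry,
                          spec: EmissionSpectrum | None = None,
                          n_histories: int = 10000,
                          seed: int | None = None,
                          det: DetectorModel | None = None,
                          atten: AttenuationModel | None = None,
                          ) -> ScatterEstimate:
    """In-window scatter and collimator crosstalk of an isotope's own
    emissions, excluding the unscattered in-window primaries that the
    deterministic projector models. Linear in the image; noise-free."""
    if np.any(image < 0):
        raise ValueError("activity image must be nonnegative")
    wl = psf_table.window.label
    if float(image.sum()) == 0.0:
        z = np.zeros((geom.n_angles, geom.nu, geom.nv))
        return ScatterEstimate(z, wl, {"n_histories": 0})
    zero = np.zeros_like(image, dtype=np.float32)
    img32 = image.astype(np.float32)
    ph = VoxelPhantom(voxel_mm, img32 if isotope == "Ho166" else zero,
                      img32 if isotope == "Tc99m" else zero, materials)
    spectra = {"Ho166": spectrum("Ho166"), "Tc99m": spectrum("Tc99m")}
    if spec is not None:
        spectra[isotope] = spec
    proj = simulate_projections(
        ph, {wl: psf_table}, geom, n_histories=n_histories, seed=seed,
        poisson=False, spectra=spectra, det=det, atten=atten,
        exclude_unscattered_in_window=True)
    return ScatterEstimate(proj.counts[wl], wl,
                           {"n_histories": n_histories, "seed": seed,
                            "source": f"{isotope}-self"})


def ho_self_scatter_estimate(ho_image: np.ndarray, voxel_mm: float,
                             materials: np.ndarray, psf_table: PSFTable,
                             geom: AcquisitionGeometry,
                             spec: EmissionSpectrum | None = None,
                             n_histories: int = 10000,
                             seed: int | None = None,
                             det: DetectorModel | None = None,
                             atten: AttenuationModel | None = None,
                             ) -> ScatterEstimate:
    """Out-of-window Ho-166 contribution to the 81-keV window.

    Simulates the full Ho spectrum over the current activity estimate but
    excludes the direct detection of unscattered in-window photons — what
    remains is in-phantom scatter of the 80.6-keV line plus the high-energy
    gamma and bremsstrahlung pathways (collimator penetration, lead x-rays,
    downscatter). Linear in the image; noise-free expectation.
    """
    return self_scatter_estimate(ho_image, "Ho166", voxel_mm, materials,
                                 psf_table, geom, spec=spec,
                                 n_histories=n_histories, seed=seed,
                                 det=det, atten=atten)


def _osem_refreshed(study: DualStudy, model: SystemModel, cfg: ReconConfig,
                    data_label: str, fixed_scatter: np.ndarray,
                    isotope: str, psf_table: PSFTable,
                    n_histories_self: int, refresh_every: int,
                    seed: int | None, atten: AttenuationModel):
    """OSEM with a fixed additive scatter term plus a self-scatter term
    recomputed from the current estimate every ``refresh_every``
    iterations (seeded from a single-iteration estimate).

    The refresh is relaxed: a raw re-simulation from an estimate that has
    absorbed its own scatter overshoots by the scatter-to-primary gain
    gamma, and feeding it straight back makes the loop oscillate with
    amplification gamma (severe for Ho-166, where out-of-window emissions
    outweigh the in-window primaries). Damping with
    lambda = 1 / (1 + gamma), with gamma measured at run time as the ratio
    of simulated self-scatter counts to primary forward-model counts,
    cancels the linearized error in a single refresh.
    """
    from dataclasses import replace
    first = replace(cfg, n_iterations=1, save_every=0)
    est, _ = osem(study.projections, fixed_scatter, model, first,
                  data_label=data_label)
    x = est.values
    done = 1
    snaps: list[ActivityImage] = []
    self_scatter = None
    s_self = np.zeros_like(fixed_scatter)
    while done < cfg.n_iterations:
        raw = self_scatter_estimate(
            x, isotope, study.voxel_mm, study.materials, psf_table,
            study.geom, n_histories=n_histories_self, seed=seed,
            det=study.det, atten=atten)
        primary_total = float(model.forward(x).sum())
        gamma = float(raw.counts.sum()) / max(primary_total, 1e-30)
        lam = 1.0 / (1.0 + gamma)
        s_self = (1.0 - lam) * s_self + lam * raw.counts
        self_scatter = ScatterEstimate(
            s_self, raw.window_label,
            {**raw.meta, "gamma": gamma, "relaxation": lam})
        chunk = min(refresh_every, cfg.n_iterations - done)
        part = replace(cfg, n_iterations=chunk)
        est, part_snaps = osem(
            study.projections, fixed_scatter + s_self,
            model, part, initial=x, data_label=data_label)
        x = est.values
        for s in part_snaps:
            s.iteration += done
        snaps.extend(part_snaps)
        done += chunk
    img = ActivityImage(x, study.voxel_mm, iteration=cfg.n_iterations,
                        meta={"window": data_label, "self_scatter": True})
    return img, snaps, self_scatter


def reconstruct_dual(study: DualStudy,
                     n_histories_downscatter: int = 20000,
                     include_self_scatter: bool = True,
                     n_histories_self: int = 10000,
                     refresh_every: int = 5,
                     atten: AttenuationModel | None = None) -> DualResult:
    """Run the three-step dual-isotope reconstruction on a study."""
    atten = atten or AttenuationModel()
    seed = study.seed

    # -- step 1: Tc-99m with energy-window crosstalk correction (and the
    # Tc in-window self-scatter the primary-only projector cannot model)
    model_tc = _system_model(study, "tc", atten)
    tew = tew_scatter_estimate(
        study.projections, study.tc_config.k_factor,
        width_correction=study.tc_config.width_correction)
    if include_self_scatter:
        tc_image, tc_snaps, _ = _osem_refreshed(
            study, model_tc, study.tc_config, "tc140", tew.counts,
            "Tc99m", study.psf_tables["tc140"], n_histories_self,
            refresh_every, None if seed is None else seed + 3, atten)
    else:
        tc_image, tc_snaps = osem(study.projections, tew, model_tc,
                                  study.tc_config, data_label="tc140")

    # -- step 2: Tc downscatter into the 81-keV window
    downscatter = simulate_downscatter(
        tc_image.values, study.voxel_mm, study.materials,
        study.psf_tables["ho81"], study.geom,
        n_histories=n_histories_downscatter,
        seed=None if seed is None else seed + 1,
        det=study.det, atten=atten)

    # -- step 3: Ho-166 with the downscatter as fixed additive scatter,
    # plus a periodically refreshed Ho self-scatter term
    model_ho = _system_model(study, "ho", atten)
    cfg = study.ho_config
    if include_self_scatter:
        ho_image, snaps, self_scatter = _osem_refreshed(
            study, model_ho, cfg, "ho81", downscatter.counts,
            "Ho166", study.psf_tables["ho81"], n_histories_self,
            refresh_every, None if seed is None else seed + 2, atten)
    else:
        self_scatter = None
        ho_image, snaps = osem(study.projections, downscatter.counts,
                               model_ho, cfg, data_label="ho81")
    return DualResult(tc_image, ho_image, downscatter, self_scatter,
                      {"tc_snapshots": tc_snaps, "ho_snapshots": snaps,
                       "tew": tew})


def simulate_dual_study(phantom: VoxelPhantom,
                        psf_tables: dict[str, PSFTable],
                        geom: AcquisitionGeometry,
                        n_histories: int = 30000,
                        seed: int | None = None,
                        poisson: bool = False,
                        tc_config: ReconConfig | None = None,
                        ho_config: ReconConfig | None = None,
                        det: DetectorModel | None = None,
                        spectra: dict[str, EmissionSpectrum] | None = None,
                        ) -> DualStudy:
    """Simulate a four-window acquisition of a phantom and wrap it as a
    reconstruction-ready :class:`DualStudy` on the same grid."""
    proj = simulate_projections(phantom, psf_tables, geom,
                                n_histories=n_histories, seed=seed,
                                poisson=poisson, det=det or DetectorModel(),
                                spectra=spectra)
    return DualStudy(proj, phantom.materials, phantom.voxel_mm,
                     psf_tables, geom,
                     tc_config=tc_config or ReconConfig(),
                     ho_config=ho_config or ReconConfig(),
                     det=det or DetectorModel(), seed=seed)
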