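"""OSEM reconstruction with an additive scatter term.

The update is the standard ordered-subsets EM form for Poisson data with a
known additive (scatter) expectation s:

    x <- x / (A_s^T 1) * A_s^T [ y / (A_s x + s) ]

applied per subset, with interleaved angle subsets. With one subset this is
exactly MLEM. Also provides the energy-window (triple-energy-window-style)
scatter estimator: scatter = k x upper-window counts, with an optional
window-width correction of k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .montecarlo import ProjectionSet, ScatterEstimate
from .physics import EnergyWindow
from .projector import SystemModel


@dataclass(frozen=True)
class ReconConfig:
    """OSEM settings: 20 iterations of 8 interleaved subsets by default;
    k = 0.93 relates upper-scatter-window counts to in-peak scatter."""

    n_iterations: int = 20
    n_subsets: int = 8
    k_factor: float = 0.93
    width_correction: bool = False
    nonneg_floor: float = 0.0
    save_every: int = 0  # 0: no snapshots; n: snapshot every n iterations

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise ValueError("k_factor must be positive")
        if self.n_iterations <= 0 or self.n_subsets <= 0:
            raise ValueError("iterations and subsets must be positive")


@dataclass
class ActivityImage:
    """A reconstructed activity-concentration grid (MBq/ml)."""

    values: np.ndarray
    voxel_mm: float
    calibration_factor: float = 1.0
    iteration: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("activity image must be nonnegative")

    @property
    def total_mbq(self) -> float:
        return float(self.values.sum() * (self.voxel_mm / 10.0) ** 3)


def apply_calibration(image: ActivityImage, factor: float) -> ActivityImage:
    """Voxelwise cross-calibration scaling; factor recorded in provenance."""
    if factor <= 0:
        raise ValueError("calibration factor must be positive")
    return ActivityImage(image.values * factor, image.voxel_mm,
                         calibration_factor=image.calibration_factor * factor,
                         iteration=image.iteration,
                         meta={**image.meta, "calibrated": True})


def width_corrected_k(k_factor: float, photopeak: EnergyWindow,
                      upper: EnergyWindow) -> float:
    """k rescaled by the photopeak-to-upper window width ratio (keV)."""
    return k_factor * photopeak.width_kev / upper.width_kev


def tew_scatter_estimate(upper_window_proj, k_factor: float = 0.93,
                         width_correction: bool = False,
                         photopeak: EnergyWindow | None = None,
                         upper: EnergyWindow | None = None,
                         upper_label: str = "sc170") -> ScatterEstimate:
    """Energy-window scatter estimate: k x upper-scatter-window counts.

    ``upper_window_proj`` may be a raw count array or a
    :class:`ProjectionSet` (then ``upper_label`` selects the stack). With
    ``width_correction`` the factor becomes k x (photopeak width keV) /
    (upper width keV), e.g. 0.93 -> 0.957 for the 140/15% and 170/12%
    window pair.
    """
    if k_factor <= 0:
        raise ValueError("k_factor must be positive")
    if isinstance(upper_window_proj, ProjectionSet):
        geom = upper_window_proj.geom
        counts = upper_window_proj.counts[upper_label]
        photopeak = photopeak or geom.window("tc140")
        upper = upper or geom.window(upper_label)
    else:
        counts = np.asarray(upper_window_proj, dtype=float)
    k = k_factor
    if width_correction:
        if photopeak is None or upper is None:
            raise ValueError("width correction needs both windows")
        k = width_corrected_k(k_factor, photopeak, upper)
    return ScatterEstimate(k * counts, "tew",
                           {"k_factor": k_factor, "k_applied": k,
                            "width_correction": width_correction})


def subset_angle_indices(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    """Interleaved subsets: (0, n_sub, 2*n_sub, ...), (1, ...), ..."""
    if n_angles % n_subsets:
        raise ValueError(
            f"{n_angles} angles not divisible into {n_subsets} subsets")
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


def poisson_loglikelihood(y: np.ndarray, ybar: np.ndarray) -> float:
    """Poisson log-likelihood (dropping the data-only ln y! term)."""
    ybar = np.clip(ybar, 1e-300, None)
    return float(np.sum(y * np.log(ybar) - ybar))


def osem(proj, scatter, model: SystemModel, cfg: ReconConfig,
         initial: np.ndarray | None = None,
         data_label: str | None = None):
    """Run OSEM; returns ``(ActivityImage, snapshots)``.

    ``proj`` is a count array ``(n_angles, nu, nv)`` or a
    :class:`ProjectionSet` with ``data_label``; ``scatter`` is an additive
    expectation of the same shape, a :class:`ScatterEstimate`, or None.
    Snapshots (copies of the estimate after every ``cfg.save_every``-th full
    iteration) are returned when configured.
    """
    if isinstance(proj, ProjectionSet):
        y = proj.counts[data_label or model.window.label]
    else:
        y = np.asarray(proj, dtype=float)
    if isinstance(scatter, ScatterEstimate):
        s = scatter.counts
    elif scatter is None:
        s = np.zeros_like(y)
    else:
        s = np.asarray(scatter, dtype=float)
    if y.shape != model.proj_shape or s.shape != y.shape:
        raise ValueError("projection/scatter shape does not match the model")
    if np.any(s < 0):
        raise ValueError("scatter estimate must be nonnegative")

    subsets = subset_angle_indices(model.geom.n_angles, cfg.n_subsets)
    sens = []
    for ais in subsets:
        ones = np.ones((ais.size, model.geom.nu, model.geom.nv))
        sv = model.back(ones, ais)
        if np.any(sv == 0):
            warnings.warn("zero-sensitivity voxels excluded from update")
        sens.append(sv)

    # uniform positive start inside the body support (where mu > 0)
    if initial is not None:
        x = initial.astype(float).copy()
    else:
        support = model.mu_map > 1e-6
        x = np.where(support, 1.0, 0.0) if support.any() \
            else np.ones(model.image_shape)

    snapshots = []
    inconsistent = False
    for it in range(1, cfg.n_iterations + 1):
        for ais, sv in zip(subsets, sens):
            ybar = model.forward(x, ais) + s[ais]
            ysub = y[ais]
            ratio = np.ones_like(ybar)
            pos = ybar > 0
            ratio[pos] = ysub[pos] / ybar[pos]
            bad = (~pos) & (ysub > 0)
            if bad.any() and not inconsistent:
                inconsistent = True
                warnings.warn("data inconsistency: counts observed in bins "
                              "with zero model expectation")
            upd = model.back(ratio, ais)
            good = sv > 0
            x[good] = x[good] * upd[good] / sv[good]
            np.clip(x, cfg.nonneg_floor, None, out=x)
        if cfg.save_every and it % cfg.save_every == 0:
            snapshots.append(ActivityImage(
                x.copy(), model.voxel_cm * 10.0, iteration=it))
    img = ActivityImage(x, model.voxel_cm * 10.0,
                        iteration=cfg.n_iterations,
                        meta={"n_subsets": cfg.n_subsets,
                              "window": model.window.label})
    return img, snapshots
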