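"""Deterministic attenuated forward/back projector with depth-dependent PSF.

This is the in-window (primary-photon) system model used inside OSEM. It is
a rotation-based parallel-beam projector: for each camera angle the volume
is rotated into the detector frame (bilinear interpolation with cached
gather indices, so the adjoint is the exact scatter transpose), each depth
plane is weighted by its Beer-Lambert attenuation factor toward the
detector, convolved with the distance-interpolated direct PSF kernel, and
accumulated onto the detector grid.

``back_project`` is the exact algebraic adjoint of ``forward_project``
(same gathers run as scatters, correlation instead of convolution), which
is what the multiplicative EM update requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve, correlate

from .geometry import AcquisitionGeometry
from .physics import DetectorModel, EnergyWindow, detection_probability
from .psf import PSF_DISTANCES, PSFTable


class _RotationSet:
    """Cached bilinear gather (and exact-adjoint scatter) per angle.

    Rotation acts in the transaxial (x, y) plane about the grid center;
    out-of-grid taps get zero weight. The scatter direction distributes
    each voxel's full value over four taps, so it conserves mass exactly —
    the forward projector uses it to move activity into the detector
    frame, and the gather is then the exact adjoint. The gather direction
    interpolates values and is used to resample the (fixed) mu map.
    """

    def __init__(self, shape_xy: tuple[int, int], angles_rad: np.ndarray):
        nx, ny = shape_xy
        self.shape_xy = shape_xy
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        gx = gx.ravel() - cx
        gy = gy.ravel() - cy
        self.idx = []
        self.wgt = []
        for a in angles_rad:
            c, s = np.cos(a), np.sin(a)
            # output frame axis x' points toward the detector at angle a
            sx = gx * c - gy * s + cx
            sy = gx * s + gy * c + cy
            x0 = np.floor(sx).astype(np.int64)
            y0 = np.floor(sy).astype(np.int64)
            fx, fy = sx - x0, sy - y0
            taps_i = []
            taps_w = []
            for dx, dy, w in ((0, 0, (1 - fx) * (1 - fy)),
                              (1, 0, fx * (1 - fy)),
                              (0, 1, (1 - fx) * fy),
                              (1, 1, fx * fy)):
                ix, iy = x0 + dx, y0 + dy
                valid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
                flat = np.where(valid, ix * ny + iy, 0)
                taps_i.append(flat)
                taps_w.append(np.where(valid, w, 0.0))
            self.idx.append(np.stack(taps_i))
            self.wgt.append(np.stack(taps_w))

    def rotate(self, vol: np.ndarray, ai: int) -> np.ndarray:
        nx, ny = self.shape_xy
        nz = vol.shape[2]
        flat = vol.reshape(nx * ny, nz)
        out = np.zeros((nx * ny, nz))
        for k in range(4):
            out += self.wgt[ai][k][:, None] * flat[self.idx[ai][k]]
        return out.reshape(nx, ny, nz)

    def rotate_adjoint(self, vol: np.ndarray, ai: int) -> np.ndarray:
        nx, ny = self.shape_xy
        nz = vol.shape[2]
        g = vol.reshape(nx * ny, nz)
        out = np.zeros((nx * ny, nz))
        for k in range(4):
            np.add.at(out, self.idx[ai][k], self.wgt[ai][k][:, None] * g)
        return out.reshape(nx, ny, nz)


def _crop_kernel(arr: np.ndarray, rel: float = 1e-7) -> np.ndarray:
    """Crop a kernel to the centered square support holding its mass."""
    n = arr.shape[0]
    c = n // 2
    mask = arr > rel * arr.max()
    if not mask.any():
        return arr[c:c + 1, c:c + 1]
    ii, jj = np.where(mask)
    h = int(max(np.abs(ii - c).max(), np.abs(jj - c).max()))
    return arr[c - h:c + h + 1, c - h:c + h + 1]


@dataclass
class SystemModel:
    """Linear forward/adjoint operator for one isotope window.

    Maps an activity image (MBq/ml, grid matching ``mu_map``) to expected
    in-window primary counts per detector bin per angle. The per-voxel
    scale is ``voxel_ml * 1e6 decays/s/MBq * photons_per_decay *
    p_detect(line in window) * time_per_angle``; collimator efficiency
    lives in the PSF kernels.
    """

    mu_map: np.ndarray           # 1/cm at the window energy
    voxel_cm: float
    geom: AcquisitionGeometry
    window: EnergyWindow
    line_energy_kev: float
    photons_per_decay: float
    psf: PSFTable | None = None
    det: DetectorModel | None = None

    def __post_init__(self) -> None:
        self.det = self.det or DetectorModel()
        nx, ny, nz = self.mu_map.shape
        if self.geom.nu < ny or self.geom.nv < nz:
            raise ValueError("detector grid smaller than image grid")
        if self.psf is not None and not np.isclose(
                self.psf.pitch_cm, self.geom.pitch_cm):
            raise ValueError("PSF pitch must match detector pitch")
        self._rot = _RotationSet((nx, ny), self.geom.angles_rad)
        # inverse-angle set: its scatter is the mass-conserving
        # image->detector-frame rotation used for activity
        self._rot_inv = _RotationSet((nx, ny), -self.geom.angles_rad)
        # attenuation factor from each voxel to the detector (+x direction),
        # half-voxel self-attenuation convention, cached per angle
        self._att = []
        for ai in range(self.geom.n_angles):
            mu_r = self._rot.rotate(self.mu_map, ai)
            s = np.cumsum(mu_r[::-1], axis=0)[::-1]  # includes self
            self._att.append(
                np.exp(-(s - 0.5 * mu_r) * self.voxel_cm).astype(np.float64))
        # depth-dependent direct kernels (distance from collimator face)
        xc = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_cm
        self.depth_cm = self.geom.radius_cm - xc
        self._kernels = None
        if self.psf is not None:
            self._kernels = []
            import warnings
            for dpt in self.depth_cm:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    k = self.psf.kernel(self.line_energy_kev,
                                        float(np.clip(dpt, PSF_DISTANCES[0],
                                                      PSF_DISTANCES[-1])),
                                        direct=True)
                self._kernels.append(_crop_kernel(k.array))
        p_det = detection_probability(self.line_energy_kev, self.window,
                                      self.det)
        self.scale = ((self.voxel_cm ** 3)  # ml
                      * 1e6 * self.photons_per_decay * float(p_det)
                      * self.geom.time_per_angle_s)
        if self.psf is None:
            # delta response still needs a nominal collimator efficiency
            self.scale *= 1.0

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.mu_map.shape

    @property
    def proj_shape(self) -> tuple[int, int, int]:
        return (self.geom.n_angles, self.geom.nu, self.geom.nv)

    def _embed(self, plane: np.ndarray) -> np.ndarray:
        ny, nz = plane.shape
        out = np.zeros((self.geom.nu, self.geom.nv))
        ou = (self.geom.nu - ny) // 2
        ov = (self.geom.nv - nz) // 2
        out[ou:ou + ny, ov:ov + nz] = plane
        return out

    def _extract(self, proj: np.ndarray, ny: int, nz: int) -> np.ndarray:
        ou = (self.geom.nu - ny) // 2
        ov = (self.geom.nv - nz) // 2
        return proj[ou:ou + ny, ov:ov + nz]

    def forward(self, image: np.ndarray,
                angle_indices: np.ndarray | None = None) -> np.ndarray:
        """Expected counts for the selected angles (all by default)."""
        if image.shape != self.image_shape:
            raise ValueError("image grid does not match the system model")
        ais = np.arange(self.geom.n_angles) if angle_indices is None \
            else np.asarray(angle_indices)
        nx, ny, nz = self.image_shape
        out = np.zeros((ais.size, self.geom.nu, self.geom.nv))
        vol = image * self.scale
        for j, ai in enumerate(ais):
            w = self._rot_inv.rotate_adjoint(vol, ai) * self._att[ai]
            if self._kernels is None:
                out[j] = self._embed(w.sum(axis=0))
            else:
                for ix in range(nx):
                    out[j] += convolve(self._embed(w[ix]),
                                       self._kernels[ix], mode="same")
        return out

    def back(self, projections: np.ndarray,
             angle_indices: np.ndarray | None = None) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        ais = np.arange(self.geom.n_angles) if angle_indices is None \
            else np.asarray(angle_indices)
        if projections.shape != (ais.size, self.geom.nu, self.geom.nv):
            raise ValueError("projection shape does not match the model")
        nx, ny, nz = self.image_shape
        img = np.zeros(self.image_shape)
        for j, ai in enumerate(ais):
            if self._kernels is None:
                p = self._extract(projections[j], ny, nz)
                w = np.broadcast_to(p, (nx, ny, nz)).copy()
            else:
                w = np.empty((nx, ny, nz))
                for ix in range(nx):
                    w[ix] = self._extract(
                        correlate(projections[j], self._kernels[ix],
                                  mode="same"), ny, nz)
            img += self._rot_inv.rotate(w * self._att[ai], ai)
        return img * self.scale


def forward_project(image: np.ndarray, model: SystemModel) -> np.ndarray:
    """Expected in-window primary counts over all angles."""
    return model.forward(image)


def back_project(projections: np.ndarray, model: SystemModel) -> np.ndarray:
    """Adjoint of :func:`forward_project`."""
    return model.back(projections)
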