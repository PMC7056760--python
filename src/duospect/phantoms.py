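"""Voxelized digital phantoms for the dual-isotope experiments.

Each generator returns a :class:`VoxelPhantom`: per-isotope activity
concentration maps (MBq/ml) plus a material-label map on a common isotropic
grid, centered on the scanner isocenter. These are the ground truth for the
Monte Carlo simulator, the projector, and the quantitative analysis.

Conventions: axes (x, y, z) with z the scanner axis; 0-based indices; voxel
centers at ``(i - (n-1)/2) * voxel`` so the grid is symmetric about the
isocenter. Membership is decided by the voxel-center-inside test unless the
``subsample`` flag requests an antialiased partial-volume fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import MATERIAL_LABELS

#: NEMA IQ sphere diameters (mm), smallest to largest.
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
#: Pitch-circle diameter of the NEMA sphere ring (mm).
NEMA_RING_DIAMETER_MM = 114.4


def sphere_volume_ml(diameter_mm: float) -> float:
    """Analytic sphere volume in ml from a diameter in mm."""
    r_cm = diameter_mm / 20.0
    return 4.0 / 3.0 * np.pi * r_cm ** 3


@dataclass
class VoxelPhantom:
    """Per-isotope activity maps + material labels on a common grid."""

    voxel_mm: float
    activity_ho: np.ndarray  # MBq/ml
    activity_tc: np.ndarray  # MBq/ml
    materials: np.ndarray    # uint8 labels per physics.MATERIAL_LABELS
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity_ho.shape != self.activity_tc.shape or \
                self.activity_ho.shape != self.materials.shape:
            raise ValueError("activity and material maps must share a grid")
        if np.any(self.activity_ho < 0) or np.any(self.activity_tc < 0):
            raise ValueError("activity concentrations must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.activity_ho.shape

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_mm / 10.0) ** 3

    @property
    def total_ho_mbq(self) -> float:
        return float(self.activity_ho.sum() * self.voxel_volume_ml)

    @property
    def total_tc_mbq(self) -> float:
        return float(self.activity_tc.sum() * self.voxel_volume_ml)

    def centers_cm(self):
        """Voxel-center coordinate axes (cm), isocenter at 0."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * self.voxel_mm / 10.0
            for n in self.shape)

    def resample(self, new_voxel_mm: float) -> "VoxelPhantom":
        """Resample to a coarser grid by activity-conserving binning.

        Each fine voxel is assigned to the coarse voxel containing its
        center; concentrations are re-derived from the binned activity, so
        total activity per isotope is conserved exactly. Materials take the
        per-bin majority label.
        """
        f = new_voxel_mm / self.voxel_mm
        new_shape = tuple(int(np.ceil(n / f)) for n in self.shape)
        idx = [np.minimum((np.arange(n) / f).astype(int), m - 1)
               for n, m in zip(self.shape, new_shape)]
        flat = (idx[0][:, None, None] * (new_shape[1] * new_shape[2])
                + idx[1][None, :, None] * new_shape[2]
                + idx[2][None, None, :]).ravel()
        size = int(np.prod(new_shape))
        counts = np.bincount(flat, minlength=size).astype(float)
        vol_ratio = (self.voxel_mm / new_voxel_mm) ** 3

        def bin_conc(conc):
            tot = np.bincount(flat, weights=conc.ravel(), minlength=size)
            return (tot * vol_ratio).reshape(new_shape).astype(conc.dtype)

        mats = np.zeros(size, dtype=np.uint8)
        best = np.full(size, -1.0)
        for name, lab in MATERIAL_LABELS.items():
            cnt = np.bincount(flat, weights=(self.materials.ravel() == lab),
                              minlength=size)
            take = cnt > best
            mats[take] = lab
            best[take] = cnt[take]
        return VoxelPhantom(
            new_voxel_mm, bin_conc(self.activity_ho),
            bin_conc(self.activity_tc), mats.reshape(new_shape),
            {**self.config, "resampled_from_mm": self.voxel_mm})


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _grid(extent_cm: tuple[float, float, float], voxel_mm: float,
          subsample: int = 1):
    """Voxel-center coordinate grids (cm) covering the requested extent."""
    v = voxel_mm / 10.0
    shape = tuple(int(np.ceil(e / v)) for e in extent_cm)
    axes = []
    for n in shape:
        c = (np.arange(n) - (n - 1) / 2.0) * v
        if subsample > 1:
            off = (np.arange(subsample) - (subsample - 1) / 2.0) \
                * v / subsample
            c = (c[:, None] + off[None, :])
        axes.append(c)
    return shape, axes


def _fill_mask(shape, axes, predicate, subsample: int = 1) -> np.ndarray:
    """Fractional occupancy of an analytic region on the voxel grid."""
    if subsample == 1:
        x, y, z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
        return predicate(x, y, z).astype(np.float32)
    acc = np.zeros(shape, dtype=np.float32)
    for i in range(subsample):
        for j in range(subsample):
            for k in range(subsample):
                x, y, z = np.meshgrid(axes[0][:, i], axes[1][:, j],
                                      axes[2][:, k], indexing="ij")
                acc += predicate(x, y, z)
    return acc / subsample ** 3


def _sphere(cx, cy, cz, diameter_mm):
    r = diameter_mm / 20.0
    return lambda x, y, z: (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 \
        <= r ** 2


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_nema_iq(tc_background_kbq_ml: float = 11.0,
                 ho_spheres_mbq_ml: float = 0.8,
                 voxel_mm: float = 2.0,
                 background_volume_l: float = 5.5,
                 subsample: int = 1) -> VoxelPhantom:
    """NEMA image-quality phantom with Ho-filled spheres and Tc background.

    Six spheres (10-37 mm diameter) on the standard 114.4-mm pitch circle
    hold the Ho-166 solution; the Tc-99m background fills the water
    compartment, reduced to 5.5 L by an inert agar region (mirroring the
    agar fill used to bring the conventional 9.7-L compartment down to a
    clinically representative total-activity-to-concentration ratio).
    """
    if voxel_mm > min(NEMA_SPHERE_DIAMETERS_MM) / 3.0:
        raise ValueError(
            f"voxel {voxel_mm} mm cannot resolve the 10-mm sphere "
            "(need >= 3 voxels across)")
    body_a, body_b, height = 14.5, 10.5, 18.0  # cm, simplified IQ body
    shape, axes = _grid((2 * body_a + 2, 2 * body_b + 2, height + 2),
                        voxel_mm, subsample)

    def body(x, y, z):
        return ((x / body_a) ** 2 + (y / body_b) ** 2 <= 1.0) \
            & (np.abs(z) <= height / 2)

    body_frac = _fill_mask(shape, axes, body, subsample)
    vox_ml = (voxel_mm / 10.0) ** 3
    interior_l = float(body_frac.sum()) * vox_ml / 1000.0
    if background_volume_l > interior_l:
        raise ValueError("requested background volume exceeds body interior")

    ho = np.zeros(shape, dtype=np.float32)
    tc = np.zeros(shape, dtype=np.float32)
    sphere_frac = np.zeros(shape, dtype=np.float32)
    ring_r = NEMA_RING_DIAMETER_MM / 20.0
    centers = []
    for k, d in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        ang = np.deg2rad(60.0 * k + 30.0)
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        centers.append((cx, cy, 0.0, d))
        sphere_frac += _fill_mask(shape, axes, _sphere(cx, cy, 0.0, d),
                                  subsample)
    sphere_frac = np.clip(sphere_frac, 0, 1)
    ho += ho_spheres_mbq_ml * sphere_frac

    # agar occupies the bottom (low-y) part of the compartment so that the
    # remaining water background has the requested volume
    bg_frac = np.clip(body_frac - sphere_frac, 0, 1)
    y3 = np.broadcast_to(
        (axes[1][:, 0] if subsample > 1 else axes[1])[None, :, None], shape)
    order = np.argsort(y3.ravel())
    cum = np.cumsum(bg_frac.ravel()[order]) * vox_ml / 1000.0
    agar_l = max(interior_l - background_volume_l, 0.0)
    n_agar = int(np.searchsorted(cum, agar_l))
    agar_mask = np.zeros(bg_frac.size, dtype=bool)
    agar_mask[order[:n_agar]] = True
    agar_mask = agar_mask.reshape(shape) & (bg_frac > 0)

    water_frac = np.where(agar_mask, 0.0, bg_frac)
    tc += tc_background_kbq_ml / 1000.0 * water_frac

    mats = np.zeros(shape, dtype=np.uint8)
    mats[body_frac > 0.5] = MATERIAL_LABELS["water"]
    mats[agar_mask] = MATERIAL_LABELS["agar"]
    return VoxelPhantom(voxel_mm, ho, tc, mats, {
        "phantom": "nema_iq",
        "tc_background_kbq_ml": tc_background_kbq_ml,
        "ho_spheres_mbq_ml": ho_spheres_mbq_ml,
        "background_volume_l": background_volume_l,
        "sphere_centers_cm": centers,
        "nominal_ho_mbq": ho_spheres_mbq_ml * sum(
            sphere_volume_ml(d) for d in NEMA_SPHERE_DIAMETERS_MM),
        "nominal_tc_mbq": tc_background_kbq_ml / 1000.0
        * background_volume_l * 1000.0,
    })


def make_cylinder(volume_l: float = 6.3, tc_activity_mbq: float = 50.0,
                  voxel_mm: float = 2.0, diameter_cm: float = 20.0,
                  subsample: int = 1) -> VoxelPhantom:
    """Homogeneous Tc-filled water cylinder (default 6.3 L, 50 MBq)."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    radius = diameter_cm / 2.0
    height = volume_l * 1000.0 / (np.pi * radius ** 2)
    shape, axes = _grid((diameter_cm + 2, diameter_cm + 2, height + 2),
                        voxel_mm, subsample)

    def cyl(x, y, z):
        return (x ** 2 + y ** 2 <= radius ** 2) & (np.abs(z) <= height / 2)

    frac = _fill_mask(shape, axes, cyl, subsample)
    conc = tc_activity_mbq / (volume_l * 1000.0)  # MBq/ml
    tc = (conc * frac).astype(np.float32)
    mats = np.where(frac > 0.5, MATERIAL_LABELS["water"],
                    MATERIAL_LABELS["air"]).astype(np.uint8)
    return VoxelPhantom(voxel_mm, np.zeros(shape, np.float32), tc, mats, {
        "phantom": "cylinder", "volume_l": volume_l,
        "tc_activity_mbq": tc_activity_mbq,
        "nominal_tc_mbq": tc_activity_mbq,
        "tc_conc_kbq_ml": conc * 1000.0,
    })


def make_line_source_pmma(line_activity_mbq: float = 20.0,
                          voxel_mm: float = 4.0,
                          slab_cm: tuple[float, float, float] = (40, 10, 40),
                          ) -> VoxelPhantom:
    """Tc line source sandwiched between two PMMA slabs.

    A one-voxel-wide line along z sits in a one-voxel air gap between two
    40 x 40 x 10 cm^3 PMMA slabs stacked along y; air elsewhere.
    """
    sx, sy, sz = slab_cm
    v = voxel_mm / 10.0
    shape, axes = _grid((sx + 2, 2 * sy + 3 * v, sz + 2), voxel_mm)
    x, y, z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    gap = v  # one-voxel air gap housing the line
    slabs = (np.abs(x) <= sx / 2) & (np.abs(z) <= sz / 2) \
        & (np.abs(y) >= gap / 2 + 1e-9) & (np.abs(y) <= gap / 2 + sy)
    mats = np.where(slabs, MATERIAL_LABELS["pmma"],
                    MATERIAL_LABELS["air"]).astype(np.uint8)

    line = (np.abs(x) <= v / 2) & (np.abs(y) <= gap / 2) \
        & (np.abs(z) <= sz / 2)
    n_line = int(line.sum())
    if n_line == 0:
        raise ValueError("line does not fit inside the slab gap")
    tc = np.zeros(shape, dtype=np.float32)
    vox_ml = v ** 3  # cm^3 == ml
    tc[line] = line_activity_mbq / (n_line * vox_ml)
    return VoxelPhantom(voxel_mm, np.zeros(shape, np.float32), tc, mats, {
        "phantom": "line_source_pmma",
        "line_activity_mbq": line_activity_mbq,
        "nominal_tc_mbq": line_activity_mbq,
        "slab_cm": list(slab_cm),
    })


def make_torso(ho_insert: tuple[float, float] = (130.0, 53.0),
               liver: tuple[float, float] = (1200.0, 34.0),
               voxel_mm: float = 2.0,
               subsample: int = 1) -> VoxelPhantom:
    """Anthropomorphic torso surrogate: water body, Tc liver, Ho insert.

    ``ho_insert`` is (volume ml, activity MBq): default 130 ml / 53 MBq,
    i.e. ~0.41 MBq/ml. ``liver`` is (volume ml, Tc concentration kBq/ml):
    default 1200 ml at 34 kBq/ml. The body is an elliptical water cylinder;
    the liver an off-center ellipsoid; the insert a sphere inside the liver.
    """
    ins_vol, ins_act = ho_insert
    liv_vol, liv_conc_kbq = liver
    body_a, body_b, height = 15.0, 10.0, 20.0
    shape, axes = _grid((2 * body_a + 2, 2 * body_b + 2, height + 2),
                        voxel_mm, subsample)

    def body(x, y, z):
        return ((x / body_a) ** 2 + (y / body_b) ** 2 <= 1.0) \
            & (np.abs(z) <= height / 2)

    # liver ellipsoid with the requested volume, fixed axis ratios
    ratios = np.array([1.45, 1.18, 1.0])
    c = (liv_vol * 3.0 / (4.0 * np.pi * ratios.prod())) ** (1.0 / 3.0)
    la, lb, lc = ratios * c
    lcx, lcy, lcz = 5.0, 2.0, 0.0

    def liver_fn(x, y, z):
        return ((x - lcx) / la) ** 2 + ((y - lcy) / lb) ** 2 \
            + ((z - lcz) / lc) ** 2 <= 1.0

    ins_r = (ins_vol * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if ins_r >= min(la, lb, lc):
        raise ValueError("insert does not fit inside the liver")

    def insert_fn(x, y, z):
        return (x - lcx) ** 2 + (y - lcy) ** 2 + (z - lcz) ** 2 <= ins_r ** 2

    body_frac = _fill_mask(shape, axes, body, subsample)
    liver_frac = _fill_mask(shape, axes, liver_fn, subsample)
    insert_frac = _fill_mask(shape, axes, insert_fn, subsample)

    ho = (ins_act / ins_vol * insert_frac).astype(np.float32)
    tc = (liv_conc_kbq / 1000.0
          * np.clip(liver_frac - insert_frac, 0, 1)).astype(np.float32)
    mats = np.where(body_frac > 0.5, MATERIAL_LABELS["water"],
                    MATERIAL_LABELS["air"]).astype(np.uint8)
    return VoxelPhantom(voxel_mm, ho, tc, mats, {
        "phantom": "torso",
        "insert_ml": ins_vol, "insert_mbq": ins_act,
        "insert_conc_mbq_ml": ins_act / ins_vol,
        "liver_ml": liv_vol, "liver_tc_kbq_ml": liv_conc_kbq,
        "nominal_ho_mbq": ins_act,
        # the insert displaces liver volume, so the Tc solution fills
        # (liver - insert) ml at the stated concentration
        "nominal_tc_mbq": liv_conc_kbq / 1000.0 * (liv_vol - ins_vol),
        "insert_center_cm": (lcx, lcy, lcz),
        "insert_radius_cm": ins_r,
    })
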