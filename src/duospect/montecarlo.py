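"""Monte Carlo photon-history simulator with PSF-table detection.

Photon histories are sampled from the phantom's activity maps and
transported through the voxelized attenuation map with Woodcock (delta)
tracking and analog Compton/photoelectric interaction sampling. Detection
uses forced detection: at the emission point and at every real scatter
vertex, the expected contribution toward every camera angle is accumulated
deterministically — the Beer-Lambert exit attenuation, the Klein-Nishina
directional probability (for scatter vertices), and the appropriate PSF
kernel (direct, weighted by the in-window detection probability, when the
photon energy lies in the window; otherwise the tabulated indirect kernel
for its energy bin). A "measured-like" acquisition is obtained by Poisson
sampling this expectation.

Counts scale as activity (MBq) x 1e6 x photons/decay x time-per-angle, so
doubling activity or acquisition time doubles the expectation exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .geometry import AcquisitionGeometry
from .phantoms import VoxelPhantom
from .physics import (
    AttenuationModel,
    DetectorModel,
    EmissionSpectrum,
    MATERIAL_LABELS,
    detection_probability,
    klein_nishina_total,
    sample_compton_energies,
    spectrum,
)
from .psf import (
    PSF_DISTANCES,
    PSF_SOURCE_ENERGIES,
    PSFTable,
    psf_energy_bin_indices,
)

_PSF_E_MIN, _PSF_E_MAX = 60.0, 2000.0


@dataclass
class ProjectionSet:
    """Per-window count images over the camera angles."""

    counts: dict[str, np.ndarray]  # label -> (n_angles, nu, nv)
    geom: AcquisitionGeometry
    seed: int | None = None
    n_histories: int = 0
    poisson: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab, arr in self.counts.items():
            if arr.shape != (self.geom.n_angles, self.geom.nu, self.geom.nv):
                raise ValueError(f"window {lab!r} has wrong projection shape")
            if np.any(arr < 0):
                raise ValueError("counts must be nonnegative")

    def total(self, label: str) -> float:
        return float(self.counts[label].sum())


@dataclass
class ScatterEstimate:
    """Expected (noise-free) additive counts in one window."""

    counts: np.ndarray  # (n_angles, nu, nv)
    window_label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("scatter estimate must be nonnegative")


def window_count_ratio(proj: ProjectionSet, wa: str, wb: str) -> float:
    """Total counts in window ``wa`` divided by total counts in ``wb``."""
    return proj.total(wa) / proj.total(wb)


class _Accumulator:
    """Impulse images per (window, kernel-class, distance-knot), convolved
    with the matching kernel only once at the end."""

    def __init__(self, geom: AcquisitionGeometry,
                 tables: dict[str, PSFTable]):
        self.geom = geom
        self.tables = tables
        self.buf: dict[tuple, np.ndarray] = {}

    def deposit(self, wl: str, cls: np.ndarray, knot0: np.ndarray,
                knot1: np.ndarray, kw: np.ndarray, ai: int,
                u: np.ndarray, v: np.ndarray, w: np.ndarray) -> None:
        """cls: -1 for direct, else PSF-energy index; bilinear in (u, v)."""
        g = self.geom
        iu0 = np.floor(u).astype(np.int64)
        iv0 = np.floor(v).astype(np.int64)
        fu, fv = u - iu0, v - iv0
        for cval in np.unique(cls):
            m = cls == cval
            for knot, kfrac in ((knot0[m], 1.0 - kw[m]), (knot1[m], kw[m])):
                for kn in np.unique(knot):
                    mm = knot == kn
                    key = (wl, int(cval), int(kn))
                    if key not in self.buf:
                        self.buf[key] = np.zeros(
                            (g.n_angles, g.nu, g.nv))
                    tgt = self.buf[key][ai]
                    ww = (w[m] * kfrac)[mm]
                    for du, dv, bw in (
                            (0, 0, (1 - fu[m][mm]) * (1 - fv[m][mm])),
                            (1, 0, fu[m][mm] * (1 - fv[m][mm])),
                            (0, 1, (1 - fu[m][mm]) * fv[m][mm]),
                            (1, 1, fu[m][mm] * fv[m][mm])):
                        uu = iu0[m][mm] + du
                        vv = iv0[m][mm] + dv
                        ok = (uu >= 0) & (uu < g.nu) & (vv >= 0) & (vv < g.nv)
                        np.add.at(tgt, (uu[ok], vv[ok]), (ww * bw)[ok])

    def finalize(self) -> dict[str, np.ndarray]:
        g = self.geom
        out = {w.label: np.zeros((g.n_angles, g.nu, g.nv))
               for w in g.windows}
        for (wl, cval, kn), imp in self.buf.items():
            table = self.tables[wl]
            dist = PSF_DISTANCES[kn]
            if cval < 0:
                kern = table.direct[dist]
            else:
                kern = table.indirect[(PSF_SOURCE_ENERGIES[cval], dist)]
            out[wl] += fftconvolve(imp, kern[None], mode="same",
                                   axes=(1, 2))
        return {k: np.clip(v, 0.0, None) for k, v in out.items()}


class _Transport:
    """Vectorized photon transport state over one phantom grid."""

    def __init__(self, phantom: VoxelPhantom, atten: AttenuationModel,
                 ray_step_cm: float = 0.4):
        self.labels = phantom.materials
        self.shape = np.array(phantom.materials.shape)
        self.voxel_cm = phantom.voxel_mm / 10.0
        self.atten = atten
        self.ray_step = ray_step_cm
        self.half = (self.shape - 1) / 2.0
        self.names = list(MATERIAL_LABELS)

    def mu_events(self, energies: np.ndarray) -> np.ndarray:
        """(n_materials, n_events) linear attenuation at event energies."""
        e = np.clip(energies, _PSF_E_MIN, _PSF_E_MAX)
        return np.stack([self.atten.mu(n, e) for n in self.names])

    def labels_at(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Material labels at positions (cm, isocenter origin); also an
        inside-grid mask. Outside positions read as air."""
        idx = np.round(pos / self.voxel_cm + self.half).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < self.shape), axis=-1)
        idx = np.clip(idx, 0, self.shape - 1)
        lab = self.labels[idx[..., 0], idx[..., 1], idx[..., 2]]
        return np.where(inside, lab, MATERIAL_LABELS["air"]), inside

    def exit_attenuation(self, pos: np.ndarray, direction: np.ndarray,
                         mu_mat: np.ndarray) -> np.ndarray:
        """exp(-integral of mu) from each position to the grid boundary
        along a common direction; mu_mat is (n_materials, n_events)."""
        n = pos.shape[0]
        ext = self.half * self.voxel_cm + self.voxel_cm
        # distance to leave the bounding box along `direction`
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (ext - pos) / direction
            t2 = (-ext - pos) / direction
        tmax = np.nanmin(np.where(np.abs(direction) > 1e-12,
                                  np.maximum(t1, t2), np.inf), axis=1)
        tmax = np.clip(tmax, 0, None)
        path = np.zeros(n)
        n_steps = int(np.ceil(tmax.max() / self.ray_step)) if n else 0
        ev = np.arange(n)
        for k in range(n_steps):
            t = (k + 0.5) * self.ray_step
            act = t < tmax
            if not act.any():
                break
            p = pos[act] + t * direction[None, :]
            lab, inside = self.labels_at(p)
            seg = np.minimum(self.ray_step, (tmax[act] - t) + 0.5
                             * self.ray_step)
            path[act] += np.where(inside, mu_mat[lab, ev[act]] * seg, 0.0)
        return np.exp(-path)


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    ct = rng.uniform(-1, 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    st = np.sqrt(1 - ct ** 2)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])


def _rotate_about(direction: np.ndarray, cos_t: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """New unit vectors at polar angle arccos(cos_t) around `direction`."""
    n = direction.shape[0]
    phi = rng.uniform(0, 2 * np.pi, n)
    st = np.sqrt(np.clip(1 - cos_t ** 2, 0, 1))
    # orthonormal frame around each direction
    a = np.where(np.abs(direction[:, 2:3]) < 0.9,
                 np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    e1 = np.cross(direction, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(direction, e1)
    out = (cos_t[:, None] * direction
           + st[:, None] * (np.cos(phi)[:, None] * e1
                            + np.sin(phi)[:, None] * e2))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _score_vertices(acc: _Accumulator, trans: _Transport,
                    geom: AcquisitionGeometry, det: DetectorModel,
                    pos: np.ndarray, energies: np.ndarray,
                    weights: np.ndarray,
                    incoming: np.ndarray | None,
                    compton_prob: np.ndarray | None,
                    exclude_unscattered_in_window: bool = False) -> None:
    """Forced-detection scoring of a batch of vertices to every angle.

    ``incoming`` is None for emission vertices (isotropic) and the current
    flight direction for scatter vertices, in which case the toward-detector
    energy and Klein-Nishina weight vary per angle.
    """
    if pos.shape[0] == 0:
        return
    angles = geom.angles_rad
    u_half = (geom.nu - 1) / 2.0
    v_half = (geom.nv - 1) / 2.0
    kn_tot = None if incoming is None else klein_nishina_total(energies)
    for ai, a in enumerate(angles):
        nvec = np.array([np.cos(a), np.sin(a), 0.0])
        tvec = np.array([-np.sin(a), np.cos(a), 0.0])
        if incoming is None:
            e_out = energies
            w_dir = weights
        else:
            cos_t = incoming @ nvec
            e_out = (energies /
                     (1.0 + energies / 510.99895 * (1.0 - cos_t)))
            diff = _kn_diff_mixed(energies, cos_t)
            w_dir = weights * compton_prob * 4.0 * np.pi * diff / kn_tot
        live = (e_out >= _PSF_E_MIN) & (e_out <= _PSF_E_MAX) & (w_dir > 0)
        if not live.any():
            continue
        p = pos[live]
        e = e_out[live]
        w = w_dir[live]
        mu_mat = trans.mu_events(e)
        w = w * trans.exit_attenuation(p, nvec, mu_mat)
        dist = np.clip(geom.radius_cm - p @ nvec,
                       PSF_DISTANCES[0], PSF_DISTANCES[-1])
        k0 = np.searchsorted(PSF_DISTANCES, dist, side="right") - 1
        k0 = np.clip(k0, 0, len(PSF_DISTANCES) - 2)
        d0 = np.asarray(PSF_DISTANCES)[k0]
        d1 = np.asarray(PSF_DISTANCES)[k0 + 1]
        kw = np.clip((dist - d0) / (d1 - d0), 0.0, 1.0)
        u = (p @ tvec) / geom.pitch_cm + u_half
        v = p[:, 2] / geom.pitch_cm + v_half
        for wl, table in acc.tables.items():
            win = table.window
            in_win = np.asarray(win.contains(e))
            cls = np.where(in_win, -1, psf_energy_bin_indices(e))
            wdep = np.where(in_win,
                            w * detection_probability(e, win, det), w)
            if exclude_unscattered_in_window and incoming is None:
                # primaries already inside the window carry no crosstalk
                wdep = np.where(in_win, 0.0, wdep)
            keep = wdep > 0
            acc.deposit(wl, cls[keep], k0[keep], k0[keep] + 1,
                        kw[keep], ai, u[keep], v[keep], wdep[keep])


def _kn_diff_mixed(energies: np.ndarray, cos_t: np.ndarray) -> np.ndarray:
    """Klein-Nishina differential cross-section with per-event energies."""
    alpha = energies / 510.99895
    ratio = 1.0 / (1.0 + alpha * (1.0 - cos_t))
    return 0.5 * ratio ** 2 * (ratio + 1.0 / ratio - (1.0 - cos_t ** 2))


def simulate_projections(phantom: VoxelPhantom,
                         psf_tables: dict[str, PSFTable],
                         geom: AcquisitionGeometry,
                         n_histories: int = 20000,
                         seed: int | None = None,
                         poisson: bool = False,
                         spectra: dict[str, EmissionSpectrum] | None = None,
                         det: DetectorModel | None = None,
                         atten: AttenuationModel | None = None,
                         scatter: bool = True,
                         max_scatters: int = 10,
                         energy_cutoff_kev: float = 50.0,
                         ray_step_cm: float = 0.4,
                         exclude_unscattered_in_window: bool = False,
                         ) -> ProjectionSet:
    """Simulate per-window projection counts for a phantom.

    Histories are sampled proportionally to voxel activity per isotope;
    counts are scaled to the phantom's total activity and the geometry's
    per-angle acquisition time. With ``poisson`` the expectation is Poisson
    sampled (integer counts); otherwise noise-free expectations are
    returned. ``scatter=False`` disables in-phantom transport (emissions
    are scored and the history ends). ``exclude_unscattered_in_window``
    drops the direct-detection contribution of unscattered in-window
    photons (used for self-scatter estimates).
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be positive")
    rng = np.random.default_rng(seed)
    det = det or DetectorModel()
    atten = atten or AttenuationModel()
    spectra = spectra or {"Ho166": spectrum("Ho166"),
                          "Tc99m": spectrum("Tc99m")}
    trans = _Transport(phantom, atten, ray_step_cm)
    acc = _Accumulator(geom, psf_tables)

    sources = []
    if phantom.total_ho_mbq > 0:
        sources.append(("Ho166", phantom.activity_ho, phantom.total_ho_mbq))
    if phantom.total_tc_mbq > 0:
        sources.append(("Tc99m", phantom.activity_tc, phantom.total_tc_mbq))
    if not sources:
        warnings.warn("phantom has no activity; returning zero counts")

    for iso, act, total_mbq in sources:
        spec = spectra[iso]
        w0 = (total_mbq * 1e6 * geom.time_per_angle_s
              * spec.photons_per_decay / n_histories)
        # emission sites proportional to voxel activity
        p = act.ravel().astype(np.float64)
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        flat = np.searchsorted(cdf, rng.random(n_histories))
        ijk = np.column_stack(np.unravel_index(flat, phantom.shape))
        pos = ((ijk - trans.half) + rng.uniform(-0.5, 0.5,
                                                ijk.shape)) * trans.voxel_cm
        energies = spec.sample(n_histories, rng)
        weights = np.full(n_histories, w0)

        _score_vertices(acc, trans, geom, det, pos, energies, weights,
                        None, None, exclude_unscattered_in_window)
        if not scatter:
            continue
        directions = _isotropic_directions(n_histories, rng)
        for _ in range(max_scatters):
            pos, energies, weights, directions = _transport_step(
                trans, rng, pos, energies, weights, directions,
                acc, geom, det, energy_cutoff_kev)
            if pos.shape[0] == 0:
                break

    counts = acc.finalize()
    if poisson:
        counts = {k: rng.poisson(v).astype(np.float64)
                  for k, v in counts.items()}
    return ProjectionSet(counts, geom, seed=seed, n_histories=n_histories,
                         poisson=poisson,
                         meta={"isotopes": [s[0] for s in sources],
                               "scatter": scatter,
                               "exclude_unscattered_in_window":
                               exclude_unscattered_in_window})


def _transport_step(trans: _Transport, rng, pos, energies, weights,
                    directions, acc, geom, det, cutoff):
    """Woodcock-track one collision generation; score scatter vertices and
    return the surviving (post-scatter) photon batch."""
    n = pos.shape[0]
    mu_mat = trans.mu_events(energies)
    mu_max = mu_mat.max(axis=0)
    alive = np.ones(n, dtype=bool)
    collided = np.zeros(n, dtype=bool)
    cur = pos.copy()
    for _ in range(200):
        act = alive & ~collided
        if not act.any():
            break
        idx = np.where(act)[0]
        s = -np.log(rng.random(idx.size)) / mu_max[idx]
        cur[idx] = cur[idx] + s[:, None] * directions[idx]
        lab, inside = trans.labels_at(cur[idx])
        alive[idx[~inside]] = False
        ins = idx[inside]
        if ins.size == 0:
            continue
        mu_here = mu_mat[lab[inside], ins]
        real = rng.random(ins.size) < mu_here / mu_max[ins]
        collided[ins[real]] = True
    hit = np.where(collided & alive)[0]
    if hit.size == 0:
        return (np.zeros((0, 3)), np.zeros(0), np.zeros(0),
                np.zeros((0, 3)))
    e = energies[hit]
    pe_frac = np.atleast_1d(trans.atten.photoelectric_fraction(
        np.clip(e, _PSF_E_MIN, _PSF_E_MAX)))
    p_compton = 1.0 - pe_frac
    # forced-detection scoring of the Compton branch at this vertex
    _score_vertices(acc, trans, geom, det, cur[hit], e, weights[hit],
                    directions[hit], p_compton)
    # analog continuation
    surv = rng.random(hit.size) < p_compton
    hit = hit[surv]
    if hit.size == 0:
        return (np.zeros((0, 3)), np.zeros(0), np.zeros(0),
                np.zeros((0, 3)))
    e_new, cos_t = sample_compton_energies(energies[hit], rng)
    new_dir = _rotate_about(directions[hit], cos_t, rng)
    keep = e_new >= cutoff
    return (cur[hit][keep], e_new[keep], weights[hit][keep],
            new_dir[keep])


def simulate_downscatter(tc_image_mbq_ml: np.ndarray, voxel_mm: float,
                         materials: np.ndarray, psf_table: PSFTable,
                         geom: AcquisitionGeometry,
                         n_histories: int = 20000,
                         seed: int | None = None,
                         det: DetectorModel | None = None,
                         atten: AttenuationModel | None = None,
                         ray_step_cm: float = 0.4) -> ScatterEstimate:
    """Expected Tc-99m downscatter counts in the Ho photopeak window.

    Runs the forced-detection simulator with the Tc spectrum over the given
    Tc activity image and returns the noise-free 81-keV-window expectation,
    linear in the input image.
    """
    if np.any(tc_image_mbq_ml < 0):
        raise ValueError("Tc image must be nonnegative")
    wl = psf_table.window.label
    if float(tc_image_mbq_ml.sum()) == 0.0:
        z = np.zeros((geom.n_angles, geom.nu, geom.nv))
        return ScatterEstimate(z, wl, {"n_histories": 0, "seed": seed})
    ph = VoxelPhantom(voxel_mm, np.zeros_like(tc_image_mbq_ml),
                      tc_image_mbq_ml.astype(np.float32), materials)
    proj = simulate_projections(
        ph, {wl: psf_table}, geom, n_histories=n_histories, seed=seed,
        poisson=False, det=det, atten=atten, ray_step_cm=ray_step_cm)
    return ScatterEstimate(proj.counts[wl], wl,
                           {"n_histories": n_histories, "seed": seed,
                            "source": "Tc99m"})
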