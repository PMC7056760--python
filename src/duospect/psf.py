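"""Energy- and distance-indexed point-spread-function lookup tables.

The camera response for detection in a given energy window is represented by
a small library of 2-D kernels: one *direct* kernel family (photons whose
incident energy already lies inside the window) and *indirect* kernels for
eight source energies x five source-collimator distances (photons outside
the window that can still produce an in-window count through a collimator or
crystal interaction: resolution tails, lead K x-rays, septal penetration
with partial energy deposition).

Kernels come from a parameterized analytic model of a medium-energy
parallel-hole collimator rather than a full radiation-transport simulation
of the collimator:

* geometric core — Gaussian, FWHM = d (l_eff + z + b) / l_eff growing
  linearly with source distance z; l_eff is the septal-penetration-corrected
  hole length, d the hole diameter, b the collimator-to-crystal gap;
* lead x-ray component — active only for source energies above the 88-keV
  Pb K-edge, feeding windows that overlap the 73-85 keV K-x-ray lines;
* penetration tail — broad exponential whose amplitude follows the lead
  transmission exp(-mu_Pb(E) t_eff), dominant for the MeV-range emissions.

Component amplitudes are config parameters with documented defaults; they
are deliberately simple stand-ins for a full collimator simulation and set
the absolute scale of crosstalk predictions (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .physics import (
    AttenuationModel,
    DetectorModel,
    EnergyWindow,
    detection_probability,
)

log = logging.getLogger(__name__)

#: Tabulated PSF source energies (keV) and the half-open photon-energy bins
#: [lo, hi) that map onto them; the last bin includes its upper edge.
PSF_SOURCE_ENERGIES = (81.0, 95.0, 118.0, 140.0, 170.0, 300.0, 713.0, 1379.0)
PSF_BIN_EDGES = (60.0, 88.0, 106.0, 129.0, 154.0, 226.0, 462.0, 992.0, 2000.0)

#: Source-collimator distances (cm) at which kernels are stored.
PSF_DISTANCES = (1.0, 5.0, 12.0, 24.0, 40.0)

#: Pb K x-ray lines (keV) with approximate relative intensities.
_PB_XRAYS = ((72.80, 0.28), (74.97, 0.47), (84.94, 0.25))


def psf_energy_bin(photon_energy: float) -> float:
    """Map a photon energy to its tabulated PSF source energy.

    Bins are half-open, lower edge inclusive; the top bin includes 2000 keV.
    """
    e = float(photon_energy)
    edges = PSF_BIN_EDGES
    if e < edges[0] or e > edges[-1]:
        raise ValueError(
            f"photon energy {e} keV outside PSF range "
            f"{edges[0]}-{edges[-1]} keV"
        )
    idx = min(int(np.searchsorted(edges, e, side="right")) - 1,
              len(PSF_SOURCE_ENERGIES) - 1)
    return PSF_SOURCE_ENERGIES[idx]


def psf_energy_bin_indices(photon_energies: np.ndarray) -> np.ndarray:
    """Vectorized bin lookup returning indices into PSF_SOURCE_ENERGIES."""
    e = np.asarray(photon_energies, dtype=float)
    edges = np.asarray(PSF_BIN_EDGES)
    if np.any(e < edges[0]) or np.any(e > edges[-1]):
        raise ValueError("photon energy outside PSF range 60-2000 keV")
    return np.minimum(np.searchsorted(edges, e, side="right") - 1,
                      len(PSF_SOURCE_ENERGIES) - 1)


@dataclass(frozen=True)
class CollimatorParams:
    """Analytic medium-energy parallel-hole collimator model parameters.

    Geometry defaults follow a typical medium-energy low-penetration
    design (hexagonal holes, cast lead). Amplitudes:

    ``xray_amplitude``  — Pb K-x-ray counts per photon headed toward the
    detector, relative to the 140-keV geometric efficiency, before the
    energy scaling (140/E)^2.5 that tracks the falling photoelectric
    cross-section in lead.

    ``penetration_amplitude`` — in-window counts per photon toward the
    detector per 100 keV of window width, before the lead-transmission
    factor exp(-mu_Pb(E) * penetration_path_cm).
    """

    hole_diameter_cm: float = 0.294
    hole_length_cm: float = 4.06
    septal_thickness_cm: float = 0.114
    gap_cm: float = 1.0
    intrinsic_fwhm_cm: float = 0.38
    sensitivity_constant: float = 0.26
    xray_amplitude: float = 0.35
    penetration_amplitude: float = 0.0045
    penetration_path_cm: float = 0.6
    tail_scale_cm: float = 1.5
    tail_distance_slope: float = 0.08


@dataclass(frozen=True)
class PSFKernel:
    """A 2-D detector-plane kernel; entries sum to the detection efficiency
    (counts per photon traveling toward the detector)."""

    array: np.ndarray
    pitch_cm: float

    @property
    def total_efficiency(self) -> float:
        return float(self.array.sum())

    def fwhm_cm(self) -> float:
        """FWHM of the central row profile (linear interpolation)."""
        prof = self.array[self.array.shape[0] // 2]
        prof = prof / prof.max()
        above = np.where(prof >= 0.5)[0]
        lo, hi = above[0], above[-1]

        def edge(i, j):
            return i + (0.5 - prof[i]) / (prof[j] - prof[i]) * (j - i)

        left = edge(lo, lo - 1) if lo > 0 else lo
        right = edge(hi, hi + 1) if hi < prof.size - 1 else hi
        return abs(right - left) * self.pitch_cm


class PSFTable:
    """Kernels for one energy window: indirect (8 energies x 5 distances)
    plus a direct family vs distance."""

    def __init__(self, window: EnergyWindow, pitch_cm: float,
                 indirect: dict[tuple[float, float], np.ndarray],
                 direct: dict[float, np.ndarray],
                 params: CollimatorParams | None = None) -> None:
        self.window = window
        self.pitch_cm = pitch_cm
        self.indirect = indirect
        self.direct = direct
        self.params = params
        for arr in list(indirect.values()) + list(direct.values()):
            if np.any(arr < 0):
                raise ValueError("PSF kernels must be nonnegative")
            if arr.sum() > 1.0 + 1e-9:
                raise ValueError("kernel efficiency exceeds 1")

    @property
    def kernel_shape(self) -> tuple[int, int]:
        return next(iter(self.direct.values())).shape

    @staticmethod
    def distance_weights(distance: float) -> tuple[int, int, float]:
        """Bracketing knot indices and blend weight for a distance (clamped
        to the tabulated 1-40 cm range, with a warning outside)."""
        d = float(distance)
        knots = PSF_DISTANCES
        if d < knots[0] or d > knots[-1]:
            warnings.warn(
                f"distance {d} cm outside tabulated {knots[0]}-{knots[-1]} cm;"
                " clamping", stacklevel=2)
            d = min(max(d, knots[0]), knots[-1])
        i1 = int(np.searchsorted(knots, d))
        if i1 == 0:
            return 0, 0, 0.0
        i0 = i1 - 1
        if i1 >= len(knots):
            return len(knots) - 1, len(knots) - 1, 0.0
        w = (d - knots[i0]) / (knots[i1] - knots[i0])
        return i0, i1, float(w)

    def _blend(self, family: dict, key0, key1, w: float) -> np.ndarray:
        if w == 0.0:
            return family[key0]
        return (1.0 - w) * family[key0] + w * family[key1]

    def kernel(self, photon_energy: float, distance: float,
               direct: bool = False) -> PSFKernel:
        """Kernel for a photon, linearly blended in distance.

        ``direct=True`` returns the direct family kernel (caller applies the
        detection-probability weight); otherwise the indirect kernel for the
        photon's tabulated source energy.
        """
        i0, i1, w = self.distance_weights(distance)
        d0, d1 = PSF_DISTANCES[i0], PSF_DISTANCES[i1]
        if direct:
            arr = self._blend(self.direct, d0, d1, w)
        else:
            es = psf_energy_bin(photon_energy)
            arr = self._blend(self.indirect, (es, d0), (es, d1), w)
        return PSFKernel(arr, self.pitch_cm)


def psf_for(photon_energy: float, distance: float, table: PSFTable,
            direct: bool = False) -> PSFKernel:
    """Functional wrapper around :meth:`PSFTable.kernel`."""
    return table.kernel(photon_energy, distance, direct=direct)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _radial_grids(size: int, pitch_cm: float):
    half = size // 2
    ax = (np.arange(size) - half) * pitch_cm
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return np.hypot(xx, yy)


def _gaussian_kernel(r: np.ndarray, fwhm_cm: float, pitch_cm: float,
                     efficiency: float) -> np.ndarray:
    sigma = max(fwhm_cm, 1e-3) / 2.354820045
    k = np.exp(-0.5 * (r / sigma) ** 2)
    return k / k.sum() * efficiency


def _exponential_kernel(r: np.ndarray, scale_cm: float, pitch_cm: float,
                        efficiency: float) -> np.ndarray:
    k = np.exp(-r / max(scale_cm, 1e-3))
    return k / k.sum() * efficiency


def _mean_out_of_window_detprob(lo: float, hi: float, window: EnergyWindow,
                                det: DetectorModel, n: int = 256) -> float:
    """Average resolution-tail detection probability over the out-of-window
    part of a photon-energy band."""
    e = np.linspace(lo, min(hi, 1999.0), n)
    mask = ~window.contains(e)
    if not mask.any():
        return 0.0
    p = detection_probability(e[mask], window, det)
    # average over the full band: in-window photons are handled directly
    return float(p.sum() / n)


def generate_psf_table(params: CollimatorParams | None = None,
                       det: DetectorModel | None = None,
                       window: EnergyWindow | None = None,
                       pitch_cm: float = 0.48,
                       size: int = 41,
                       atten: AttenuationModel | None = None) -> PSFTable:
    """Build the kernel table for one acquisition window.

    Produces indirect kernels for the 8 tabulated source energies at the 5
    tabulated distances, plus the direct kernel family. Kernels are not
    renormalized after grid truncation; the truncation loss of the broadest
    kernel is logged.
    """
    params = params or CollimatorParams()
    det = det or DetectorModel()
    window = window or EnergyWindow("ho81", 81.0, 0.15)
    atten = atten or AttenuationModel()
    if params.hole_diameter_cm <= 0 or params.hole_length_cm <= 0:
        raise ValueError("collimator hole geometry must be positive")
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    r = _radial_grids(size, pitch_cm)

    d, length, t = (params.hole_diameter_cm, params.hole_length_cm,
                    params.septal_thickness_cm)

    def l_eff(e):
        return max(length - 2.0 / atten.mu_lead(e), 0.5 * length)

    def fwhm_geo(e, z):
        return d * (l_eff(e) + z + params.gap_cm) / l_eff(e)

    def eff_geo(e):
        le = l_eff(e)
        return (params.sensitivity_constant * d ** 2 / (le * (d + t))) ** 2

    eff_geo_ref = eff_geo(140.0)

    # window overlap of the Pb K x-ray lines, resolution-weighted
    xray_overlap = sum(
        w * detection_probability(e, window, det) for e, w in _PB_XRAYS)

    def components(es: float, z: float, kind: str) -> np.ndarray:
        fg = np.hypot(fwhm_geo(es, z), params.intrinsic_fwhm_cm)
        pen_eff = (params.penetration_amplitude
                   * np.exp(-atten.mu_lead(es) * params.penetration_path_cm)
                   * window.width_kev / 100.0)
        tail = _exponential_kernel(
            r, (params.tail_scale_cm + params.tail_distance_slope * z)
            * (es / 140.0) ** 0.3, pitch_cm, pen_eff)
        if kind == "direct":
            core = _gaussian_kernel(r, fg, pitch_cm,
                                    eff_geo(es) * det.crystal_efficiency)
            return core + tail
        # indirect: resolution tail + lead x-rays (above the K-edge)
        i = list(PSF_SOURCE_ENERGIES).index(es)
        band = (PSF_BIN_EDGES[i], PSF_BIN_EDGES[i + 1])
        res_eff = (eff_geo(es) * det.crystal_efficiency
                   * _mean_out_of_window_detprob(*band, window, det))
        core = _gaussian_kernel(r, fg, pitch_cm, res_eff)
        if es >= 88.0 and xray_overlap > 0:
            xr_eff = (params.xray_amplitude * eff_geo_ref * xray_overlap
                      * min((140.0 / es) ** 2.5, 1.5))
            core = core + _gaussian_kernel(r, 1.2 * fg, pitch_cm, xr_eff)
        return core + tail

    indirect = {}
    for es in PSF_SOURCE_ENERGIES:
        for z in PSF_DISTANCES:
            indirect[(es, z)] = _truncate(components(es, z, "indirect"))
    direct = {z: _truncate(components(window.center, z, "direct"))
              for z in PSF_DISTANCES}

    broad = indirect[(PSF_SOURCE_ENERGIES[-1], PSF_DISTANCES[-1])]
    edge = float(broad[0].sum() + broad[-1].sum()
                 + broad[:, 0].sum() + broad[:, -1].sum())
    log.info("PSF table (%s): broadest kernel edge mass %.2e of efficiency "
             "%.2e (grid truncation, not renormalized)",
             window.label, edge, broad.sum())
    return PSFTable(window, pitch_cm, indirect, direct, params)


def _truncate(arr: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    """Zero entries below ``rel`` of the peak; no renormalization.

    Kernels whose total efficiency is numerically negligible (< 1e-12
    counts/photon, i.e. far below any physical channel) are zeroed
    outright so that disabled pathways contribute exactly nothing.
    """
    if arr.sum() < 1e-12:
        return np.zeros_like(arr)
    out = arr.copy()
    out[out < rel * out.max()] = 0.0
    return out
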