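"""Photon physics for dual-isotope SPECT simulation.

Covers isotope emission spectra (Ho-166 with its gamma lines and a coarse
bremsstrahlung continuum, Tc-99m), acquisition energy windows, the gamma
camera's Gaussian energy response, attenuation in phantom materials, and
Klein-Nishina Compton sampling. These primitives are shared by the Monte
Carlo simulator, the PSF generator and the deterministic projector.

Energies are in keV, distances in cm, linear attenuation in 1/cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import ndtr

ELECTRON_REST_KEV = 510.99895
ENERGY_RANGE_KEV = (60.0, 2000.0)


# ---------------------------------------------------------------------------
# Energy windows
# ---------------------------------------------------------------------------

def window_bounds(center: float, width_fraction: float) -> tuple[float, float]:
    """Lower/upper bound of a fractional-width acquisition window.

    A window of center ``c`` and width fraction ``w`` accepts deposited
    energies in ``[c*(1 - w/2), c*(1 + w/2)]``.
    """
    if center <= 0:
        raise ValueError(f"window center must be positive, got {center}")
    if not 0 < width_fraction < 1:
        raise ValueError(
            f"width fraction must be in (0, 1), got {width_fraction}"
        )
    return center * (1 - width_fraction / 2), center * (1 + width_fraction / 2)


@dataclass(frozen=True)
class EnergyWindow:
    """An acquisition energy window defined by center and fractional width."""

    label: str
    center: float
    width_fraction: float

    def __post_init__(self) -> None:
        window_bounds(self.center, self.width_fraction)  # validates

    @property
    def bounds(self) -> tuple[float, float]:
        return window_bounds(self.center, self.width_fraction)

    @property
    def lo(self) -> float:
        return self.bounds[0]

    @property
    def hi(self) -> float:
        return self.bounds[1]

    @property
    def width_kev(self) -> float:
        return self.center * self.width_fraction

    def contains(self, energy) -> np.ndarray | bool:
        lo, hi = self.bounds
        return (np.asarray(energy) >= lo) & (np.asarray(energy) <= hi)


def standard_windows() -> dict[str, EnergyWindow]:
    """The clinical dual-isotope window set.

    Photopeaks at 81 keV (Ho-166) and 140 keV (Tc-99m), both 15% wide, plus
    two 12%-wide scatter windows at 118 and 170 keV.
    """
    return {
        "ho81": EnergyWindow("ho81", 81.0, 0.15),
        "sc118": EnergyWindow("sc118", 118.0, 0.12),
        "tc140": EnergyWindow("tc140", 140.0, 0.15),
        "sc170": EnergyWindow("sc170", 170.0, 0.12),
    }


# ---------------------------------------------------------------------------
# Detector energy response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorModel:
    """Gaussian energy response of the gamma camera.

    FWHM(E) = ``fwhm_ref * (e_ref / E) ** exponent`` as a fraction of E.
    Default: 9.5% at 140 keV with the 1/sqrt(E) scaling typical of NaI(Tl)
    statistics-limited resolution.
    """

    fwhm_ref: float = 0.095
    e_ref: float = 140.0
    exponent: float = 0.5
    crystal_efficiency: float = 1.0

    def fwhm_fraction(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        return self.fwhm_ref * (self.e_ref / e) ** self.exponent

    def sigma_kev(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        return self.fwhm_fraction(e) * e / 2.354820045


def detection_probability(photon_energy, window: EnergyWindow,
                          det: DetectorModel) -> np.ndarray:
    """Probability that a photon's deposited-energy reading falls in-window.

    The recorded energy is Gaussian around the incident energy with the
    camera's resolution; the detection probability is the Gaussian mass
    between the window bounds. Vectorized over ``photon_energy``.
    """
    e = np.asarray(photon_energy, dtype=float)
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    sigma = det.sigma_kev(e)
    lo, hi = window.bounds
    p = ndtr((hi - e) / sigma) - ndtr((lo - e) / sigma)
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# Emission spectra
# ---------------------------------------------------------------------------

def _load_json(name: str) -> dict:
    with resources.files("duospect.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Discrete gamma lines plus an optional piecewise-constant continuum."""

    isotope: str
    lines: tuple[tuple[float, float], ...]
    continuum_edges: tuple[float, ...] | None = None
    continuum_density: tuple[float, ...] | None = None  # photons/decay/keV

    def __post_init__(self) -> None:
        for e, i in self.lines:
            if e <= 0 or i < 0:
                raise ValueError("line energies must be > 0, intensities >= 0")

    @property
    def continuum_bin_intensities(self) -> np.ndarray:
        if self.continuum_edges is None:
            return np.zeros(0)
        edges = np.asarray(self.continuum_edges)
        dens = np.asarray(self.continuum_density)
        return dens * np.diff(edges)

    @property
    def photons_per_decay(self) -> float:
        return float(sum(i for _, i in self.lines)
                     + self.continuum_bin_intensities.sum())

    def truncate(self, lo: float | None = None, hi: float | None = None,
                 lines_only: bool = False) -> "EmissionSpectrum":
        """Restrict the spectrum to an energy band (used for crosstalk studies)."""
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        lines = tuple((e, i) for e, i in self.lines if lo <= e <= hi)
        if lines_only or self.continuum_edges is None:
            return EmissionSpectrum(self.isotope, lines)
        edges = np.asarray(self.continuum_edges)
        dens = np.array(self.continuum_density, dtype=float)
        mids = 0.5 * (edges[:-1] + edges[1:])
        dens[(mids < lo) | (mids > hi)] = 0.0
        return EmissionSpectrum(self.isotope, lines,
                                tuple(edges), tuple(dens))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` emission energies, one photon each, with probability
        proportional to per-decay intensity."""
        line_int = np.array([i for _, i in self.lines])
        cont_int = self.continuum_bin_intensities
        weights = np.concatenate([line_int, cont_int])
        total = weights.sum()
        if total <= 0:
            raise ValueError("spectrum has no intensity")
        idx = rng.choice(weights.size, size=n, p=weights / total)
        energies = np.empty(n)
        n_lines = line_int.size
        for k, (e, _) in enumerate(self.lines):
            energies[idx == k] = e
        if cont_int.size:
            edges = np.asarray(self.continuum_edges)
            for b in range(cont_int.size):
                m = idx == n_lines + b
                energies[m] = rng.uniform(edges[b], edges[b + 1], m.sum())
        return energies


def spectrum(isotope: str, continuum: bool = True) -> EmissionSpectrum:
    """Load a packaged emission spectrum ('Ho166' or 'Tc99m')."""
    data = _load_json("spectra.json")
    if isotope not in ("Ho166", "Tc99m"):
        raise KeyError(f"unknown isotope {isotope!r}")
    entry = data[isotope]
    lines = tuple((float(e), float(i)) for e, i in entry["lines"])
    cont = entry.get("continuum")
    if continuum and cont is not None:
        return EmissionSpectrum(isotope, lines,
                                tuple(cont["edges_kev"]),
                                tuple(cont["density_per_kev"]))
    return EmissionSpectrum(isotope, lines)


# ---------------------------------------------------------------------------
# Attenuation
# ---------------------------------------------------------------------------

MATERIAL_LABELS = {"air": 0, "water": 1, "pmma": 2, "bone": 3, "agar": 4}


class AttenuationModel:
    """Linear attenuation coefficients from packaged mu/rho tables.

    Tables are log-log interpolated; valid on 60-2000 keV. ``mu`` returns
    1/cm for a named material; ``mu_map`` evaluates a whole label volume.
    """

    def __init__(self) -> None:
        data = _load_json("attenuation.json")
        self._energies = np.asarray(data["energies_kev"], dtype=float)
        self._tables = {}
        self._densities = {}
        for name, entry in data["materials"].items():
            self._tables[name] = np.asarray(entry["mu_rho"], dtype=float)
            self._densities[name] = float(entry["density_g_cm3"])
        pe = data["photoelectric_fraction"]
        self._pe_energies = np.asarray(pe["energies_kev"], dtype=float)
        self._pe_fraction = np.asarray(pe["water"], dtype=float)
        lead = data["collimator_lead"]
        self._lead_energies = np.asarray(lead["energies_kev"], dtype=float)
        self._lead_mu = (np.asarray(lead["mu_rho"], dtype=float)
                         * lead["density_g_cm3"])

    @property
    def materials(self) -> tuple[str, ...]:
        return tuple(self._tables)

    def density(self, material: str) -> float:
        return self._densities[material]

    def _check_energy(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = ENERGY_RANGE_KEV
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside supported range {lo}-{hi} keV"
            )
        return e

    def mu(self, material: str, energy) -> np.ndarray | float:
        """Linear attenuation coefficient (1/cm), log-log interpolated."""
        if material not in self._tables:
            raise KeyError(f"unknown material {material!r}")
        e = self._check_energy(energy)
        mu_rho = np.exp(np.interp(np.log(e), np.log(self._energies),
                                  np.log(self._tables[material])))
        out = mu_rho * self._densities[material]
        return out if out.ndim else float(out)

    def mu_by_label(self, energy) -> np.ndarray:
        """mu (1/cm) for every material label index, at one energy."""
        out = np.zeros(len(MATERIAL_LABELS))
        for name, lab in MATERIAL_LABELS.items():
            out[lab] = self.mu(name, energy)
        return out

    def mu_map(self, labels: np.ndarray, energy: float) -> np.ndarray:
        """Evaluate mu over a material-label volume at one energy."""
        return self.mu_by_label(energy)[labels]

    def photoelectric_fraction(self, energy) -> np.ndarray:
        """Photoelectric share of interactions in water-like media."""
        e = self._check_energy(energy)
        f = np.exp(np.interp(np.log(e), np.log(self._pe_energies),
                             np.log(self._pe_fraction)))
        return f if f.ndim else float(f)

    def mu_lead(self, energy) -> np.ndarray | float:
        """Linear attenuation of lead (collimator model only; K-edge kept)."""
        e = np.asarray(energy, dtype=float)
        out = np.exp(np.interp(np.log(e), np.log(self._lead_energies),
                               np.log(self._lead_mu)))
        return out if out.ndim else float(out)


def attenuation_coefficient(material: str, energy) -> np.ndarray | float:
    """Convenience wrapper: mu (1/cm) from the packaged tables."""
    return AttenuationModel().mu(material, energy)


# ---------------------------------------------------------------------------
# Compton scattering (Klein-Nishina)
# ---------------------------------------------------------------------------

def compton_energy(energy: float, cos_theta) -> np.ndarray:
    """Scattered photon energy for scattering angle theta."""
    alpha = np.asarray(energy, dtype=float) / ELECTRON_REST_KEV
    return energy / (1.0 + alpha * (1.0 - np.asarray(cos_theta)))


def compton_min_energy(energy: float) -> float:
    """Minimum (backscatter) energy allowed by Compton kinematics."""
    return energy / (1.0 + 2.0 * energy / ELECTRON_REST_KEV)


def klein_nishina_differential(energy: float, cos_theta) -> np.ndarray:
    """Klein-Nishina dsigma/dOmega in units of r_e^2 (unpolarized)."""
    ct = np.asarray(cos_theta, dtype=float)
    ratio = compton_energy(energy, ct) / energy  # E'/E
    return 0.5 * ratio ** 2 * (ratio + 1.0 / ratio - (1.0 - ct ** 2))


def klein_nishina_total(energy) -> np.ndarray | float:
    """Total Klein-Nishina cross-section in units of r_e^2 (closed form)."""
    a = np.asarray(energy, dtype=float) / ELECTRON_REST_KEV
    t1 = (1 + a) / a ** 2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    out = 2 * np.pi * (t1 + t2 + t3)
    return out if out.ndim else float(out)


def sample_compton(energy: float, rng: np.random.Generator,
                   size: int | None = None):
    """Sample Compton-scattered energy and polar angle via Kahn's method.

    Returns ``(scattered_energy, theta)``; arrays of shape ``(size,)`` when
    ``size`` is given, scalars otherwise. The sampled pair always satisfies
    the kinematic relation and the energy bound
    ``E' in [E/(1+2E/m_e c^2), E]``.
    """
    if energy <= 0:
        raise ValueError("energy must be positive")
    n = 1 if size is None else int(size)
    alpha = energy / ELECTRON_REST_KEV
    kappa = 2.0 * alpha
    branch_p = (kappa + 1.0) / (kappa + 9.0)
    r = np.empty(n)  # R = E/E'
    todo = np.arange(n)
    while todo.size:
        x1 = rng.random(todo.size)
        x2 = rng.random(todo.size)
        x3 = rng.random(todo.size)
        cand = np.empty(todo.size)
        ok = np.empty(todo.size, dtype=bool)
        b1 = x1 <= branch_p
        cand[b1] = 1.0 + kappa * x2[b1]
        ok[b1] = x3[b1] <= 4.0 * (1.0 / cand[b1] - 1.0 / cand[b1] ** 2)
        b2 = ~b1
        cand[b2] = (1.0 + kappa) / (1.0 + kappa * x2[b2])
        ct2 = 1.0 - (cand[b2] - 1.0) / alpha
        ok[b2] = x3[b2] <= 0.5 * (ct2 ** 2 + 1.0 / cand[b2])
        r[todo[ok]] = cand[ok]
        todo = todo[~ok]
    e_out = energy / r
    cos_theta = np.clip(1.0 - (r - 1.0) / alpha, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if size is None:
        return float(e_out[0]), float(theta[0])
    return e_out, theta


def sample_compton_energies(energies: np.ndarray, rng: np.random.Generator):
    """Kahn sampling with a different incident energy per photon.

    Returns ``(scattered_energies, cos_theta)`` arrays matching
    ``energies``; used by the transport loop where in-flight energies mix.
    """
    e = np.asarray(energies, dtype=float)
    alpha = e / ELECTRON_REST_KEV
    kappa = 2.0 * alpha
    branch_p = (kappa + 1.0) / (kappa + 9.0)
    r = np.empty(e.size)
    todo = np.arange(e.size)
    while todo.size:
        k = kappa[todo]
        a = alpha[todo]
        x1 = rng.random(todo.size)
        x2 = rng.random(todo.size)
        x3 = rng.random(todo.size)
        cand = np.empty(todo.size)
        ok = np.empty(todo.size, dtype=bool)
        b1 = x1 <= branch_p[todo]
        cand[b1] = 1.0 + k[b1] * x2[b1]
        ok[b1] = x3[b1] <= 4.0 * (1.0 / cand[b1] - 1.0 / cand[b1] ** 2)
        b2 = ~b1
        cand[b2] = (1.0 + k[b2]) / (1.0 + k[b2] * x2[b2])
        ct2 = 1.0 - (cand[b2] - 1.0) / a[b2]
        ok[b2] = x3[b2] <= 0.5 * (ct2 ** 2 + 1.0 / cand[b2])
        r[todo[ok]] = cand[ok]
        todo = todo[~ok]
    cos_theta = np.clip(1.0 - (r - 1.0) / alpha, -1.0, 1.0)
    return e / r, cos_theta
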