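# Methods

`duospect` models a simultaneous Ho-166/Tc-99m SPECT acquisition and its
quantitative reconstruction. Ho-166 microspheres are the therapy-simulating
scout agent in liver radioembolization; Tc-99m stannous phytate labels
healthy parenchyma. Imaging both at once removes registration error but
couples the two signals: Tc-99m contaminates the 81-keV Ho photopeak window
(multiple scatter and collimator lead x-rays — a single Compton scatter of a
140.5-keV photon cannot fall below 90.4 keV, so the crosstalk is carried by
higher-order and collimator pathways), while Ho-166's high-energy gammas
(1.38-1.66 MeV) and bremsstrahlung contaminate the 140-keV Tc window. The
package provides the photon-transport simulator, the detector model, the
three-step crosstalk-corrected OSEM reconstruction, and the phantom-based
evaluation of that pipeline.

## Emission and detection model

**Windows.** Photopeaks 81 keV and 140 keV at 15% width; auxiliary scatter
windows 118 keV and 170 keV at 12%. The 118-keV window is recorded and
stored but unused by the default pipeline.

**Spectra** (packaged in `data/spectra.json`). Tc-99m: a single 140.5-keV
line, 0.885 photons/decay. Ho-166: gamma lines at 80.6 (0.0671), 1379
(0.00922), 1582 (0.00182) and 1662 keV (0.00120 photons/decay) from standard
decay tables, plus a coarse piecewise-constant bremsstrahlung continuum.
The continuum integrates to 0.05 photons/decay over 60-2000 keV with a
roughly 1/E falloff, sized from a radiative-yield estimate for the ~0.69-MeV
mean beta energy in water (~10 keV radiated per decay) including scatter
buildup. It is a deliberate simplification — the true in-tissue
bremsstrahlung spectrum depends on geometry — and it is the single largest
uncertainty in the Ho self-background; it can be rescaled or disabled via
`spectrum("Ho166", continuum=False)`.

**Energy response.** Gaussian, 9.5% FWHM at 140 keV scaling as E^-1/2
(typical NaI(Tl)); the camera's real resolution was not specified for the
reference system, so this is an assumption surfaced in the config. The
in-window detection probability of a photon is the Gaussian mass between
the window bounds.

**Attenuation.** Packaged NIST-style mass-attenuation tables (water, PMMA,
cortical bone, air; agar treated as water), log-log interpolated on
60-2000 keV, multiplied by packaged densities. Photoelectric absorption
terminates a history (no fluorescence in tissue); coherent scatter is
omitted. The photoelectric share of interactions uses a water-like
fraction for all materials — a documented approximation that matters only
below ~100 keV where that share is a few percent.

## PSF lookup tables

The collimator/detector response for detection in a given window is a
library of 2-D kernels: a *direct* family versus source-collimator distance
(photons already in-window), and *indirect* kernels on an 8-energy x
5-distance grid (81, 95, 118, 140, 170, 300, 713, 1379 keV x 1, 5, 12, 24,
40 cm). Photon energies map to grid energies through half-open bins with
edges 60/88/106/129/154/226/462/992/2000 keV (lower edge inclusive; the
88-keV edge is the lead K-edge, below which no K x-rays can be excited).
Distances interpolate linearly; energies do not (the bin map is the model).

Kernels come from a parameterized analytic model rather than a radiation
transport simulation of the collimator (`CollimatorParams`):

* **Geometric core** — Gaussian with FWHM = d(l_eff + z + b)/l_eff (hole
  diameter d = 2.94 mm, hole length l = 40.6 mm, septa 1.14 mm,
  collimator-crystal gap b = 1 cm, medium-energy defaults), l_eff
  penetration-corrected by 2/mu_Pb(E); efficiency
  (K d^2 / (l_eff (d+t)))^2 with K = 0.26, about 1.9e-4.
* **Lead x-ray component** — for source energies above 88 keV, a slightly
  widened Gaussian with efficiency `xray_amplitude` (0.35) x the reference
  geometric efficiency x the resolution-weighted window overlap of the Pb
  K lines (72.8/75.0/84.9 keV) x (140/E)^2.5 tracking the photoelectric
  cross-section in lead. This channel feeds the 81-keV window and is the
  dominant Tc-to-Ho crosstalk carrier.
* **Penetration tail** — a broad exponential (scale growing with distance
  and energy) with efficiency `penetration_amplitude` (0.0045) x
  exp(-mu_Pb(E) * 0.6 cm) x window-width/100 keV. This stands in for
  septal penetration plus partial energy deposition of MeV photons; its
  amplitude was set by a branching-ratio argument: the observed
  order-of-magnitude balance between Tc and Ho counts in the 140-keV
  window (about 4:1 per unit activity) requires the ~0.03 photons/decay of
  high-energy Ho flux to detect at roughly 1-2x the geometric efficiency.
* **Resolution tail** — out-of-window photons in the bins adjacent to the
  window detect with the band-averaged Gaussian tail probability.

Kernels are truncated below 1e-6 of their peak and *not* renormalized;
kernels with negligible total efficiency (< 1e-12) are zeroed so disabled
channels contribute exactly nothing. Grid: 41 x 41 bins at the detector
pitch (4.8 mm default). Neither the kernel pitch nor the direct family's
distance dependence is prescribed by the reference system's description;
both are config choices here.

## Monte Carlo simulator

Histories are drawn per isotope proportionally to voxel activity, with one
photon per history and weight scaled so that expectations are exact in
total activity x 10^6 decays/s/MBq x photons-per-decay x per-angle
acquisition time. Transport uses Woodcock (delta) tracking on the material
grid with analog interaction sampling; Compton angles/energies come from
Kahn's rejection method for the Klein-Nishina law. Histories end on
photoelectric absorption, below 50 keV, after 10 scatters, or on leaving
the grid.

**Detection is forced**: at the emission vertex and every scatter vertex
the expected contribution to *every* camera angle is accumulated — exit
attenuation along the detector direction (ray steps of 0.4 cm), the
Klein-Nishina directional density (times 4 pi, since kernel efficiencies
are per isotropically emitted photon) for scatter vertices, and the
direct-kernel-times-detection-probability or indirect-kernel response.
Deposits are impulse images per (window, kernel class, distance knot),
convolved with their kernels once at the end — distance interpolation is
exact because a vertex's weight is split linearly between its two
bracketing knots. A "measured-like" acquisition Poisson-samples this
expectation; an analog escape-direction mode would waste essentially every
history against a ~1e-4 collimator acceptance, which is why it is not
offered. Fixed seeds make every simulation bit-reproducible.

## Deterministic projector and OSEM

The in-window primary system model is a rotation-based parallel-beam
projector: per angle the activity is moved into the detector frame by the
*scatter* (transpose) direction of a cached bilinear rotation — chosen
because the scatter direction conserves mass exactly, keeping the
projector's absolute scale consistent with the Monte Carlo to a few per
mil — each depth plane is weighted by its Beer-Lambert factor toward the
detector (mu at the window center energy, half-voxel self-attenuation),
convolved with the distance-interpolated direct kernel, and accumulated.
`back_project` is the exact algebraic adjoint (verified against a densely
probed matrix), which the EM update requires.

OSEM uses the standard multiplicative update with an additive scatter
expectation in the denominator, interleaved angle subsets (0, 8, 16, ...),
a uniform start inside the attenuating support, and ratio guards (0/0 bins
contribute 1; counts in zero-expectation bins raise a data-inconsistency
warning). One subset reproduces MLEM bit for bit.

**Scatter terms.** The Tc reconstruction takes k x 170-keV-window counts
(k = 0.93 on raw counts by default; a flag applies the window-width-ratio
variant, 0.93 x 21/20.4 ≈ 0.96 — which of the two the reference protocol
meant is ambiguous, so both are implemented) to remove Ho crosstalk, plus
a Monte Carlo *self-scatter* term for Tc's own in-window scatter, which a
primary-only projector cannot represent. The Ho reconstruction takes the
simulated Tc downscatter (step 2) as a fixed additive term plus its own
self-scatter term (scatter of the 80.6-keV line, high-energy gammas,
continuum; computed by excluding only unscattered in-window primaries).

**Relaxed self-scatter refresh.** Re-simulating self-scatter from an
estimate that has absorbed its own scatter overestimates it by the
scatter-to-primary gain gamma, and feeding that straight back makes the
estimate oscillate with amplification gamma per refresh — ruinous for
Ho-166, where gamma ≈ 5 at these energies. Each refresh therefore blends
`lambda = 1/(1 + gamma)` of the new simulation into the running estimate,
with gamma measured at run time as simulated-scatter counts over primary
forward-model counts; this cancels the linearized error in one refresh.
The default refresh interval is 5 iterations.

## Phantoms

All experiment inputs are generated: the NEMA IQ phantom (six spheres,
10-37 mm, on the standard 114.4-mm ring, 0.8 MBq/ml Ho; Tc background at
0/6/11 kBq/ml in a water compartment reduced to 5.5 L by an inert agar
region; simplified elliptical body), a 6.3-L/50-MBq Tc cylinder, a Tc line
source between two 40x40x10 cm PMMA slabs, and a torso surrogate (water
body, 1200-ml liver at 34 kBq/ml Tc, 130-ml spherical insert at 53 MBq Ho
≈ 0.41 MBq/ml; the insert displaces liver volume, so the Tc load is
34 kBq/ml x 1070 ml ≈ 36 MBq). Default generation voxel 2 mm,
voxel-center-inside membership (a subsampled partial-volume fill is
available); resampling to the 4.8-mm reconstruction grid bins each fine
voxel into the coarse voxel containing its center, conserving activity
exactly. Generators are deterministic.

What the generators do *not* emulate: real compartment walls and fill
ports, CT-derived attenuation maps (materials are labeled analytically),
detector dead time and pile-up, breathing motion, and the true NEMA body
shell shape (an elliptical cylinder stands in). Tests passing on these
phantoms therefore validate the reconstruction and correction logic, not
camera-specific calibration.

## Problem sizes and numerical choices

Default study conditions follow the modeled protocol: 120 angles over 360
degrees, 8 subsets of 15 projections, 20 iterations, k = 0.93. The test
suite and the acceptance script run scaled instances chosen as the
package's own desk-scale configuration — 48 angles (still 8 interleaved
subsets), 15-50 k histories with forced detection (noise-free
expectations), 4.8-mm reconstruction grids — because every property they
check (adjointness, EM monotonicity, degeneracy, ordering of recovery
curves, count-ratio magnitudes) is invariant to that scaling. Protocol-fixed
conditions (the window set, the energy-bin map, sphere sizes and
concentrations, k) are never scaled.

Degenerate inputs: zero-activity phantoms warn and return zero counts;
zero Tc images yield exactly zero downscatter; all-zero data drive OSEM to
zero after one subset (0/0 guards keep it there); VOI dilation raises once
spheres geometrically overlap (on the standard ring the 10- and 37-mm
neighbors touch at +40 mm dilation). Ties in the VOI position fit break
toward the lexicographically smallest offset.

## Known limitations

The collimator model is analytic; its x-ray and penetration amplitudes set
the absolute crosstalk scale and were calibrated by branching-ratio
arguments, not by collimator transport — simulated count ratios (e.g.
C81/C140 ≈ 0.5 for the PMMA line source) are order-of-magnitude, not
percent-level, statements. Self-scatter refresh is a surrogate for
embedding Monte Carlo scatter inside the forward operator and inherits
Monte Carlo noise into the additive term at low history counts. The
continuum intensity is an assumption. Materials share a water-like
photoelectric fraction. No dead time, no motion, no regularization.
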