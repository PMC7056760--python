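{
  "version": 1,
  "comment": "Photon emission data. Lines are (energy keV, photons per decay) from standard decay tables. The Ho-166 continuum is a coarse piecewise-constant stand-in for in-tissue bremsstrahlung from the beta spectrum (Emax 1.85 MeV), binned to the detector-model energy bands; density in photons/decay/keV.",
  "Ho166": {
    "lines": [
      [80.574, 0.0671],
      [1379.4, 0.00922],
      [1581.9, 0.00182],
      [1662.4, 0.00120]
    ],
    "continuum": {
      "edges_kev": [60, 88, 106, 129, 154, 226, 462, 992, 2000],
      "density_per_kev": [2.0e-4, 1.5e-4, 1.25e-4, 1.05e-4, 7.8e-5, 4.3e-5, 2.0e-5, 1.0e-5]
    }
  },
  "Tc99m": {
    "lines": [
      [140.511, 0.885]
    ],
    "continuum": null
  }
}
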