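{
  "version": 1,
  "comment": "Mass attenuation coefficients mu/rho in cm^2/g (total, incl. coherent) at the grid energies, from standard NIST-style reference tables; log-log interpolated at runtime. Patient/phantom materials only; no K-edges on 60-2000 keV.",
  "energies_kev": [60, 80, 100, 150, 200, 300, 400, 500, 600, 800, 1000, 1250, 1500, 2000],
  "materials": {
    "water": {
      "density_g_cm3": 1.0,
      "mu_rho": [0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186, 0.1061, 0.0969, 0.0896, 0.0786, 0.0707, 0.0630, 0.0575, 0.0494]
    },
    "pmma": {
      "density_g_cm3": 1.19,
      "mu_rho": [0.1924, 0.1751, 0.1641, 0.1456, 0.1328, 0.1152, 0.1031, 0.0941, 0.0870, 0.0763, 0.0686, 0.0612, 0.0559, 0.0480]
    },
    "bone": {
      "density_g_cm3": 1.92,
      "mu_rho": [0.3148, 0.2229, 0.1855, 0.1480, 0.1309, 0.1113, 0.0992, 0.0906, 0.0836, 0.0734, 0.0657, 0.0586, 0.0535, 0.0461]
    },
    "air": {
      "density_g_cm3": 0.0012,
      "mu_rho": [0.1875, 0.1662, 0.1541, 0.1356, 0.1233, 0.1067, 0.0955, 0.0870, 0.0806, 0.0707, 0.0636, 0.0567, 0.0518, 0.0445]
    },
    "agar": {
      "density_g_cm3": 1.0,
      "mu_rho": [0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186, 0.1061, 0.0969, 0.0896, 0.0786, 0.0707, 0.0630, 0.0575, 0.0494]
    }
  },
  "collimator_lead": {
    "comment": "Lead mu/rho for the analytic collimator model only (has a K-edge at 88 keV; not a phantom material).",
    "density_g_cm3": 11.35,
    "energies_kev": [60, 80, 88.0, 88.01, 100, 150, 200, 300, 400, 500, 600, 800, 1000, 1500, 2000],
    "mu_rho": [5.021, 2.419, 1.910, 7.683, 5.549, 2.014, 0.999, 0.403, 0.2323, 0.1614, 0.1248, 0.0887, 0.0710, 0.0522, 0.0455]
  },
  "photoelectric_fraction": {
    "comment": "Approximate photoelectric share of the total interaction cross-section in water-like media; log-log interpolated, used to split Compton vs photoelectric during transport.",
    "energies_kev": [60, 80, 100, 150, 200, 300, 500, 1000, 2000],
    "water": [0.070, 0.030, 0.015, 0.005, 0.002, 0.0008, 0.0002, 0.00005, 0.00002]
  }
}
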