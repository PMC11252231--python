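{
  "version": 1,
  "comment": "Published per-element summary statistics of the 129-orchard Izmir olive-orchard topsoil survey (mg/kg dry soil; cv_percent in %, skewness dimensionless). These printed statistics are the calibration targets of soiltrace.simulate.emulate_study and the inputs to the worked examples; the underlying 129-sample table is not public.",
  "n": 129,
  "elements": ["Al", "Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn"],
  "statistics": {
    "Al": {"mean": 22521, "median": 22466, "sd": 5623, "se": 495, "cv_percent": 24.97, "skewness": 0.266, "min": 10956, "max": 37522},
    "Cd": {"mean": 0.176, "median": 0.170, "sd": 0.0874, "se": 0.0077, "cv_percent": 49.3, "skewness": 0.43, "min": 0.02, "max": 0.42},
    "Co": {"mean": 7.58, "median": 6.83, "sd": 4.07, "se": 0.36, "cv_percent": 53.7, "skewness": 4.22, "min": 2.06, "max": 39.8},
    "Cr": {"mean": 44.9, "median": 33.8, "sd": 36.5, "se": 3.21, "cv_percent": 81.3, "skewness": 2.73, "min": 9.28, "max": 210.7},
    "Cu": {"mean": 19.1, "median": 17.4, "sd": 7.98, "se": 0.70, "cv_percent": 41.8, "skewness": 1.24, "min": 6.59, "max": 47.8},
    "Fe": {"mean": 15821, "median": 15875, "sd": 5013, "se": 441, "cv_percent": 31.7, "skewness": 0.242, "min": 5464, "max": 28834},
    "Mn": {"mean": 352, "median": 326, "sd": 148, "se": 13.1, "cv_percent": 42.1, "skewness": 1.437, "min": 133.9, "max": 984},
    "Ni": {"mean": 37.9, "median": 24.8, "sd": 39.5, "se": 3.48, "cv_percent": 104.4, "skewness": 3.792, "min": 6.5, "max": 312},
    "Pb": {"mean": 8.85, "median": 8.61, "sd": 4.44, "se": 0.39, "cv_percent": 50.2, "skewness": 0.969, "min": 1.29, "max": 25.4},
    "Zn": {"mean": 34.9, "median": 32.8, "sd": 11.8, "se": 1.04, "cv_percent": 33.8, "skewness": 1.16, "min": 13.4, "max": 79.6}
  }
}
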