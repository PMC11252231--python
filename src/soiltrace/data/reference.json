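{
  "version": 1,
  "comment": "Per-element geochemical background and soil guideline concentrations (mg/kg dry soil) and Hakanson toxicity response coefficients. Background is upper continental crust (UCC). Guideline keys: WSA = world soil average, ESA = European soil average, MAC = maximum allowable concentration, CSQG = Canadian soil quality guideline (agricultural). All values are editable constants; override via a file with the same schema.",
  "elements": ["Al", "Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn"],
  "background_ucc": {
    "Al": 81500,
    "Cd": 0.09,
    "Co": 17.3,
    "Cr": 92,
    "Cu": 28,
    "Fe": 39200,
    "Mn": 774,
    "Ni": 47,
    "Pb": 17,
    "Zn": 67
  },
  "guidelines": {
    "WSA": {"Cd": 0.41, "Co": 11.3, "Cr": 59.5, "Cu": 38.9, "Mn": 488, "Ni": 29, "Pb": 27, "Zn": 70},
    "ESA": {"Cd": 0.28, "Co": 10.4, "Cr": 94.8, "Cu": 17.3, "Mn": 524, "Ni": 37, "Pb": 32, "Zn": 68.1},
    "MAC": {"Cd": 5, "Co": 50, "Cr": 200, "Cu": 150, "Ni": 60, "Pb": 300, "Zn": 300},
    "CSQG": {"Cd": 1.4, "Co": 40, "Cr": 64, "Cu": 63, "Ni": 50, "Pb": 70, "Zn": 200}
  },
  "toxicity_response": {"Zn": 1, "Cu": 5, "Cd": 30, "Ni": 5, "Cr": 2, "Pb": 5}
}
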