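{
  "version": 1,
  "comment": "Residential-soil toxicity values in the USEPA RSL convention. RfDo: oral reference dose, mg/kg-day. RfC: inhalation reference concentration, mg/m3 (null = no inhalation toxicity value; route skipped). ABSd: dermal absorption fraction. GIABS: gastrointestinal absorption fraction. RBA: relative bioavailability. CSFo: oral slope factor, (mg/kg-day)^-1; IUR: inhalation unit risk, (ug/m3)^-1 - present only for the carcinogens assessed (Cr, Cd, Ni, Co). Chromium is assessed as Cr(VI) - a deliberately conservative speciation assumption; override via a file with the same schema if total-Cr or Cr(III) toxicity is wanted.",
  "elements": {
    "Al": {"RfDo": 1.0,    "RfC": 0.005,  "ABSd": 0.001, "GIABS": 1.0,   "RBA": 1.0},
    "Cd": {"RfDo": 0.001,  "RfC": 1e-05,  "ABSd": 0.001, "GIABS": 0.025, "RBA": 1.0, "IUR": 0.0018},
    "Co": {"RfDo": 0.0003, "RfC": 6e-06,  "ABSd": 0.001, "GIABS": 1.0,   "RBA": 1.0, "IUR": 0.009},
    "Cr": {"RfDo": 0.003,  "RfC": 0.0001, "ABSd": 0.001, "GIABS": 0.025, "RBA": 1.0, "CSFo": 0.5, "IUR": 0.084},
    "Cu": {"RfDo": 0.04,   "RfC": null,   "ABSd": 0.001, "GIABS": 1.0,   "RBA": 1.0},
    "Fe": {"RfDo": 0.7,    "RfC": null,   "ABSd": 0.001, "GIABS": 1.0,   "RBA": 1.0},
    "Mn": {"RfDo": 0.024,  "RfC": 5e-05,  "ABSd": 0.001, "GIABS": 0.04,  "RBA": 1.0},
    "Ni": {"RfDo": 0.02,   "RfC": 9e-05,  "ABSd": 0.001, "GIABS": 0.04,  "RBA": 1.0, "IUR": 0.00026},
    "Pb": {"RfDo": 0.0035, "RfC": null,   "ABSd": 0.001, "GIABS": 1.0,   "RBA": 1.0},
    "Zn": {"RfDo": 0.3,    "RfC": null,   "ABSd": 0.001, "GIABS": 1.0,   "RBA": 1.0}
  }
}
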