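{
  "windkessel_outlets": {
    "RC":  {"Rp": 0.50931,  "Rd": 2.68885, "C": 0.71603},
    "LC":  {"Rp": 0.50004,  "Rd": 2.43319, "C": 0.74383},
    "RS":  {"Rp": 0.50878,  "Rd": 2.6307,  "C": 0.74512},
    "LS":  {"Rp": 0.45264,  "Rd": 2.10615, "C": 0.84197},
    "DAo": {"Rp": 5.919e-2, "Rd": 0.28437, "C": 5.01933},
    "RPA": {"Rp": 3.277e-2, "Rd": 0.1361,  "C": 1.76235},
    "LPA": {"Rp": 3.108e-2, "Rd": 0.31950, "C": 1.00099}
  },
  "venous_sections": {
    "SVC": {"Rp": 0.15500,  "Rd": 1.807e-2, "C": 284.73779},
    "IVC": {"Rp": 0.22075,  "Rd": 2.261e-2, "C": 135.95630},
    "RPV": {"Rp": 2.693e-2, "Rd": 2.040e-2, "C": 72.05470},
    "LPV": {"Rp": 1.027e-2, "Rd": 8.970e-3, "C": 132.96730}
  },
  "heart_and_shunts": {
    "RA_valve_resistance": 3.3e-3,
    "RA_valve_inertance": 6.667e-5,
    "NAV_resistance": 1.0e-3,
    "NAV_inertance": 1.0e-5,
    "collateral_1_resistance": 9.69600e-2,
    "collateral_2_resistance": 0.05,
    "ASD_resistance": 3.0e-4
  }
}
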