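{
  "comment": "Clinical comparison targets. Only values quoted numerically in the source clinical dataset are filled in; indices reported only graphically are placeholders (value null) and are skipped by the scorer until supplied.",
  "targets": {
    "aortic_root_mean_pressure":      {"value": 56.4, "rule": "rel10"},
    "aortic_root_systolic_pressure":  {"value": null, "rule": "rel10"},
    "aortic_root_diastolic_pressure": {"value": null, "rule": "rel10"},
    "aortic_root_pulse_pressure":     {"value": null, "rule": "rel10"},
    "LPA_mean_pressure":              {"value": 14.7, "rule": "range", "bounds": [12.9, 16.5]},
    "RPA_mean_pressure":              {"value": 14.7, "rule": "range", "bounds": [12.9, 16.5]},
    "aortic_root_mean_flow":          {"value": null, "rule": "rel10"},
    "DAo_mean_flow":                  {"value": null, "rule": "rel10"},
    "LPA_mean_flow":                  {"value": null, "rule": "rel10"},
    "RPA_mean_flow":                  {"value": null, "rule": "rel10"},
    "SVC_mean_flow":                  {"value": 10.5, "rule": "rel10"},
    "IVC_mean_flow":                  {"value": null, "rule": "rel10"},
    "RPV_mean_flow":                  {"value": null, "rule": "rel10"},
    "LPV_mean_flow":                  {"value": null, "rule": "rel10"},
    "ASD_mean_flow":                  {"value": null, "rule": "rel10"},
    "shunt_mean_flow":                {"value": 9.7,  "rule": "rel10"}
  }
}
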