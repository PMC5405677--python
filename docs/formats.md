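# File formats

All formats are plain text; scalars round-trip at 17 significant digits.

## Netlist (`.net`)

One component per line, `#` starts a comment, identifiers case-sensitive:

```
# ground ground
resistor      shunt  AoR  PA_jct  resistance=3.5
capacitor     RPA_C  RPA_mid  ground  compliance=1.76235
diode_valve   NAV    V    AoR     resistance=0.001 inertance=1e-05
elastance_chamber ventricle V ground v0=0
```

Kinds: `resistor` (resistance), `capacitor` (compliance), `inductor`
(inertance), `diode_valve` (resistance, inertance), `elastance_chamber`
(v0; its E(t) is a simulator driver), `flow_source` (flow),
`pressure_source` (pressure). Units: mmHg, ml/s, ml, s, mmHg·s/ml,
ml/mmHg, mmHg·s²/ml. The reference node is declared in the
`# ground <name>` header comment (default `ground`).

## Waveform CSV

Columns: `time_s`, then `P_<node>_mmHg` per pressure trace and
`Q_<name>_mls` per flow trace. `time_s` must be strictly increasing.
Elastance output CSV: `time_s,E_mmHg_per_ml,segment` with segment
`measured` or `extrapolated`.

## Parameter config JSON

Mirrors the parameter tables verbatim (see
`src/shuntloop/data/figure1_params.json`): `windkessel_outlets` (RC, LC,
RS, LS, DAo, RPA, LPA → {Rp, Rd, C}), `venous_sections` (SVC, IVC, RPV,
LPV → {Rp, Rd, C}), `heart_and_shunts` (valve resistances/inertances,
collateral and ASD resistances).

## Run config JSON

Flat object: `model` (`figure1_baseline` | `figure1_flared` |
`figure1_implant_time`), `dt`, `period`, `max_cycles`, `tol`,
`initial_pressure`, `seed`, optional nested `heart` block
(`e_min, e_max, peak_time, sigma, v0, edv`). Missing keys take the
documented defaults.

## Targets JSON

`{"targets": {<index>: {"value": <number|null>, "rule": "rel10"|"range",
"bounds": [lo, hi]}}}`. Null-valued relative targets are placeholders and
skipped by the scorer.

## Summary JSON

`{"pressures": {site: {mean, systolic, diastolic, pulse}}, "flows":
{site: mean}, "indices": {<16 flat indices>}}` — the form consumed by
`shuntloop compare` and `shuntloop score`.
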