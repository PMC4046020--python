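name: volunteer_pegfilgrastim_300ug
horizon_days: 80
grid_dt_days: 0.25
injections:
- day: 0.0
  drug: pegfilgrastim
  dose: 300.0
  unit: ug
  route: sc
  site: gcsf_default
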