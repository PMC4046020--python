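name: volunteer_epo_150iukg_iv
horizon_days: 80
grid_dt_days: 0.25
injections:
- day: 0.0
  drug: epo_alfa
  dose: 150.0
  unit: IU/kg
  route: iv
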