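name: chop14_elderly
grid_dt_days: 0.25
injections: []
chemo:
  regimen: CHOP-14
  age_group: '>=60'
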