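# Term-neonate run: 100 mg/kg IV q24h to steady state.
population:
  group: term_neonate
  n_subjects: 200
regimen:
  route: iv_infusion
  dose_per_event: 100.0   # mg/kg
  interval: 24.0          # h
  infusion_duration: 0.5  # h
seed: 1
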