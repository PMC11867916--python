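# Adult run: low-dose linear-range regimen, 0.75 mg/kg IV q24h.
population:
  group: adult
  n_subjects: 200
regimen:
  route: iv_infusion
  dose_per_event: 0.75
  interval: 24.0
seed: 1
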