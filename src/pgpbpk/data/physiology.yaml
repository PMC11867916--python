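# Reference physiology for the two study groups.
#
# Organ volume fractions are L per kg body weight (density ~1 except the
# liver, converted to mass at 1.05 g/mL); blood-flow fractions are fractions
# of cardiac output and must sum to 1 over the perfused tissues
# (liver_arterial is the hepatic-artery share; the portal inflow is the gut
# and spleen venous outflow).  Values are standard published human reference
# values (ICRP-style) and are deliberately editable: they stand in for the
# proprietary virtual populations of commercial PBPK platforms.
adult:
  age: 30.0              # years
  reference_weight: 81.0 # kg
  reference_height: 177.0 # cm
  cardiac_output_ref: 390.0 # L/h
  hematocrit: 0.45
  cppgl: 80.7            # mg cytosolic protein per g liver
  blood_volume_fraction: 0.065
  organ_volume_fractions:
    lung: 0.012
    liver: 0.022222
    kidney: 0.0044
    muscle: 0.40
    adipose: 0.21
    skin: 0.037
    brain: 0.018
    heart: 0.0044
    gut: 0.017
    spleen: 0.0024
    bone: 0.086
    rest: 0.05
  blood_flow_fractions:
    liver_arterial: 0.065
    gut: 0.15
    spleen: 0.03
    kidney: 0.19
    muscle: 0.17
    adipose: 0.05
    skin: 0.05
    brain: 0.12
    heart: 0.04
    bone: 0.05
    rest: 0.085
  variability_cv:
    weight: 0.15
    height: 0.03
    liver: 0.25
    cppgl: 0.30
    renal: 0.25

term_neonate:
  age: 0.0
  reference_weight: 3.5
  reference_height: 51.0
  cardiac_output_ref: 36.0
  hematocrit: 0.50
  cppgl: 80.7
  blood_volume_fraction: 0.085
  organ_volume_fractions:
    lung: 0.015
    liver: 0.035374   # -> 130 g at 1.05 g/mL for the 3.5 kg reference
    kidney: 0.0071
    muscle: 0.22
    adipose: 0.14
    skin: 0.06
    brain: 0.10
    heart: 0.006
    gut: 0.02
    spleen: 0.0029
    bone: 0.06
    rest: 0.05
  blood_flow_fractions:
    liver_arterial: 0.06
    gut: 0.14
    spleen: 0.02
    kidney: 0.16
    muscle: 0.10
    adipose: 0.03
    skin: 0.06
    brain: 0.23
    heart: 0.05
    bone: 0.03
    rest: 0.12
  variability_cv:
    weight: 0.12
    height: 0.035
    liver: 0.25
    cppgl: 0.30
    renal: 0.0
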