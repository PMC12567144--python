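# Rifampicin (RIF) — PBPK and dosing parameters.
# Doses are amounts of the dosed form (RIF is dosed as the free form).
name: RIF
dose_mg: 300.0                  # oral dose used in the validated clinical trial simulation
therapeutic_oral_dose_mg: 600.0 # common oral therapeutic dose used for dose translation
mw_free: 822.94
mw_salt: 822.94                 # dosed as free form
bp_ratio: 0.67
fu: 0.15
vdss_L_per_kg: 0.42
peff_1e4_cm_per_s: 1.3
cl_iv_L_per_h: 8.307
cl_r_L_per_h: 1.5
kp:
  Lung: 0.14
  Adipose: 0.28
  Muscle: 0.15
  Liver: 0.29
  Spleen: 0.19
  Heart: 0.14
  Brain: 0.16
  Kidney: 0.24
  Skin: 0.19
  ReproOrg: 0.24
  RedMarrow: 0.30
  YellowMarrow: 0.30
  RestOfBody: 5.0
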