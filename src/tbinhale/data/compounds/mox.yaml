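# Moxifloxacin (MOX) — PBPK and dosing parameters.
# Doses are amounts of the dosed form (MOX is dosed as the hydrochloride).
name: MOX
dose_mg: 200.0
therapeutic_oral_dose_mg: 400.0
mw_free: 401.44
mw_salt: 437.9                  # hydrochloride
bp_ratio: 1.14
fu: 0.52
vdss_L_per_kg: 1.9
peff_1e4_cm_per_s: 1.45
cl_iv_L_per_h: 13.15
cl_r_L_per_h: 2.54
kp:
  Lung: 4.90
  Adipose: 0.52
  Muscle: 2.00
  Liver: 5.69
  Spleen: 4.01
  Heart: 2.88
  Brain: 0.64
  Kidney: 6.26
  Skin: 1.74
  ReproOrg: 6.33
  RedMarrow: 0.75
  YellowMarrow: 0.75
  RestOfBody: 17.55
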