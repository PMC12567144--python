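# Ethambutol (ETH) — PBPK and dosing parameters.
# Doses are amounts of the dosed form (ETH is dosed as the dihydrochloride;
# the 1974.6 mg trial dose is consistent with a salt amount).
name: ETH
dose_mg: 1974.6
therapeutic_oral_dose_mg: 1200.0
mw_free: 204.31
mw_salt: 277.23                 # dihydrochloride
bp_ratio: 0.94
fu: 0.75
vdss_L_per_kg: 6.1
peff_1e4_cm_per_s: 0.67
cl_iv_L_per_h: 41.9
cl_r_L_per_h: 32.4
kp:
  Lung: 7.92
  Adipose: 1.22
  Muscle: 9.14
  Liver: 8.65
  Spleen: 8.75
  Heart: 7.48
  Brain: 8.90
  Kidney: 8.07
  Skin: 6.26
  ReproOrg: 8.07
  RedMarrow: 3.15
  YellowMarrow: 3.15
  RestOfBody: 46.0
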