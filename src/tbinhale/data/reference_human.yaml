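# Reference adult male physiology (73 kg) for the whole-body perfusion-limited
# PBPK model. Volumes are ICRP-89-style organ volumes in litres; flows are
# fractions of cardiac output delivered arterially to each tissue.
#
# Conventions (see docs/methods.md):
#  * Lung volume is the whole perfusion-limited lung compartment (parenchyma
#    plus resident capillary blood), excluding the central venous/arterial
#    blood pools which are modelled separately.
#  * There is no gut tissue compartment (the compound partition tables carry
#    no gut Kp), so splanchnic blood flow is routed with the hepatic artery
#    directly into the liver inflow: the liver's arterial fraction (0.225)
#    is hepatic artery proper (~0.065) plus the splanchnic bed (~0.16).
#    The spleen drains portally into the liver on top of that.
#  * RestOfBody is the soft-tissue remainder (connective tissue, GI walls'
#    non-perfused share, glands) excluding bone mineral, which drugs do not
#    partition into; its flow fraction is the residual bone/connective share,
#    skeletal perfusion otherwise being carried by the marrow compartments.
version: 1
reference_body_weight_kg: 73.0
cardiac_output_L_per_h: 336.0      # 5.6 L/min at rest
hematocrit: 0.45
venous_blood_L: 3.90
arterial_blood_L: 1.80
portal_inflow_tissues: [Spleen]
tissues:
  Lung:         {volume_L: 1.17,  flow_fraction_of_co: 1.000}
  Adipose:      {volume_L: 18.20, flow_fraction_of_co: 0.050}
  Muscle:       {volume_L: 29.00, flow_fraction_of_co: 0.170}
  Liver:        {volume_L: 1.80,  flow_fraction_of_co: 0.225}
  Spleen:       {volume_L: 0.19,  flow_fraction_of_co: 0.030}
  Heart:        {volume_L: 0.33,  flow_fraction_of_co: 0.040}
  Brain:        {volume_L: 1.45,  flow_fraction_of_co: 0.120}
  Kidney:       {volume_L: 0.31,  flow_fraction_of_co: 0.190}
  Skin:         {volume_L: 3.30,  flow_fraction_of_co: 0.050}
  ReproOrg:     {volume_L: 0.04,  flow_fraction_of_co: 0.005}
  RedMarrow:    {volume_L: 1.10,  flow_fraction_of_co: 0.040}
  YellowMarrow: {volume_L: 2.40,  flow_fraction_of_co: 0.040}
  RestOfBody:   {volume_L: 3.60,  flow_fraction_of_co: 0.040}
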