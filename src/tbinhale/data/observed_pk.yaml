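# Observed clinical PK metrics used as the model-validation reference
# (means reported by the underlying clinical trials; units: cmax µg/mL,
# auc µg·h/mL).
RIF:
  cmax: 5.81
  auc_0_t: 31.02
  auc_0_inf: 31.02
ETH:
  cmax: 3.54
  auc_0_t: 27.80
  auc_0_inf: 30.76
MOX:
  cmax: 1.16
  auc_0_t: 11.88
  auc_0_inf: 14.57
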