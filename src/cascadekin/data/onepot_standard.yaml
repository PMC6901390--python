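# Standard one-pot recipe: 5 mM mannose, 5 mM NAD+, standard enzyme
# loading, 100 mM sodium-phosphate buffer pH 7.0, 50 C, 18 h.
label: onepot_standard
temperature_K: 323.0
buffer_mM: 100.0
initial:
  MAN: 5.0
  NADp: 5.0
loadings:
  - {enzyme: AldT, u_per_ml: 0.2}
  - {enzyme: ManD, u_per_ml: 0.1}
  - {enzyme: KDGA, u_per_ml: 0.4}
  - {enzyme: LDH, u_per_ml: 11.6}
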