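# Pure-mannose control for the biomass comparison: 13.9 mM mannose,
# 3.75 mM NAD+, standard enzyme loading, 100 mM sodium-phosphate buffer.
label: pure_mannose
temperature_K: 323.0
buffer_mM: 100.0
initial:
  MAN: 13.9
  NADp: 3.75
loadings:
  - {enzyme: AldT, u_per_ml: 0.2}
  - {enzyme: ManD, u_per_ml: 0.1}
  - {enzyme: KDGA, u_per_ml: 0.4}
  - {enzyme: LDH, u_per_ml: 11.6}
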