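# One-pot recipe of the real-time 13C-NMR run: 10 mM [1,6-13C2]mannose,
# 10 mM NAD+, standard enzyme loading, 100 mM sodium-phosphate buffer
# (pH 7.5 in the NMR tube), 50 C, followed for 16 h.
label: nmr_onepot
temperature_K: 323.0
buffer_mM: 100.0
initial:
  MAN: 10.0
  NADp: 10.0
loadings:
  - {enzyme: AldT, u_per_ml: 0.2}
  - {enzyme: ManD, u_per_ml: 0.1}
  - {enzyme: KDGA, u_per_ml: 0.4}
  - {enzyme: LDH, u_per_ml: 11.6}
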