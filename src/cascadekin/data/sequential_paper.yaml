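# Sequential proof-of-concept protocol: 20 mM mannose, 20 mM NAD+ in 50 mM
# sodium-phosphate buffer; AldT starts the reaction, ManD is added after
# 1.5 h, KDGA after 16.5 h, LDH together with a 10 mM NADH spike after
# 17.5 h; the run is stopped at 18.5 h.
label: sequential_paper
temperature_K: 323.0
buffer_mM: 50.0
initial:
  MAN: 20.0
  NADp: 20.0
loadings:
  - {enzyme: AldT, u_per_ml: 0.16, addition_time_h: 0.0}
  - {enzyme: ManD, u_per_ml: 0.07, addition_time_h: 1.5}
  - {enzyme: KDGA, u_per_ml: 0.51, addition_time_h: 16.5}
  - {enzyme: LDH, u_per_ml: 5.8, addition_time_h: 17.5}
spikes:
  - {time_h: 17.5, species: NADH, mM: 10.0}
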