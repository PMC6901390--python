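# Kinetic constants of the cascade enzymes measured at 50 C, pH 7.0 in
# sodium-phosphate buffer, plus operational half-lives at the standard
# process loadings.  ManD also accepts the lactone (Km 4.90 mM, Vmax
# 1.90 U/mg, kcat 1.33 1/s); the model routes the lactone through
# spontaneous hydrolysis instead, so only the mannonate constants enter.
enzymes:
  AldT:
    km_mM: {MAN: 9.73}
    vmax_u_per_mg: 5.20
    kcat_per_s: 2.51
    half_life_h: 9.8
    substrates: [MAN, NADp]
    products: [ML, NADH]
  ManD:
    km_mM: {MA: 5.37}
    vmax_u_per_mg: 2.39
    kcat_per_s: 1.67
    half_life_h: 1.4
    substrates: [MA]
    products: [KDG]
  KDGA:
    km_mM: {PYR+GA: 8.07}
    vmax_u_per_mg: 17.04
    kcat_per_s: 10.51
    half_life_h: .inf
    substrates: [KDG]
    products: [PYR, GA]
  LDH:
    km_mM: {PYR: 10.95}
    vmax_u_per_mg: 194.3
    kcat_per_s: 116.58
    half_life_h: .inf
    substrates: [PYR, NADH]
    products: [LA, NADp]
thermo:
  # standard transformed Gibbs energy of KDG cleavage, 1 M standard state
  dG_cleavage_kJ_per_mol: 6.2
  temperature_K: 323.0
aux:
  # spontaneous lactone hydrolysis (no measured rate; fast relative to the
  # dehydratase turnover, fittable)
  k_hyd_per_min: 0.05
  # glyceraldehyde-oxidation side reaction, as a fraction of AldT capacity
  k_gaox: 0.05
# cofactor saturation constant for AldT (NAD+) and LDH (NADH); not measured,
# small so the factor is ~1 at >= 1.25 mM cofactor
cofactor_km_mM: 0.05
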