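# Methods

## Model

`cascadekin` models a cell-free cascade that oxidises D-mannose to
mannono-1,4-lactone (AldT, NAD⁺-dependent), hydrolyses the lactone to
mannonate, dehydrates mannonate to 2-keto-3-deoxygluconate (ManD), cleaves
KDG into pyruvate and glyceraldehyde (KDGA, reversible) and reduces
pyruvate to L-lactate (LDH, NADH-dependent).  The state is a ten-component
concentration vector (eight carbon species plus NAD⁺/NADH) evolved by mass-
action/Michaelis–Menten ODEs.  Assumptions:

- **Well-mixed, isothermal, constant volume.** Timed additions are
  concentration spikes; the slight dilution of a real pipetting step is
  ignored.  Temperature is fixed at 323 K; pH, ionic-strength effects and
  Maillard chemistry are not modelled mechanistically.
- **Saturation kinetics with capacity decay.** Every enzymatic rate is
  bounded by the loading in U/ml (numerically mM/min), decayed as
  `2^(−(t−t_add)/t_½)` from the enzyme's own addition time with the
  half-life measured under operating conditions.  The deactivation plateau
  is fixed at zero.
- **One combined Km for the aldol addition.** The aldolase was
  characterised with a single Michaelis constant for pyruvate +
  glyceraldehyde; the addition branch is a rapid-equilibrium random-order
  form with that constant in both factors, which is symmetric and reduces
  to single-substrate MM when one partner saturates.
- **Thermodynamically consistent reversible aldol.** The net rate is a
  reversible uni-bi law whose numerator is proportional to
  `[KDG] − [PYR][GA]/K_eq'` (`K_eq' = 1000·exp(−ΔG°′/RT)` mM with
  ΔG°′ = +6.2 kJ/mol for cleavage), over a shared binding denominator.
  The forward limit is exactly MM in KDG and the reverse limit is exactly
  the scaled addition law, with the scale fixed by the Haldane relation —
  so the rate changes sign exactly at the mass-action ratio `K_eq`, at any
  composition.  A single multiplier (`aldol_scale`) scales the whole step
  and is the natural free parameter when fitting.
- **Cofactor dependence.** No cofactor Km was measured for AldT or LDH;
  both carry a saturable factor `C/(K_cof + C)` with `K_cof = 0.05` mM by
  default (configurable, 0 disables it).  At the ≥ 1.25 mM cofactor used
  in practice the factor is ≥ 0.96, so behaviour stays substrate-limited
  while turnover still stops at zero cofactor.
- **Lactone route.** ManD also accepts the lactone with similar constants,
  but modelling both routes would double-count the pool; the model sends
  the lactone through first-order spontaneous hydrolysis
  (`k_hyd = 0.05 min⁻¹` by default, fittable — fast relative to ManD
  turnover, consistent with the lactone signal decaying earlier than
  mannonate) and lets ManD act on mannonate only.
- **Glyceraldehyde oxidation.** Glycerate formation is attributed to the
  dehydrogenase acting on accumulated glyceraldehyde; the rate is
  `k_gaox·V_AldT(t)·[GA]/(K_m+[GA])` with `k_gaox = 0.05` and the
  dehydrogenase Km reused, consuming NAD⁺ one-for-one so the cofactor pool
  stays closed.  The step can be disabled.
- **Not modelled:** thermal NAD⁺ decomposition (observed not to limit
  yields on the 18 h timescale), product inhibition and intermediate
  inhibition (suspected at ≥ 25 mM substrate but unquantified), LDH
  reversibility.

## Parameters

Packaged defaults (`src/cascadekin/data/params_cascade.yaml`), measured at
50 °C, pH 7.0:

| enzyme | Km (mM) | Vmax (U/mg) | kcat (s⁻¹) | t_½ (h) |
|---|---|---|---|---|
| AldT (mannose) | 9.73 | 5.20 | 2.51 | 9.8 |
| ManD (mannonate) | 5.37 | 2.39 | 1.67 | 1.4 |
| KDGA (pyr+ga combined) | 8.07 | 17.04 | 10.51 | ∞ |
| LDH (pyruvate) | 10.95 | 194.3 | 116.58 | ∞ |

Standard loadings 0.2/0.1/0.4/11.6 U/ml (AldT/ManD/KDGA/LDH).  Recipes for
the standard one-pot (5 mM mannose + NAD⁺), the labelled 10 mM run, the
sequential 20 mM protocol and the two biomass-comparison runs are packaged
as YAML.

## Synthetic data

The generators emulate the *statistical* form of the two read-outs, not
the instruments: NMR-style courses are the simulation sampled every
6.5 min over 16 h, normalized per species to its own maximum (absolute
intensities between NMR peaks are not comparable under short acquisition),
with additive homoscedastic Gaussian noise (default sd 0.02 of the
per-species maximum) applied after normalization and clipped at zero;
pyruvate and the cofactors are excluded because they never show a usable
signal.  HPLC-style courses are concentrations for mannose and lactate at
0/1/4/8/10/18 h in replicates with additive noise in mM (default sd 0.1).
No error model was reported for either instrument, so additive Gaussian is
the simplest structure that exercises the fitters; real NMR integrals have
correlated, possibly intensity-dependent errors that these generators do
not reproduce.  Consequently, passing recovery tests demonstrate that the
estimation machinery is correct and well-conditioned under the assumed
noise, not that real spectra would constrain the parameters equally well.

## Fitting

Half-lives: least squares of `A₀·2^(−t/t_½)` with the plateau fixed at
zero; non-decaying data return t_½ = ∞ with a warning.  Cascade fits:
bounded trust-region least squares (lmfit/`least_squares`) on residuals
between data and simulation, with the model prediction max-normalized per
species when the data are relative integrals.  Multi-start (default 5
starts: the nominal value, then log-uniform draws within bounds from a
seeded generator) guards against the multimodality of the SSR surface in
(V_ManD, k_hyd); fits are bit-for-bit reproducible given the seed.
Standard errors come from the jacobian-based covariance at the optimum;
estimates at a search bound are flagged.  Mechanism comparison fits the
cascade twice — irreversible cleavage vs. net reversible aldol, same free
parameters — and selects the lower `n·ln(SSR/n) + 2k` score, ties going to
the simpler mechanism; AIC-style scoring was chosen over an F-test because
the variants need not be nested.

## Numerics

LSODA with rtol 1e-8 / atol 1e-10 by default (the LDH/ManD capacity
spread of two orders of magnitude makes the system mildly stiff); fit
objectives use rtol 1e-7 with a finite-difference step of 1e-3 so solver
noise stays far below the jacobian perturbation.  Events (additions,
spikes) are handled by segment-wise integration with exact state splicing;
values reported at an event time are post-addition.  States are clipped at
zero inside the derivative (stiff steps can undershoot) and in reported
trajectories.  On the standard recipe, carbon and cofactor totals hold to
~1e-15 relative, the dehydrogenase-only limit matches the implicit
closed-form progress curve to ~2e-11, and a fixed-step RK4 integration
(dt = 0.001 h) agrees to ~5e-7.  Problem sizes used in the test-suite
Monte-Carlo studies: 20 seeded replicates for parameter recovery and for
half-life recovery, 2×20 seeded trials for mechanism discrimination.

## Known model-vs-data gaps

With the measured constants the model reproduces the cascade's qualitative
behaviour (early lactate burst, lactone decaying before mannonate, a
mannonate remainder, glycerate formation) but three quantitative
observations from the original experiments are *not* reproducible from
those constants, and the package makes no attempt to force them:

1. **Early mannose consumption.** At 0.2 U/ml and Km = 9.73 mM, the
   integrated capacity over 3 h (≈ 32 mM with decay) cannot cover the
   ≈ 55 mM progress integral that ≥ 99 % consumption of 10 mM would
   require; the simulation reaches ≈ 91 % at 3 h.  The observed complete
   consumption implies faster in-situ kinetics than the isolated assay.
2. **Late KDG re-accumulation.** In a thermodynamically consistent
   well-mixed model, once the dehydratase has died the KDG level tracks
   the quasi-equilibrium `[PYR][GA]/K_eq ≈ 10⁻³ mM` and declines
   monotonically; the observed slow linear re-accumulation cannot arise
   from the reversible aldol step alone at ΔG°′ = +6.2 kJ/mol.  This is
   consistent with the original analysis needing a second, empirical
   mechanism to fit the KDG signal.
3. **Residual AldT activity.** The pure exponential with t_½ = 9.8 h
   predicts 24.3 % activity at 20 h where 30 % was measured — the measured
   decay is slightly non-exponential.

These gaps are properties of the parameter set, not of the integrator, and
are left visible rather than absorbed into re-tuned constants.

## Limitations

Single-compartment batch only; no identifiability analysis beyond standard
errors; no Bayesian uncertainty; the relative-integral likelihood treats
the per-species normalization as exact, which slightly underweights
species whose maxima are themselves noisy.
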