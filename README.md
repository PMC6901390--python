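# cascadekin

Kinetic modelling, simulation and parameter fitting for a **cell-free
four-enzyme cascade that converts D-mannose into L-lactic acid** — the kind
of minimal, cofactor-balanced in-vitro pathway used to valorise
mannose-rich waste streams such as spent-coffee-ground hydrolysate.

The package is aimed at biocatalysis researchers who want to ask
quantitative questions about such cascades: where the kinetic bottleneck
sits, how much product a loading scheme can deliver before the least
stable enzyme dies, whether an observed intermediate transient needs a
reversible step to be explained, and how well time-course read-outs
constrain the underlying parameters.

## The model

The cascade couples four reactions plus two non-enzymatic/side steps
(concentrations in mM, capacities in U/ml ≡ mM/min):

| step | reaction | rate law |
|---|---|---|
| AldT (aldohexose dehydrogenase) | MAN + NAD⁺ → ML + NADH | `V_AldT(t)·[MAN]/(K_m+[MAN])·f(NAD⁺)` |
| spontaneous hydrolysis | ML → MA | `k_hyd·[ML]` |
| ManD (mannonate dehydratase) | MA → KDG | `V_ManD(t)·[MA]/(K_m+[MA])` |
| KDGA (KDG aldolase), reversible | KDG ⇌ PYR + GA | reversible uni-bi law, zero exactly at `[PYR][GA]/[KDG] = K_eq` |
| LDH (lactate dehydrogenase) | PYR + NADH → LA + NAD⁺ | `V_LDH(t)·[PYR]/(K_m+[PYR])·f(NADH)` |
| side oxidation | GA + NAD⁺ → GLYA + NADH | `k_gaox·V_AldT(t)·[GA]/(K_m+[GA])·f(NAD⁺)` |

Each capacity decays thermally from the enzyme's own addition time,
`V(t) = V₀·2^(−t/t_½)` (t_½ = 9.8 h for AldT, 1.4 h for ManD, ∞ for KDGA
and LDH).  The aldol equilibrium constant comes from the cleavage Gibbs
energy, `K_eq = exp(−ΔG°′/RT)` with ΔG°′ = +6.2 kJ/mol at 323 K, and the
addition branch is tied to the cleavage branch by a Haldane constraint so
the net rate is thermodynamically consistent.  NADH made by the first
oxidation is consumed by the last reduction, so the cofactor pool is
conserved; carbon is conserved by construction (C6 → C6 → C6 → C3+C3 →
C3).  Because only the pyruvate half of each cleaved KDG reaches lactate,
the theoretical maximum is **1 mol LA per mol mannose — 50 % of the
carbon**.

## Worked example

Simulate the standard one-pot reaction (5 mM mannose, 5 mM NAD⁺, loadings
0.2/0.1/0.4/11.6 U/ml of AldT/ManD/KDGA/LDH, 50 °C, 18 h):

```bash
$ cascadekin simulate --recipe onepot_standard --out onepot.csv
final LA titre: 2.8 mM
yield: 55.3 % of theoretical maximum
```

2.8 mM lactate from 5 mM mannose is 55.3 % of the 5 mM ceiling: the run is
limited by the dehydratase, whose 1.4 h half-life leaves roughly half of
the mannonate pool unconverted.  The sequential proof-of-concept protocol
(20 mM mannose; ManD added at 1.5 h, KDGA at 16.5 h, LDH plus a 10 mM NADH
spike at 17.5 h):

```bash
$ cascadekin simulate --recipe sequential_paper --out seq.csv
final LA titre: 5.1 mM
yield: 25.5 % of theoretical maximum
```

Lactate appears only after the final enzyme enters — a one-hour production
window — which is why the sequential yield is far below the one-pot value.

The same things are available as library calls:

```python
import cascadekin as ck

recipe = ck.builtin_recipe("nmr_onepot")        # 10 mM labelled mannose
data = ck.generate_nmr_timecourse(recipe, noise=ck.NoiseModel(sd=0.02, seed=1))
spec = ck.FitSpec(free={"vcap_ManD": (0.02, 0.5)}, n_restarts=5, seed=1)
fit = ck.fit_cascade_params(data, spec, recipe)
print(fit.estimates)   # {'vcap_ManD': 0.0986...}  (truth: 0.1 U/ml)
```

Other subcommands: `cascadekin generate` (synthetic NMR/HPLC CSVs),
`cascadekin fit` (parameter estimation from a time-course CSV, optional
mechanism comparison), `cascadekin hydrolysis` (biomass sugar-content
correction).  Time courses travel as tidy CSV with columns
`time_h, species, value, kind, replicate`.

## Layout

- `src/cascadekin/cascade_model.py` — species, parameters, rate laws, ODE assembly
- `src/cascadekin/simulator.py` — event-aware integration, conservation diagnostics
- `src/cascadekin/mass_balance.py` — yield/titre/assay/hydrolysis arithmetic
- `src/cascadekin/fitting.py` — half-life fits, cascade fits, mechanism comparison
- `src/cascadekin/synthetic_data.py` — NMR/HPLC/decay-assay generators
- `src/cascadekin/io.py`, `cli.py` — YAML configs, tidy CSV, command line
- `docs/methods.md` — modelling assumptions, defaults and limitations
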