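# p2xkin

Kinetic analysis of P2X2 receptor activation gating.

P2X2 receptors are trimeric cation channels opened by extracellular ATP
binding at three inter-subunit sites. Their concentration–activation
relationships are steep (Hill coefficients near 2) even though, at the level
of the individual binding steps, each bound ATP can *hinder* the next. This
package implements the modelling workflow that untangles such subunit
cooperativity from whole-cell recordings:

- a family of 10-state Markov schemes (closed C0–C3, flipped F1–F3, open
  O1–O3) with three binding steps per conformational tier, a flip
  isomerization C_x–F_x and an opening F_x–O_x at every liganding degree
  x = 1..3, parameterized by 26 free rate constants k1…k26;
- coupled model variants for a gating mutant (H319K) and a low-affinity
  fluorescent agonist (fATP), obtained from the reference scheme by
  dimensionless coupling factors (f, g on the flips; h, j on binding and
  unbinding; m as an extra flip accelerator), so that two or four datasets
  can be fitted *simultaneously with shared rate constants*;
- a spectral master-equation solver (`dp/dt = Q(L) p`, eigenvalue method with
  a stiff-integrator fallback) for concentration-jump protocols and
  equilibrium concentration–P_o and concentration–binding curves;
- a weighted global least-squares objective
  `S = Σ_traces u Σ_t (I_m − I_c)²/σ_I² + Σ_rel s_k Σ_L (P_om − P_oc)²/σ_Po²`
  with effective-fit-point balancing between time courses and steady-state
  relationships, Levenberg–Marquardt optimization on log parameters, and
  covariance-based standard errors;
- net probability-flux analysis `F_XY = ∫ (p_X k_XY − p_Y k_YX) dt` that
  identifies the transition pathways used during activation and deactivation
  and quantifies gating hysteresis;
- Gibbs free-energy profiles `ΔG_A = −RT ln(L k_x/k_{x+1})` (binding) and
  `ΔG_E = −RT ln(k_x/k_{x+1})` (isomerizations) with per-tier cooperativity
  labels;
- the pre-model reductions: P_o,max from ensemble noise
  (`P_o,max = 1 − σ²/(i·I_max)`), Hill fits, two-Gaussian amplitude-histogram
  fits for the unitary current, and peak truncation/normalization of traces;
- a synthetic-data generator that emulates the whole experimental design
  (four conditions, binomial channel noise, per-point variances, single-
  channel amplitude samples) from a documented ground-truth parameter set, so
  the entire pipeline is testable without recordings.

## Worked example

`examples/` holds one short script per capability. For instance

```bash
python examples/02_concentration_response.py
```

prints

```
wt·ATP       EC50 =   1215.1 nM   Hill = 2.06   Po,max = 0.715
H319K·ATP    EC50 =     20.8 nM   Hill = 1.16   Po,max = 0.717
wt·fATP      EC50 =  11978.7 nM   Hill = 2.29   Po,max = 0.716
H319K·fATP   EC50 =    679.0 nM   Hill = 1.16   Po,max = 0.717
```

— the same 26 rate constants describe all four conditions; the H319K flip
factors shift the curve ~60-fold left and the fATP binding factors ~10-fold
right. `examples/05_energetics.py` shows why the wild-type curve is steep
despite anticooperative binding:

```
dG_A (kJ/mol) binding, closed row : ['+1.24', '+4.32', '+6.98']
dG_E (kJ/mol) flip isomerizations : ['+16.83', '+3.38', '-11.22']
binding_closed        : ['negative', 'negative']
isomerization_flip    : ['positive', 'positive']
```

Binding free energies rise with liganding (negative cooperativity, ~+3
kJ/mol per step) but the flip free energies fall much faster (−13 to −15
kJ/mol per step), overbalancing it — activation as a whole is positively
cooperative. `examples/03_global_fit.py` demonstrates that a coupled
two-scheme fit recovers the mutant factors (f = 11.10 fitted vs 11.20
generating) from perturbed starts.

A thin CLI wraps the same library calls:

```bash
p2xkin simulate --seed 0 --out data/        # write synthetic bundles
p2xkin report --seed 0 --out results/demo   # full pipeline
```

## Layout

```
src/p2xkin/
  model.py       state space, transition table, coupling factors, Q(L)
  relax.py       spectral relaxation, equilibria, protocols, curves
  fitting.py     weights, objective, coupled LM fit, standard errors
  flux.py        flux densities, net fluxes, pathway graphs, hysteresis
  energetics.py  free-energy profiles, cooperativity, cycle energies
  reduction.py   noise Po,max, Hill fit, amplitude histograms, truncation
  synthetic.py   ground truth fixture and data generators
  io.py          bundle CSV/JSON formats, RunConfig, pipeline
  cli.py         click command-line surface
docs/methods.md  model description, assumptions, numerical choices
examples/        narrative scripts, one per capability
```
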