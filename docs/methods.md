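# Methods

## The gating model

A P2X2 receptor is modelled as a continuous-time Markov chain on ten states
arranged as a three-rung ladder. Horizontal transitions bind or unbind one
ATP (or fATP) molecule; vertical transitions are conformational. The closed
row C0–C3 carries the three sequential binding steps; from each liganded
closed state C_x a "flip" leads to F_x — an intermediate conformation that
represents propagation of the binding signal from the distant inter-subunit
sites toward the transmembrane gate — and from each F_x an opening
isomerization leads to O_x. The unliganded channel cannot open (no
constitutive activity), so F0/O0 do not exist.

Statistical multiplicities are fixed by the trimeric stoichiometry and are
part of the notation, not free parameters: an association step from a state
with x ligands bound proceeds at (3 − x)·k·L, a dissociation at x·k, and
the isomerizations at 1·k. The 26 rate constants themselves are free — no
detailed-balance or stoichiometric constraint ties them, so the model can in
principle represent driven cycles; cycle free energies are reported
(`energetics.cycle_energies`) rather than constrained.

The rate-index convention is row-major: C-row binding (k1–k6), flips
(k7–k12), F-row binding (k13–k16), openings (k17–k22), O-row binding
(k23–k26), with odd indices forward (toward O3) and even indices backward.
The forward direction of every pair points toward O3, which also fixes the
positive sign of probability fluxes.

Four coupled variants share the 26 constants. F1 is the reference (wild
type with ATP). F2 (H319K mutant, ATP) multiplies the flip rates k7, k9,
k11 by f and the back-flips k8, k10, k12 by g — the mutation sits in the
transmission pathway and is modelled as acting on the flip step only. F3
(wild type, fATP) multiplies every association constant by h, every
dissociation constant by j, and additionally accelerates the flips by m.
F4 (H319K, fATP) combines f, g, h, j; m is not applied in F4.

Units: concentration in µM, time in s, association constants in µM⁻¹s⁻¹.

## Solving the master equation

`dp/dt = Q(L) p` is solved by eigendecomposition,
`p(t) = V exp(Λt) V⁻¹ p0`, vectorized over the sampling grid. Spurious
positive real parts in the computed spectrum (a generator's eigenvalues have
non-positive real parts) are clamped to zero to keep long-grid exponentials
bounded. If the eigenvector matrix is ill-conditioned (condition number
above 1e12, e.g. for near-defective generators) the solver falls back to
LSODA integration with the analytic Jacobian. Occupancies more negative
than −1e-9 raise an error; smaller violations are clipped and renormalized.
Equilibrium distributions are the normalized null vector of Q from an SVD;
at L = 0 the chain is reducible and the null vector is the point mass on
C0, which is also the correct long-time limit from any start.

Concentration-jump protocols are piecewise-constant in L; each segment's
initial condition is the previous segment's exact final occupancy. The
default per-segment sampling grid is 100 uniform points (the spacing of the
fitted time courses); flux integration uses far denser grids (below).

## Weighting and the global objective

Current time courses contribute hundreds of points each, steady-state
concentration–P_o relationships only a handful. To make the two data kinds
carry equal weight, every trace point is weighted u (default 0.1) and each
steady-state relationship k of n_k points receives
s_k = (E/n_s)/n_k where E = u·(total trace points) — so all relationships
share E effective points equally and the time courses together also carry E.
The objective is the variance-weighted sum of squares over both parts;
simulated traces are normalized to their own maximum over the activation
window, mirroring the normalization of measured currents, and activation
windows are truncated at the peak so that desensitization (absent from the
scheme) never enters the fit.

Optimization is Levenberg–Marquardt on log-transformed parameters, which
enforces positivity and makes steps act on relative changes; iteration stops
when the relative change of S falls below a configurable threshold (default
1e-6). Because LM is local, a seeded multi-start option (log-uniform
perturbations around the supplied start) is provided and used for the
harder coupled fits. Model evaluations that fail numerically during a
search (e.g. a parameter excursion that never opens the channel) return a
large penalty residual instead of aborting the fit; the public `objective`
function reports such failures as exceptions.

Standard errors are sqrt of the diagonal of the inverse Gauss–Newton normal
matrix of the weighted residuals at the optimum, computed in the log
parameterization and mapped to the natural scale by the delta method (the
relative error se/|p| is parameterization-free). Parameters with no
influence on any residual are reported as unavailable (NaN), not fabricated.

## Flux and pathway analysis

Unidirectional flux densities are p_X(t)·k_XY with the full
(multiplicity- and L-scaled) rates; net densities are their differences and
total net fluxes their trapezoidal time integrals. Activation fluxes are
integrated from the jump to the time of peak open probability (the fitted
window); deactivation over the full off-segment (default 5 s, configurable
to 8 s). Because flip/open transients are orders of magnitude faster than
the fitted sampling, flux grids are refined by doubling until the largest
total flux changes by less than 0.1% (integral bookkeeping against occupancy
changes reaches ~1e-7 at 4·10⁴ points per segment). Pathway graphs keep
pairs with |F| ≥ 0.01 by default; the hysteresis score per pair is
|F_act + F_deact|, zero when deactivation exactly retraces activation.

## Free energies and cooperativity

ΔG_A = −RT ln(L·k_fwd/k_bwd) for the seven binding pairs (ratios of bare
rate constants — multiplicities are excluded) at a reference concentration
of 1 µM (near the wild-type EC50); ΔG_E = −RT ln(k_fwd/k_bwd) for the six
isomerizations. T defaults to 293 K (room-temperature recordings) and is
configurable. Successive differences within a tier are labelled
negative/positive/none cooperativity with a 0.5 kJ/mol dead band.

## The synthetic-data generator

No recordings ship with the package; the generator emulates the full
experimental design from a documented ground-truth fixture. The fixture is
*not* a fitted parameter set: forward rates and equilibrium constants were
chosen once, at design time, to reproduce the qualitative physiology —
wild-type EC50 ≈ 1.2 µM with Hill slope ≈ 2, P_o,max ≈ 0.715 set by the
F3–O3 equilibrium (2380/938 s⁻¹, the physically rescaled values of the
unresolvably fast fitted pair), negative binding cooperativity in every
tier, strongly positive flip cooperativity, and an H319K-like left shift
under the printed coupling factors (f = 11.20, g = 5.14e-4, h = 0.17,
j = 5.57, m = 15.59). Backward rates off a spanning tree are derived from
cycle closure, so the fixture obeys detailed balance exactly — convenient
for equilibrium flux checks — even though the fitter never imposes it.

Ensemble traces are i·N·P_o(t) for N = 1000 channels of unitary current
i = 0.80 pA (wt) / 0.78 pA (H319K), with Gaussian noise of variance
i²·N·P_o(1−P_o) + σ₀² (σ₀ = 2 pA instrument floor) per sweep, averaged over
10 sweeps; the quoted per-point variance equals the variance of the noise
actually injected, so objective weights are statistically consistent. An
overall noise scale multiplies both (0 disables noise and the quoted
variance reverts to the noise model, keeping weights positive). Steady-state
points get binomial-like noise with an ensemble size of 2000. Per-condition
pulse concentrations span each variant's EC50 range, and the steady-state
relationships carry 6/7/4/11 points (wt·ATP / H319K·ATP / wt·fATP /
H319K·fATP), matching the four-dataset design the fit is built for.
Desensitization, series-resistance artifacts and solution-exchange kinetics
(~10 ms, fast relative to the gating) are not emulated — passing tests show
the pipeline's correctness and identifiability under the modelled noise,
not robustness to those artifacts.

The scaled-down parameter-recovery experiment in the acceptance tests uses
3 pulse concentrations per condition, 100 points per trace and a noise
scale of 0.001 (per-point current noise ~10⁻⁴ of the peak). At that noise
the coupled four-scheme fit pins the coupling factors to within a few
percent; soft directions remain — the absolute speed of the F3–O3 pair and
of weakly visited flips moves tens of percent under noise while its
equilibrium constant stays put, the same sloppiness that motivates the
k21/k22 rescaling.

## Known limitations

- Only the F1–F4 family is tested; the transition-table machinery could
  describe other ladders but nothing validates them.
- Covariance-based standard errors only; no profile likelihoods.
- The fit assumes instantaneous solution exchange and no desensitization;
  traces must be truncated at the peak before fitting.
- Voltage is not a model variable (all emulated data at −50 mV).
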