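# Methods

This note records the model, the numerical conventions, and the design
choices behind `chemorad`, at the level of detail a maintainer or reviewer
needs to interpret (and distrust appropriately) its outputs.

## Model and assumptions

The state is `(T, TR, N, I, M, R)`: tumor-sensitive cells, tumor-resistant
cells, normal cells, immune (natural-killer) cells, and the chemotherapy
and radiotherapy concentrations in mg.  Assumptions baked into the
equations:

- **Logistic growth, separate capacities.**  `T`, `TR` and `N` each grow
  logistically against their *own* carrying capacity (`Tmax` for both
  tumor pools, `Nmax` for normal cells).  The two tumor subpopulations do
  not compete for a shared capacity; the only coupling between them is the
  one-way mutation flux `μT`.
- **Mutation-driven resistance.**  Resistant cells arise only from
  sensitive cells (rate `μ`, default `1e-3`/day); there is no back
  mutation and no spontaneous generation, so `μ = 0` with `T(0) = TR(0) = 0`
  keeps both pools identically zero (a tested invariant).
- **Saturating drug kill.**  Each drug kills each cell type at per-capita
  rate `a·(1 − e^(−δC))`: linear in concentration `C` at low dose,
  saturating at the kill coefficient `a` for large `C`.  The saturation
  exponents `δ1, δ2` default to 1/mg (the stability thresholds quoted for
  the model are written with unit exponents); both are configurable.
  Consequence worth internalizing: **beyond a few mg the dose no longer
  matters** — at the default decay `d1 = 0.011`/day even the low infusion
  0.25 mg/day reaches `M ≈ 4.5` mg within ten days, where the kill
  fraction is already ≈ 0.99.
- **Immune dynamics.**  Constant source `s`, Michaelis–Menten-type
  stimulation by tumor (`ε1 I T/(ε2 + T)`), natural death `d`, exhaustion
  `α2 I T`, plus drug toxicity.  Immune pressure on the tumor is the
  bilinear `α1 I T` with the very small default `α1 = 1e-8`.
- **Single drug compartment.**  `dM/dt = V_M(t) − d1 M` (and likewise R):
  well-mixed, no spatial dependence, no multi-compartment
  pharmacokinetics.  Under constant infusion the closed form
  `V/dk + (c0 − V/dk)e^(−dk t)` holds and is tested against the
  integrator to < 1e-6 relative error.

Units: days for time, cells for the four pools, mg for drug amounts.

## Numerical conventions

- **Integration.**  Adaptive explicit Runge–Kutta (`solve_ivp` RK45) with
  `rtol = 1e-8` and per-compartment `atol = 1e-6 ×` a typical scale
  (1e6 cells for the pools, 1 mg for drugs); LSODA is the automatic
  fallback on step failure.  The system is non-stiff at the default
  values.  Piecewise-constant dose schedules are integrated
  segment-by-segment between breakpoints (schedules are right-continuous
  at breakpoints).
- **Nonnegativity.**  The vector field cannot drive a compartment below
  zero analytically, but adaptive steppers can overshoot; the right-hand
  side is therefore evaluated on states clipped at zero and trajectories
  are floored at zero post hoc.
- **Equilibrium residuals on the projected field.**  Because cell counts
  are constrained nonnegative, a steady state may sit on the boundary of
  the orthant: a component pinned at zero whose raw inflow is negative.
  Residuals are measured on the projected vector field (outflow at such a
  boundary suppressed), and the raw residual plus the list of pinned
  components are reported alongside (`Equilibrium.raw_residual`,
  `boundary_defect`) so nothing is hidden.
- **Tumor-free equilibrium** is closed-form: drugs at `V/d`, then
  `N = Nmax(1 − (aN·sM + bN·sR)/r3)` and `I = s/(d + aI·sM + bI·sR)`
  with `sM, sR` the steady kill fractions.  If toxicity exceeds `r3` there
  is no positive normal branch and the `N = 0` state is flagged `other`.
- **Coexistence equilibrium** by block elimination: drugs analytically,
  then a hybrid-Newton root find on the `(T, TR, I)` subsystem (which is
  independent of `N`) in capacity-scaled variables, multi-started from a
  3×3×3 grid over `(0, Tmax]² × (0, s/d]`, then the scalar quadratic for
  `N` solved analytically keeping nonnegative roots.  Multiple positive
  roots are all returned, sorted by `T` descending.  A cross-check via an
  independent scalar reduction (eliminate `I` and `TR` given `T`, bisect
  in `T`) agrees to 1e-8 relative and is kept as a test oracle.
  At the default values with `r3 = 0.007` the `N` equation has **no**
  nonnegative root — the tumor-activation term `kT(1 − T/T*)` is strongly
  negative at `T ≈ 4.06e7 ≫ T* = 5e5` — so the returned state has `N`
  resting on the zero boundary, flagged as above.
- **Stability** is classified from the eigenvalues of the full 6×6
  analytic Jacobian (verified against central finite differences):
  stable iff the largest real part is below −1e-9, marginal within
  ±1e-9.  The simplified immune-threshold inequality
  (`I > r1/α1` for tumor-free stability) is evaluated and reported for
  comparison, but it omits the mutation and kill terms, so the eigenvalue
  verdict is authoritative.

## Treatment simulation and trajectory metrics

Strategies are constant-infusion runs at the named levels low 0.25,
standard 0.5, high 1.0 mg/day (chemo alone, radio alone, or combination)
from the clinical initial state `T = 3.5e6, TR = 1.4e6, N = 1e6, I = 1e6,
M = R = 0`; default horizon 200 days (all events of interest occur before
day 150), sampled at ≥ 4 points/day.

- **Inhibition time** is the time of the strict global maximum of a
  compartment series (first occurrence; `None` for series nonincreasing
  from the start).  Caveat: at the default parameters the tumor-sensitive
  pool saturates toward `≈ 4.44e7` cells rather than rising and falling.
  Under low-dose chemo the slowly ramping kill term produces a genuine
  interior peak at ≈ 27 days; under standard/high dose the series creeps
  monotonically onto the plateau and the argmax is a plateau point, not a
  biological event.  The visually read "day the curve flattens" (~day 20)
  and the strict argmax are different functionals; this package reports
  the strict argmax, and its robustness-to-tolerance test is run on the
  low-dose case where the peak is real.
- **Eradication time** is the first *sustained* crossing below a
  threshold (default 1 cell — ODE counts never reach zero exactly);
  transient dips do not count.  At the default kill coefficients
  eradication of the resistant pool is impossible at any infusion rate:
  the maximal combined kill `aTR + bTR = 0.11`/day is below the resistant
  growth rate `r2 = 0.25`/day, so `TR` equilibrates near `3.1e7` cells
  for every dose combination.  What the dose–response invariants do
  guarantee (and tests assert) is monotonicity — higher dose, lower final
  burden — and that combination therapy is never worse than either single
  therapy.
- **Healthy-cell reporting.**  "Normal cells stayed above threshold" has
  no canonical definition here; the summary table reports the `N` nadir,
  the nadir as a fraction of `N(0)`, and a flag against a configurable
  reference fraction (default 0.5) — a reporting convention, not a claim.

## Calibration

Observations are `(time, diameter)` pairs.  Diameters convert to cell
counts under a spherical-tumor convention at fixed packing density;
the default density `9.455e5 cells/cm³` is pinned by the clinical
anchor (4.9e6 total tumor cells ↔ 2.147 cm), the only choice consistent
with that record — roughly a thousandfold below typical histological
packing, so treat absolute cell counts as model-internal currency rather
than biology.  The loss is the SSE between the model's total burden
`T + TR` and observed counts (option: diameter units), minimized over a
free subset (default: the four tumor kill coefficients `aT, bT, aTR,
bTR`, the least-constrained constants) within the published ranges by
`least_squares(trf)` with Latin-hypercube multi-start (default 8 starts,
seeded, bit-reproducible).  Values landing on a bound are flagged.

**Identifiability, measured.**  With two observations and four free
parameters the clinical fit is under-determined by construction; it is an
existence/shape demonstration, not parameter inference.  The synthetic
recovery harness quantifies the sharper limit: because only the *sum*
`T + TR` is observed, the two kill routes compensate along a near-flat
likelihood ridge.  Noise-free recovery of any two of `{r1, r2, aT, aTR}`
from 8 observations is exact to < 1e-14, but 10% multiplicative diameter
noise (≈ 30% cell-count noise after cubing) yields median relative errors
of order 50–100% for `(aT, aTR)` — anticorrelated, in the sensitivity
ratio of the two plateaus — and the error does not vanish as the noise
shrinks tenfold.  This is a property of the observation design, not the
optimizer (more starts do not change it).  Conclusions that depend on
individual kill coefficients from size-only data should not be trusted.

## Sensitivity analysis

Latin hypercube sampling (one draw per equal-probability stratum per
parameter, strata permuted independently, uniform marginals over the
published ranges) over the seven screened constants
`r2, aTR, bTR, d1, d2, VM, VR`; default n = 100, output = total burden
`T + TR` at day 150 (per-compartment options available).  PRCC:
rank-transform everything, regress each parameter's ranks and the
output's ranks on all other parameters' ranks, correlate the residuals;
p-values from `r·sqrt(df/(1 − r²))` with `df = n − 2 − (k − 1)`.  Failed
integrations become missing outputs, excluded with a reported count
(> 10% failures aborts).  The implementation is verified against an
independent inverse-correlation-matrix oracle to 1e-10 and its p-values
against the nominal type-I rate under the null.

Observed behavior at the defaults: the signs are stable (`r2, d1, d2`
positive; `aTR, bTR, VM, VR` negative — in 18/20 seeds at n = 100), but
the *ranking* of magnitudes is not: `bTR`, `aTR` or `VM` usually carries
the largest |PRCC|, with `r2` largest in only a few seeds.  Because kill
saturates, `VM`'s influence is concentrated in its lowest stratum
(near-zero dose), a caution for interpreting dose PRCCs sampled over
`(0, 1]` mg/day.

## Synthetic data

The generator emulates the calibration's observation process: simulate
known ("true") parameters from the clinical initial state, read `T + TR`
at sparse times (default 8 points over 0–140 days), convert to diameter,
multiply by `exp(σz)`, `z ~ N(0,1)` seeded (σ default 0.1; measurement
error on a diameter scales with size).  It does *not* emulate real-data
features such as inter-patient variability, measurement rounding,
censoring/dropout, or model misspecification — recovery results bound
what the calibration can do when the model is exactly right, an upper
bound on real performance.

## Problem sizes and determinism

Default analysis sizes: 200-day simulations at 4 samples/day; n = 100
LHS rows per sensitivity run; 8 multi-starts per fit; 8-observation,
20-seed recovery experiments.  Every stochastic component (LHS, noise,
multi-start) draws from an explicit integer seed; repeated runs at the
same seed are bit-identical, and the CLI records seeds and resolved
configuration in a manifest per run.

## Known limitations

- The default parameter set is internally tense: several narrative
  behaviors of this model family (tumor decline under chemo alone,
  resistant-cell eradication under combination therapy) are unreachable
  at the default kill coefficients, as quantified above.  The package
  reports what the equations do.
- Local stability only: no bifurcation tracking, no global analysis.
- No fractionated/pulsed radiotherapy beyond piecewise-constant infusion
  schedules; no toxicity-constrained optimization; no identifiability
  machinery beyond bound-activity flags and the recovery harness.
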