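# Methods

Models, assumptions, numerical choices and known limitations of `angiosim`.

## 1. Growth model

State: tumour volume `V` and carrying capacity `K`, both mm³, both strictly
above the avascular threshold `V* = π/6 ≈ 0.5236 mm³` (a 1 mm diameter
sphere). Dynamics:

```
dV/dt = −λ₁ (V − V*) ln((V − V*)/(K − V*))
dK/dt = −λ₂ (K − V*)
        + c (β + (V − V*)^p)(V − V*) / (α (β + (V − V*)^p) + I)
        − d (K − V*)(V − V*)^(2/3)
```

- Gompertzian volume growth in the vascularised excess `V − V*`; `V`
  increases while `V < K`, decreases while `V > K`.
- Stimulation: proangiogenic factors secreted proportionally to the
  vascularised volume; under therapy the drug concentration `I` competes
  with the clearance `α`, attenuated by the vessel-abnormality factor
  `β + (V − V*)^p`. At `I = 0` the factor cancels and stimulation is
  `(c/α)(V − V*)` regardless of `β, p`.
- Inhibition: endogenous antiangiogenic factors released from the tumour
  surface, hence the `(V − V*)^(2/3)` scaling.

Untreated steady state (with `λ₂ = 0`): `V_ss = V* + (c/(αd))^{3/2}` —
independent of λ₁ (which only sets the timescale), and of `β, p` (which only
act under therapy). As `I → ∞` the stimulation term vanishes and the system
contracts to `(V*, V*)`: the trajectory approaches the avascular floor from
above and never crosses it.

Reference values (library defaults): λ₁ = 0.192 day⁻¹, λ₂ = 0, c = 5.85,
d = 0.00873, α = 1, β = 1, p = 0, initial state (V₀, K₀) = (200, 625) mm³.

Domain guard: right-hand-side evaluation requires both excesses `V − V*`,
`K − V*` to exceed 10⁻¹² mm³; violations raise `DomainError` (wrapped in
`SimulationError` during integration). The abnormality factor is computed
with an overflow guard (`p·ln(v̂) > 700 → ∞`) and the stimulation term is
written as `c v̂ / (α + I/(β + v̂^p))` so that an overflowing factor
saturates the term at its drug-free value instead of producing NaN.

## 2. Pharmacokinetics

Standard two-compartment model with first-order exchange (`k₁₂`, `k₂₁`),
first-order elimination from the central compartment (`k_e`) and zero-order
input `D/T` during an infusion of duration `T`. Hybrid constants:

```
a + b = k₁₂ + k₂₁ + k_e,   a·b = k₂₁·k_e,   b = ½(S − √(S² − 4 k₂₁ k_e))
A = (a − k₂₁)/(V_c (a − b)),   B = (b − k₂₁)/(V_c (b − a))
```

The central concentration is the textbook closed form: during infusion
`(D/T)·[A/a·(1−e^{−a τ}) + B/b·(1−e^{−b τ})]`, after infusion the same
bracket evaluated at `τ = T` decayed by `e^{−a(τ−T)}`, `e^{−b(τ−T)}`.
Multi-dose regimens superpose linearly. The closed form is verified in the
test suite against an independent mass-balance integration of the
compartment ODEs to 10⁻⁶ relative.

Strictly positive rate constants always yield distinct real hybrid roots
(`(k₂₁+k_e)² ≥ 4k₂₁k_e`), so no degenerate branch is needed.

Units: the PK model produces mg/ml of plasma; the growth model consumes
mg/kg. Conversion divides by the plasma density 1.025·10⁻³ kg/ml.

Reference values: V_c = 7.975 ml, k₁₂ = 0.7536, k₂₁ = 0.3144,
k_e = 0.3888 day⁻¹; reference regimen: 0.125 mg (5 mg/kg × 0.025 kg) infused
over 1/48 day on days 1, 4, 8, 11, 15, 18, 22, 25, 29.

## 3. Numerical integration

`scipy.integrate.solve_ivp` (adaptive RK45, dense output), relative
tolerance 10⁻⁸, absolute tolerance 10⁻¹⁰ mm³. The bi-exponential forcing has
slope discontinuities at every infusion start and end, so integration is
restarted at each such breakpoint; within a segment the right-hand side is
smooth and the solver's error control is valid. The dense solution is
sampled onto a uniform 0.1-day grid for plateau detection and endpoint
evaluation. Halving the tolerances changes the reference trajectory by
< 10⁻⁴ relative (tested).

The concentration function inside the right-hand side is a pure-scalar loop
over pre-flattened event constants with an early exit on not-yet-started
doses; this keeps the treated simulation at ~0.1 s per 300-day run, which is
what makes the calibration stage practical.

## 4. Plateau detection

The plateau is reported at display resolution: the first grid sample from
which `round(V)` and `round(K)` agree on a single repeated integer value for
at least 10 days. Two conventions matter:

- nearest-integer comparison (not truncation), because the plateau is
  approached from below — a 12412.94 asymptote must be reported as 12413;
- a minimum duration (10 days) rather than a fixed sample count, because the
  slowly converging `V` and `K` can transiently share the integer band one
  unit below the asymptote for several days.

With these conventions the detected values equal the rounded analytic
steady states exactly for the reference set and all ±20 % one-at-a-time
perturbations of λ₁, c, d, and the detected times land within a few percent
of the reference timings (plateau *times* are inherently solver- and
grid-resolution-dependent; tests allow ±15 %).

## 5. Parameter analysis

- One-at-a-time study (`oat_table`): ±20 % perturbations of λ₁, c, d from
  (V₀, K₀) = (200, 625) over 300 days; records the plateau value/time and
  the percent variation against the unperturbed run. λ₁ changes timing only;
  c and d move the plateau by +31.45/−28.44 % and −23.93/+39.75 %.
- Plateau surface: the analytic `V_ss(c, d)` on a grid (no simulation).
- Bounds (`valid_parameter_bounds`): inverting the steady state at a plateau
  cap `V_max` gives `c_max = α d (V_max − V*)^{2/3}` and
  `d_min = c/(α (V_max − V*)^{2/3})`; requiring `dK/dt ≥ 0` at the anchor
  state (no self-regressing vasculature in untreated growth) gives
  `c_min = α d (K₀ − V*)/(V₀ − V*)^{1/3}` and
  `d_max = c (V₀ − V*)^{1/3}/(α (K₀ − V*))`. At cap 10⁶ mm³:
  c ∈ (0.93, 87.3), d ∈ (5.85·10⁻⁴, 5.47·10⁻²).

## 6. Calibration

Two-stage bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, default `ftol = 10⁻⁶`):

1. **Control stage** — free (λ₁, c, d, K₀); initial point from the reference
   set with K₀ seeded by the reference V₀/K₀ = 200/625 ratio; bounds ≥ 0
   (c ≥ 10⁻¹⁰, since the model requires c > 0) and K₀ ≥ V₀ (an untreated
   curve must not start by shrinking).
2. **Treatment stage** — free (λ₁, c, β, p, K₀); `d` frozen at the control
   estimate (endogenous inhibition is assumed unaffected by an anti-VEGF
   agent); λ₁ bounded above by the control estimate so the fit can express a
   direct antitumour effect but never an accelerated intrinsic growth rate;
   K₀ freed only when the first observation coincides with the first dose
   time (otherwise the pre-treatment capacity is not separately observable
   and stays at its seeded value). Multi-dose-level experiments are fitted
   in dose order, each arm warm-started from the nearest lower level
   (`fit_dose_chain`).

Conventions: the simulation for a fit starts at the first observation time
with `V₀` fixed to the first observed volume; residuals are model − observed
at the observation times, unweighted by default (SD-weighting available via
`FitConfig(sd_weighted=True)`); RMSE divides by the number of observations
`n` (not `n − k`); NRMSE is RMSE over the observed range, in percent;
first-order optimality is the solver's projected-gradient infinity norm.
Instead of manual initial-point tuning, an optional deterministic coarse
pre-scan (`FitConfig(prescan=True)`) tries each free parameter at ×¼, ×½,
×2, ×4 of its initial value.

Identifiability: (c, α, β) are not jointly identifiable with `p = 0`, and
β/p can trade off; recovery tests therefore assert fit quality and the
constrained parameters, not uniqueness of (β, p).

## 7. Synthetic data generator

Emulates xenograft efficacy studies: per arm, one ground-truth parameter set
(the ODE model assumes a homogeneous cohort), a measurement schedule, a
cohort of `n_animals` (default 10), and multiplicative lognormal measurement
noise per animal and timepoint, parameterised for unit mean:
`σ² = ln(1 + cv²)`, `μ = −σ²/2`. Lognormal (not additive Gaussian) because
caliper error scales with tumour size and volumes must stay positive. The
series reports the per-time cohort mean and SD (ddof = 1); `noise_cv = 0`
returns the exact truth with zero SDs. Generation is deterministic under a
fixed seed (`numpy.random.default_rng`).

Parameter-recovery harness (acceptance property): 20 seeded control arms at
5 % per-animal CV, truth (λ₁, c, d) = (0.15, 3.0, 0.005), K₀ = 400. The
magnitude of (c, d) — as opposed to their ratio, which sets the plateau and
is always recovered to ~1 % — is informed only by the early transient in
which `K` relaxes toward its nullcline. The harness therefore samples daily
over days 1–14 and twice-weekly to day 130, and fits with SD-weighted
residuals (the appropriate estimator under multiplicative noise; the
unweighted cost is dominated by plateau-magnitude points and its minimiser
wanders along the flat (c, d)-scaling valley). Median relative errors over
the 20 seeds: λ₁ 0.7 %, c 5.0 %, d 5.0 %, K₀ 10.7 %.

## 8. Limitations and known discrepancies

- **Growth inhibition at day 32.** For the reference treated scenario the
  published reference value is 19.38 % inhibition; this implementation
  computes 91.85 %. The PK closed form here is verified against an
  independent mass-balance integration, the dose (0.125 mg into
  V_c = 7.975 ml over 30 min, nine times) produces peak plasma
  concentrations ~0.015 mg/ml ≈ 15 mg/kg ≫ α = 1, and with β = 1, p = 0 the
  stimulation is then suppressed ~15-fold, which collapses `K` and yields
  strong inhibition. Reproducing 19.38 % would require the concentration
  scale to be ~30× smaller than any defensible reading of the stated units
  (e.g. an implausible plasma density of ~0.03 kg/ml; reading the rate
  constants as per-hour instead of per-day gives 17.2 %, which both misses
  the value and contradicts the drug's ~8-day terminal half-life). The
  faithful pipeline is kept and the discrepancy is reported rather than
  absorbed by unit tweaking; the corresponding acceptance test is expected
  to fail.
- **Plateau times** are solver-step- and grid-dependent; only the plateau
  *values* are reproduced exactly.
- **Growth delay** depends strongly on the chosen reference volume; no
  single published delay value is targeted.
- The model has no resistance, no vessel normalisation dynamics, no
  inter-animal heterogeneity, and the generator mimics neither dropout nor
  caliper bias.
- Calibration is local (trust-region from documented starts), not global;
  profile-likelihood identifiability analysis is out of scope.
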