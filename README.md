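# angiosim

Simulation, analysis and calibration of a vascular tumour-growth model under
antiangiogenic (anti-VEGF) therapy.

## The model

A tumour is described by two coupled state variables, both in mm³: the total
volume `V` and the carrying capacity `K` — the maximal volume the current
vasculature can sustain. Growth is Gompertzian in the vascularised excess
volume above the avascular threshold `V*` (the volume of a 1 mm diameter
sphere, ≈ 0.52 mm³, at which the angiogenic switch occurs):

```
dV/dt = −λ₁ (V − V*) ln((V − V*)/(K − V*))
dK/dt = −λ₂ (K − V*)
        + c (β + (V − V*)^p)(V − V*) / (α (β + (V − V*)^p) + I)
        − d (K − V*)(V − V*)^(2/3)
```

The carrying capacity grows with tumour-secreted proangiogenic stimulation
(coefficient `c`, opposed by clearance `α` and, under therapy, by the plasma
drug concentration `I`, modulated by the vessel-abnormality factor
`β + (V−V*)^p`) and shrinks through endogenous inhibition (`d`, scaling with
the tumour surface `(V−V*)^(2/3)`). Untreated (`I = 0`) the system reaches the
post-vascular dormancy plateau

```
V_ss = V* + (c/(α d))^(3/2),
```

independent of λ₁, λ₂, β and p. As `I → ∞` the system contracts to the
avascular floor `(V*, V*)` — therapy can shut the vasculature down to, but
never below, the avascular state.

The drug enters through a two-compartment pharmacokinetic model with
zero-order (constant-rate) intravenous infusions: central-compartment
concentration is a bi-exponential in the hybrid rate constants `(a, b)`
(`a·b = k₂₁·k_e`, `a + b = k₁₂ + k₂₁ + k_e`), multi-dose regimens superpose
linearly, and mg/ml converts to the growth model's mg/kg units through the
plasma density (1.025·10⁻³ kg/ml).

Reference parameterisation (mouse, bevacizumab): λ₁ = 0.192 day⁻¹, λ₂ = 0,
c = 5.85, d = 0.00873, α = 1, β = 1, p = 0; PK: V_c = 7.975 ml,
k₁₂ = 0.7536, k₂₁ = 0.3144, k_e = 0.3888 day⁻¹. These are the library
defaults (`GrowthParams()`, `PkParams()`).

## Worked example

```python
from angiosim import (GrowthParams, PkParams, TumourState, simulate,
                      detect_plateau, make_regimen, growth_inhibition,
                      growth_delay, steady_state_volume)

params = GrowthParams()          # reference mouse parameter set
init = TumourState(V=200.0, K=625.0)

free = simulate(params, init, (0.0, 300.0))
plateau = detect_plateau(free)
print(f"analytic plateau : {steady_state_volume(params):.1f} mm^3")
print(f"detected plateau : {plateau.plateau_value:.0f} mm^3 at day {plateau.t_plateau:.1f}")

regimen = make_regimen(5.0)      # 9 x 5 mg/kg, days 1..29, 30-min infusions
treated = simulate(params, init, (0.0, 300.0), regimen=regimen, pk=PkParams())
tgi = growth_inhibition(treated, free, t_eval=32.0)
delay = growth_delay(treated, free, ref_volume=16000.0)
print(f"inhibition day 32: {tgi:.1f} %")
print(f"growth delay     : {delay:.1f} days at 16000 mm^3")
```

Output:

```
analytic plateau : 17347.0 mm^3
detected plateau : 17347 mm^3 at day 95.3
inhibition day 32: 91.9 %
growth delay     : 57.3 days at 16000 mm^3
```

Calibration runs in two stages: `fit_control` estimates (λ₁, c, d, K₀) from an
untreated arm by bounded trust-region least squares; `fit_treatment` then
estimates (λ₁, c, β, p, K₀) from a treated arm with `d` frozen at the control
value and λ₁ capped by the control estimate (therapy may only be
growth-suppressing). `generate_series` produces xenograft-like synthetic
arms (cohort mean ± SD under multiplicative lognormal measurement noise) to
exercise the whole pipeline without external data.

## Command line

```bash
angiosim simulate --params params.csv --t1 300 --out traj.csv
angiosim analyze  --out oat.csv --surface-out surface.csv
angiosim generate --spec spec.json --out-dir data/
angiosim fit      --control data/control.csv --estimates-out est.csv
```

`angiosim <cmd> --help` documents each file format.

## Layout

- `src/angiosim/model_core.py` — growth ODE right-hand sides, steady state, geometry, parameter I/O
- `src/angiosim/pharmacokinetics.py` — two-compartment infusion PK, hybrid constants, regimens
- `src/angiosim/simulation.py` — piecewise adaptive integration, plateau detection, treatment endpoints
- `src/angiosim/parameter_analysis.py` — one-at-a-time perturbation study, plateau surface, parameter bounds
- `src/angiosim/fitting.py` — two-stage least-squares calibration
- `src/angiosim/synthetic_data.py` — synthetic xenograft-like observation series
- `src/angiosim/cli.py` — `angiosim` command-line entry point
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
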