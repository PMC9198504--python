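# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

Batch growth of a planktonic microalga in a flask illuminated from below
through a regulated aperture. Biomass `N(t)` (cells) follows a logistic
equation; the maximum specific growth rate is the product of two Monod
factors, one in the light flux absorbed per cell `L` and one in the
relative medium concentration `C`:

```
dN/dt = μ · C/(ξ_C + C) · L/(λ_L + L) · (1 − N/Γ) · N,
dC/dt = −α · dN/dt,
L(N, E_in) = (1 − 10^(−K·(N/V)·D)) · E_in / N.
```

Assumptions inherited from this structure:

* light is absorbed according to the base-10 Lambert–Beer law over the
  fixed culture depth `D`, and the absorbed flux is shared equally by
  all cells (well-mixed culture);
* a single rate-limiting nutrient species represents the medium, and it
  is consumed strictly in proportion to biomass increase, giving the
  exact conservation law `C(t) + αN(t) = C0 + αN0`;
* the light response is an increasing, saturating function only — no
  photoinhibition at high flux and no minimum-light threshold
  (sigmoidal onset). The model is therefore only meant for the mild
  light fluxes at which cultivation is actually run;
* temperature, CO₂, pH and toxic by-products are not modelled
  explicitly; their bulk self-limiting effect is absorbed by the
  carrying capacity `Γ`.

The **MR (medium-rich) model** is the special case `r_medium ≡ 1`, valid
while nutrients are in excess. Its stationary state is `Γ`; the full
model's stationary biomass is the light-independent closed form
`N_max = min(C0/α + N0, Γ)`, which the planner inverts.

## Units

The interface carries light fluxes in μE s⁻¹, the unit a light meter
reports, while all rate equations run in hour-consistent units
(`E_in × 3600`, `L` and `λ_L` in μE h⁻¹ cell⁻¹) so that fluxes compose
with `μ` in h⁻¹. This is the only reading under which the default
parameter set produces stationary phase on the few-hundred-hour
timescale of real flask experiments: interpreting `λ_L = 1.9 × 10⁻⁶` in
per-second flux units would put the half-velocity constant three orders
of magnitude above the largest attainable `L` and predict essentially no
growth over a thousand hours. The conversion happens once, at
`CultureCondition.e_in_hour`; no quantity in per-second units ever
enters a rate formula.

Biomass↔OD conversion uses 3.01 × 10⁷ cell ml⁻¹ per OD730 unit, fixed by
the calibration pair 99.9 × 10⁹ cells in 200 ml ↔ OD 16.6. The dry-mass
density 0.213 mg ml⁻¹ per OD is carried as metadata only.

## Default parameters

| parameter | value | unit | meaning |
|---|---|---|---|
| `mu` | 0.194 | h⁻¹ | maximum specific growth rate |
| `lambda_l` | 1.90e-6 | μE h⁻¹ cell⁻¹ | light half-velocity constant |
| `gamma_cap` | 99.9e9 | cell | carrying capacity |
| `xi_c` | 0.012 | — | medium half-velocity constant |
| `alpha` | 8.7e-12 | cell⁻¹ | medium consumed per cell grown |
| `k_ext` | 5.1e-9 | ml cm⁻¹ cell⁻¹ | extinction coefficient |
| `V`, `D` | 200, 3.7 | ml, cm | flask volume and light path |
| aperture | 2.826e-3 | m² | illuminated area |
| `OD0` | 0.025 | — | inoculation density |

These are the assessed values for the *Monoraphidium* sp. strain the
model was developed on and serve as the ground truth of the synthetic
data generator.

## Numerical choices

* **Integration.** Only `N` is integrated (LSODA, rtol 1e-8, atol 1
  cell); `C` follows algebraically from the conservation law. One state
  instead of a redundantly coupled pair, and the conservation law then
  holds to round-off by construction. The absolute tolerance of one
  cell is meaningful because trajectories span ~9 decades of `N`; tests
  that shrink the population to toy sizes (e.g. the logistic closed-form
  oracle at `Γ = 100`) pass a proportionally smaller `atol`.
* **Stationary horizon.** "Long enough" is defined as 5× the first time
  the specific growth rate falls below `1e-6·μ`, located by event
  detection inside a doubling search window — no closed-form transition
  time exists. At that horizon the terminal biomass agrees with the
  analytic `N_max` to better than 0.1% in every default condition.
* **Crossing times.** Harvest times `T1`, `T2` come from the
  integrator's event root-finding, not from any output grid, so they
  are resolved below 0.1 h.
* **Rate evaluation at depleted medium.** Solver round-off can push `C`
  a hair below zero; the Monod factor clamps values within 1e-9 at zero
  (the model's own boundary, `r_medium(0) = 0`) and treats anything more
  negative as a genuine domain error.
* **Fitting.** Both estimation steps are bounded nonlinear least squares
  (`scipy.optimize.least_squares`, trf) over log10-transformed
  parameters, because the parameters span many decades. Residuals are
  unweighted OD differences — OD is the measured quantity — pooled over
  raw observations. Multi-start: one data-driven heuristic start
  (steepest log-OD slope for `μ`, the dilute-culture light flux per
  cell for `λ_L`, 1.5× the largest observed biomass for `Γ`; the
  most-dilute plateau for `α`) plus 8 Latin-hypercube points seeded from
  the run seed; a start that drives the RMS residual below 1e-7 OD ends
  the scan early, since that is the integration-noise floor. Bounds:
  `μ ∈ [1e-3, 1]`, `λ_L ∈ [1e-9, 1e-2]`, `ξ_C ∈ [1e-5, 10]`,
  `α ∈ [1e-15, 1e-9]`, `Γ` between **half** the largest observed biomass
  and 1e13. The half matters: with multiplicative noise the largest
  observed plateau OD overshoots the true capacity by a few percent, and
  a lower bound at the raw maximum would pin `Γ` above the truth and
  drag `μ` and `λ_L` with it.
* **Fitting windows.** Step 1 truncates the two brightest
  undiluted-medium series at 306 h and 690 h; those cultures approach
  stationary phase early, where the medium-rich assumption fails.
  Windows are per-series configuration, matched on the incident flux;
  there is no automatic stationary-phase detection.
* **Identifiability diagnostics.** A parameter whose log-space Jacobian
  column at the optimum is two orders of magnitude below the largest
  column is reported as unidentifiable (a light-saturated curve carries
  no information about `λ_L`; consumption-free data none about `α`).

## Two-step estimation and what it can and cannot recover

Step 1 fits `(μ, λ_L, Γ)` of the MR model to the undiluted-medium panel;
step 2 holds them (and `K`) fixed and fits `(ξ_C, α)` of the full model
to all conditions. The split mirrors the experimental design and avoids
a five-parameter joint fit overreacting to a single dataset.

A structural caveat the test suite makes visible: even noise-free
synthetic data generated by the *full* model are not exactly MR, because
`C` declines a few percent before the plateau (with `C0 = 1` the Monod
medium factor falls from 0.988 to ≈ 0.92 near `Γ`). Step 1 therefore
recovers `μ` to a few tenths of a percent, not to machine precision —
tests that demand exact recovery use MR-generated panels, which is the
estimator's own oracle. The small step-1 bias is absorbed almost
entirely by `ξ_C` in step 2 (it is the softest direction of the
objective), while `α` — pinned by the plateau heights across the
dilution series — is insensitive to it. Accuracy claims for `ξ_C` are
therefore only made with the first-stage parameters fixed at their
generating values, the setting the second step is defined for.

## Synthetic data

The generator emulates the reference calibration experiment: the 4 × 4
matrix of incident fluxes (2.92, 1.09, 0.521, 0.274 μE s⁻¹) ×
initial medium concentrations (1, 0.5, 0.25, 0.125), inoculated at
OD 0.025 in the default geometry, sampled every 24 h. Each condition
runs 1.5× past the time it reaches 99% of its stationary biomass so
every curve shows a plateau. The default noise model is multiplicative
lognormal (turbidity error scales with signal; σ configurable), applied
to every reading except the t = 0 inoculum, which the experimenter sets.
The attenuation generator covers a 4-depth × 5-concentration grid
(depths up to the flask's 3.7 cm light path, densities spanning
OD ≈ 0.5–8) with exact Lambert–Beer decay plus optional log-scale noise.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: plate-reader nonlinearity at
high OD, evaporation and volume loss over multi-week runs, subculture
carry-over effects, photoinhibition, and day/night or lamp-aging
variation in `E_in`. Parameter-recovery results certify the estimation
machinery, not the biological adequacy of the model.

## Planner semantics

`required_c0` inverts the medium-limited branch of `N_max`; targets
above `Γ` are infeasible (the OD ceiling of the default parameter set is
≈ 16.6 in the 200 ml flask). Because cultures are harvested before
stationary phase, `plan()` doses the medium so the target biomass sits
at a configurable fraction (default 0.8, the midpoint of the default
70–90% harvest band) of the planned stationary biomass. Among light-flux
candidates whose harvest window contains the target time the planner
prefers the dimmest (lowest energy cost); if none contains it, the
result is flagged infeasible and the nearest windows are reported so the
operator can renegotiate the target time.

## Problem sizes

The default test suite and the acceptance script run entirely on
synthetic data at the scale of the reference experiment (16 conditions,
24 h sampling; noisy recovery checks use five seeds at σ = 1%). The
cross-validation noise-sensitivity check uses 72 h sampling and two
optimizer starts per fold — it asserts a monotone trend, not a recovery
tolerance, and the coarser setting keeps the whole suite under a couple
of minutes on one CPU.

## Known limitations

* `λ_L` and `μ` are strongly correlated when no series gets close to
  light saturation; the diagnostics flag only the extreme case.
* The planner scans a discrete candidate list for `E_in` rather than
  optimizing continuously, matching how lamp settings are actually
  stepped; a target time falling between two candidates' windows is
  reported infeasible with both neighbours rather than interpolated.
* Uncertainty quantification is limited to OLS diagnostics for the
  extinction regression; the growth-model fits report point estimates,
  residual norms and identifiability flags, not confidence regions.
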