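# Methods

## Scope and structure

`cscrit` couples three layers that operate on different time scales and are
deliberately kept separable:

1. **Radionuclide kinetics and LQ radiobiology** (days): dose-rate curve,
   protraction factor, BED/OER/SF/TCP (`radionuclides.py`,
   `radiobiology.py`).
2. **Delayed cell-population dynamics** (years): the four-species model
   with the therapy coupling R_imm (`dynamics.py`).
3. **Oxygen reaction–diffusion** (seconds): the hypoxia field whose
   pressure histogram can be fed back into the surviving-fraction average
   (`oxygen.py`).

`sensitivity.py` wraps any scalar output of layers 2–3 in a one-at-a-time
elasticity analysis; `reporting.py` provides declarative scenarios and the
`reproduce` reference report; `units.py` is the single day/year conversion
layer (365 days/year by default, configurable) — the model runs in years
while all dosimetry runs in days, and no other module converts units.

## Radiobiology layer

The dose rate in tumor after administration is
`r(t) = r₀(2^(−t/T_e) − 2^(−t/T_eu))` with effective half-times formed
harmonically from the physical half-life and the biological uptake or
clearance half-time. Registry defaults (days):

| radionuclide | T_p | T_b | T_u |
|---|---|---|---|
| ⁹⁰Y | 64.1/24 | 8.00 | 3.00 |
| ¹³¹I | 8.0 | 2.50 | 1.20 |
| ¹⁷⁷Lu | 6.7 | 3.50 | 1.15 |
| ²²⁵Ac | 10.0 | 9.50 | 3.20 |

The nominal 8 d and 10 d values (rather than the exact isotope half-lives
8.02 d and 9.92 d) are the defaults because the package's reference
scenarios are parameterized with them; exact values can be supplied via a
custom registry entry. The 64.1 h half-life of ⁹⁰Y is converted at exactly
24 h/day.

The protraction factor Λ is evaluated by the three-term closed form in
T_μ, T_e, T_eu. It was verified against an independent quadrature of the
standard LQ dose-protraction double integral
`(2/(D(α_c/β_c))) ∫₀^∞ r(t) ∫₀^t r(t′) e^{−(ln2/T_μ)(t−t′)} dt′ dt`:
agreement is at machine precision for all four registry radionuclides
(test suite asserts ≤ 1e−5 relative). The closed form has poles at
T_μ = T_e and T_μ = T_eu; evaluation within 1e−9 days of a pole raises.

**RE convention.** Two conventions for the relative effectiveness
circulate: a dimensionally bare `RE = 1 + r₀Λ/ln2` and the standard LQ
form dividing the protraction term by `(α_c/β_c)·OER`. Only the latter has
consistent units (r₀Λ is a dose, normalized by the α/β dose), so it is the
canonical behavior here; the bare variant is available through
`re_convention="plain"` for comparison.

**Repopulation.** The BED subtraction `ln2(T−T_k)/(α_c T_d)` is applied
only when a `RepopulationParams` is passed with `T > T_k`. No defaults are
provided for T, T_k, T_d — repopulation is off unless explicitly
configured.

**Oxygen averaging.** `surviving_fraction_integrated` consumes any
discrete probability density over pressures (weights summing to 1 within
1e−6): a point mass, a quadrature rule, or the empirical histogram
exported by the oxygen field. The capillary-density argument of such
densities is carried as a label only; no formula in the package uses it
quantitatively.

**TCP saturation.** "TCP reaches 1" is operationalized as the smallest
grid r₀ with TCP ≥ 1 − 1e−3 (`tcp_saturation_dose`, threshold
configurable), since saturation is asymptotic.

## Dynamics layer

The four equations are implemented exactly as stated, including the
asymmetry that the dedifferentiation source in dS/dt uses the delayed pair
`q(m(t−τ))·D(t−τ)` while dD/dt uses the instantaneous `q(m)`. The a = 0
plane is exactly invariant in floating point (da/dt carries the factor a).

**Integrator.** Fixed-step classical RK4 with the method of steps: each
step stores state and right-hand side, and delayed values are read from
the cubic-Hermite interpolant of the stored nodes (or from the history
function for lookups before t₀). Default Δt = 0.01 year; halving the step
changes reference endpoints by < 1e−6 relative, and the closed-form
subcases (pure exponential decays) converge at the expected fourth order.
A warning is issued when Δt > τ/2. The therapy coupling switches on at the
first step boundary at or after `t_start` and is constant within a step.
τ = 0 degrades to a plain RK4 ODE solve. An alternative `time_resolved`
mode replaces the constant R_imm by `α_c · r(t−t_start) · RE`; it is not
the canonical behavior because the model as formulated couples therapy
through a single dimensionless constant.

**Default parameters** (years): η=1, ψ=0.5, ε=1, m₀=0.05, σ=0.05, υ=25,
θ=50, α=0.3, β=1, γ=1, S₀=0.038. The DC death rate is only constrained to
36.5–109.5 /y in the literature and the dedifferentiation ceiling only to
q₀ > d; the defaults d = 36.5, q₀ = 40 sit at the low end of that range
(slow DC turnover, moderate plasticity) and are ordinary config fields.

**Initial conditions.** The reference scenarios start from
`(S, D, a, m)(0) = (S₀, S₀/d, 0.01, 0.01)` with constant history on
[−τ, 0]: a pre-recurrence tumor near the Wnt-inactive branch whose
microRNA level is still below the activation threshold m₀. The
sub-threshold m(0) matters: because delayed terms replay the trajectory's
own first months once t > τ, the early ramp of q(m)·D — microRNA crossing
m₀ about 40 days in — is what produces the transient repopulation phase
observed right after therapy start, before the kill terms win. Starting
instead from the fully activated microRNA level (m(0) = γ/α·e^(−1) ≈ 1.23)
gives a constant delayed source and a monotone post-therapy decline with
no transient. Initial conditions are ordinary config fields
(`Scenario.initial_state`), and absolute trajectory values should be read
as scenario-specific; the robust outputs are orderings and relative
changes across radionuclides.

**Equilibria.** The therapy-free system has three closed-form equilibrium
families. E1 = (0,0,0,m₁) is exact in S, D, a for any m₁ (m itself relaxes
toward γ/α). E2 = (S₂, S₂/d, 0, m₂) with S₂ = −S₀ln(αm₂/γ) is an exact
equilibrium only where dedifferentiation balances DC turnover; the default
m₂ therefore solves q(m₂) = d (requires d < q₀ and ε = 1), and any other
m₂ is accepted with its residual annotated. E3 uses the closed-form root
a₃ of the symmetric-division balance 2p(D₃(a), a) = 1 (verified against a
1-D root finder); its printed closed forms neglect the dedifferentiation
inflow q(m₃)D₃, so `equilibria` reports both the defining-condition
residual (< 1e−8 at defaults) and the full right-hand-side residual, where
that inflow appears explicitly. When ψα/(dβ) ≥ 1 the a₃ branch changes
character and the point is flagged invalid.

## Oxygen layer

Explicit RK4 (forward Euler selectable) on the 5-point Laplacian, 101×101
nodes (Δx = 0.2 mm on a 20 mm domain), Δt = 0.01 s; the stability number
D_O2·Δt/Δx² = 5e−4 is far below the 0.25 bound, which the constructor
enforces. The Dirichlet ring at P_c = 40 mmHg is re-imposed after every
stage. With zero cell density the uniform 40 mmHg state is preserved to
machine precision; with density 1 cell/mm³ the center node tracks the
diffusion-free implicit solution `k ln P + P = k ln P₀ + P₀ − C_max t`
to < 0.5 % at t = 2 s (the boundary layer needs √(D_O2·t) ≈ 0.06 mm to
move, far less than the 10 mm to the center).

**Initial condition.** The structured perturbation
`40 + 0.1cos((x²+y²−55)π) − 0.01sin((x²+y²+91)π)` is read additively (the
`nested` reading, with the sine inside the cosine argument, is available
by flag; the two differ by ≤ 0.11 mmHg). Coordinates are centered on the
domain so x²+y² produces the circular depletion patterns.

**Density coupling.** The canonical runs use a scalar cell density
(0.001 cell/mm³ for field evolution, 1 cell/mm³ for the sensitivity and
oracle scenarios), uncoupled from the dynamics layer; a per-node density
array is accepted for future coupling. The interior mean excludes the
Dirichlet ring by default (flag to include it, since the choice affects
sensitivity magnitudes).

## Sensitivity analysis

Forward one-sided perturbation of +0.1 % per parameter (δ = 1e−3),
normalized as an elasticity; central differences selectable. Zero-valued
nominals are skipped (a relative perturbation of zero is still zero) and
non-finite perturbed outputs are flagged out of the ranking, which orders
by |index| with an alphabetical tie-break. On power laws Y = pⁿ the
forward scheme recovers n with error ≈ n(n−1)δ/2, which the tests assert.

The dynamics scenario's output is the final CSC concentration S(16 y) with
therapy from t = τ = 8.8964 y at r₀ = 50 Gy/year (²²⁵Ac by default — the
choice of radionuclide for this analysis is a convention, and the asserted
sign pattern T_e −, T_eu +, q₀ +, r₀ −, υ − holds across the registry).
Pharmacokinetic parameters receive a dual treatment so that roots and
derived times each get their own row: T_p, T_b, T_u are perturbed and
propagated through T_e, T_eu, while a directly perturbed T_e or T_eu
bypasses the propagation. The two layers double-count the same physics by
construction; the report is to be read per-row, not as a decomposition.
The oxygen scenario's output is the interior mean pressure at t = 2 s
(center-node and boundary-inclusive variants by flag); only signs and
ranks of its indices are asserted, as the magnitudes depend on the output
definition.

## Reference report and its limits

`reproduce_reference_tables` tags each recomputed quantity pass/fail:
peak dose rates at r₀ = 2 Gy/day (0.5 % relative), percent reductions
between the two tabulated therapy time points (exact to 2 decimals —
these are internal arithmetic on the reference concentration tables),
BED/SF/TCP ordering checks, and oxygen-sensitivity signs/ranks. Reference
quantities whose inputs are not pinned down by the package's scenarios —
TCP saturation doses, absolute SF values at r₀ given in Gy/year, absolute
concentration tables, eradication durations — are emitted as informational
rows only and never graded.

## Known limitations

- The oxygen field ignores vascular geometry, perfusion heterogeneity and
  acidity; capillary supply is a uniform Dirichlet boundary.
- The dynamics layer is space-free; only oxygen diffuses.
- R_imm is time-constant once switched on (the time-resolved mode exists
  but is non-canonical), and ²²⁵Ac is treated as a single effective
  emitter — no daughter-chain dosimetry or LET microdosimetry.
- Absolute trajectory concentrations depend on initial conditions that are
  scenario choices; cross-radionuclide orderings and relative reductions
  are the supported outputs.
- The OAT sensitivity is local: no parameter interactions, and indices
  hold only near the nominal point.
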