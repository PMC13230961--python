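# cscrit

Simulation toolkit for **radioimmunotherapy (RIT) of cancer-stem-cell-driven
tumors**: a delayed four-population model of tumor dynamics coupled to the
linear-quadratic (LQ) radiobiology of protracted irradiation, a 2-D oxygen
reaction–diffusion field for hypoxia effects, and a local one-at-a-time
sensitivity analysis. It is aimed at modelers in radiobiology and
mathematical oncology who want to compare radiolabeled-antibody therapies
(⁹⁰Y, ¹³¹I, ¹⁷⁷Lu, ²²⁵Ac) by biologically effective dose (BED), surviving
fraction (SF), tumor control probability (TCP) and their effect on
cancer-stem-cell kinetics.

## The model

**Tumor dynamics** (time in years). Cancer stem cells *S*, differentiated
cancer cells *D*, Wnt-β-catenin proteins *a*, and microRNAs *m* evolve as

```
dS/dt = (2 p(D,a) − 1) ε S + q(m(t−τ)) D(t−τ) − υ R_imm S
dD/dt = 2 (1 − p(D,a)) ε S − (d + q(m)) D − θ R_imm D
da/dt = a (β S a/(1+a) − α)
dm/dt = γ e^(−S/S₀) − α m
```

with symmetric-division probability `p(D,a) = ηa/((1+ηa)(1+ψD))` and
microRNA-activated dedifferentiation `q(m) = (q₀/2)(1 + tanh((m−m₀)/σ))`
acting after a conversion delay τ. The system is integrated by fixed-step
classical RK4 with cubic-Hermite dense output for the delayed terms.

**Radiobiology** (time in days). The tumor dose rate is the bi-exponential
`r(t) = r₀ (2^(−t/T_e) − 2^(−t/T_eu))` with effective half-times
`T_e = T_p T_b/(T_p+T_b)`, `T_eu = T_p T_u/(T_p+T_u)`; total dose
`D = r₀ τ_e / ln 2` with `τ_e = T_e − T_eu`. Protracted delivery competing
with sublethal-damage repair (half-time T_μ) gives

```
RE  = 1 + r₀ Λ / (ln2 · (α_c/β_c) · OER(P_o))
BED = (D / OER(P_o)) · RE        [− ln2 (T−T_k)/(α_c T_d) if T > T_k]
```

with the closed-form protraction factor Λ(T_μ, T_e, T_eu), the oxygen
enhancement ratio `OER(P_o) = OER_max (P_o + K_m)/(OER_max P_o + K_m)`,
surviving fraction `SF = exp(−α_c BED)` (optionally averaged over an oxygen
pressure density) and Poisson `TCP = exp(−N · SF)` for `N = ς·V` clonogens.
The scalar `R_imm = α_c · BED` couples therapy into the kill terms of the
dynamical model.

**Oxygenation.** `∂P_o/∂t = −C_max P_o/(k+P_o) · (S+D) + D_O2 ∇²P_o` on a
20 mm square domain with 40 mmHg Dirichlet capillary boundary; field
histograms feed the OER-averaged surviving fraction.

## Worked example

```python
from cscrit import (DoseSchedule, LQParams, ModelParams, TherapySchedule,
                    TumorBurden, bed, integrate_dde, peak_dose_rate,
                    surviving_fraction_point, tcp, total_dose)

sched = DoseSchedule.for_radionuclide("225Ac", 2.0)   # r0 = 2 Gy/day
lq = LQParams()                                        # α_c=0.46, β_c=0.30, T_μ=0.062 d
print(peak_dose_rate(sched))   # (4.8588, 0.5033)  -> peak 0.5033 Gy/day at 4.86 d
print(total_dose(sched))       # 7.0621 Gy total absorbed dose
print(bed(sched, lq))          # 7.3385 Gy  (RE = 1.0391)
print(surviving_fraction_point(sched, lq, 40.0))  # 0.0408 at 40 mmHg
print(tcp(sched, lq, TumorBurden(0.004576, 1e5), P_o=40.0))  # 7.8e-09

therapy = TherapySchedule.build("225Ac", 20.0, "Gy/year", t_start=8.8964)
traj = integrate_dde(ModelParams(), therapy, t_end=16.0, dt=0.01)
print(traj.at(9.796)["S"])     # 0.00753 cell/mm^3 CSC burden after therapy
```

The peak dose rate says ²²⁵Ac delivers its maximum of 0.5033 Gy/day about
4.9 days after administration — later and more sustained than the β
emitters — which is why it accumulates the largest BED and the lowest
surviving fraction of the four radionuclides at equal r₀. The trajectory
shows the therapy-phase transient: a brief repopulation rise after the
start at t = 8.8964 y, then a monotone decline of the stem-cell burden.

Command-line equivalents:

```
cscrit simulate --radionuclide 225Ac --r0 20 --r0-unit Gy/year --t-end 16
cscrit doseresponse --po 40
cscrit oxygen --density 0.001 --t-end 45
cscrit sensitivity --scenario oxygen
cscrit reproduce
```

`cscrit reproduce` recomputes the package's reference checks (peak dose
rates, therapy-phase percent reductions, BED/SF/TCP orderings, oxygen
sensitivity ranking) and exits nonzero if any fails.

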