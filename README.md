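# losartan-pkpd

Genotype-stratified pharmacokinetic/pharmacodynamic modelling of the
antihypertensive losartan and its active metabolite E-3174
(carboxylosartan), for pharmacogenomics researchers and modellers who want
to ask: *how do CYP2C9 and ABCB1 polymorphisms change drug exposure, and
does that change the expected AT1-receptor blockade?*

## The model

A single oral dose of losartan potassium (converted to nmol via MW
461.01 g/mol) moves through five compartments:

    stomach --v_sg(t)--> intestine <--k_ent_int-- enterocyte
                             |--k_int_ent-->  enterocyte --k_ent_cc--> central <--Q--> peripheral

* **Gastric emptying** is sinusoidal, `v_sg(t) = a (1 + sin 2πt/b) / 2`,
  modelling open/close cycles of the pyloric valve (amplitude `a` h⁻¹,
  period `b` h).
* **ABCB1 (P-glycoprotein)** efflux in the enterocyte pumps absorbed drug
  back into the intestinal lumen at rate `k_ent_int`; its fitted values are
  genotype-specific: 151.485 h⁻¹ (GG/CC), 101.800 h⁻¹ (GT/CT),
  1.431×10⁻¹² h⁻¹ (TT/TT).
* **CYP2C9** converts central-compartment losartan to E-3174 at a
  first-order rate `k_m` with a time delay `T`; `k_m` = 2.817 h⁻¹ for
  \*1/\*1 carriers and 0.039 h⁻¹ for \*3/\*3. The metabolite appears at the
  lagged rate `k_m · A_cc(t−T)` (a delay differential equation, integrated
  by the method of steps).
* Both analytes clear linearly (`CL_p`, `CL_m`); concentrations are
  algebraic assignments `C = amount / V`.

On top of the kinetics sit: the standard single-dose PK panel (C_max,
t_max, terminal t½ from a semilog line through 6/8/10 h, AUC₀₋∞ by
integrating dAUC/dt = C, CL/F = dose·10⁶/(AUC·461.01)); a Hill coupling
`k_block = E_max·AUCᵅ/(ED₅₀ᵅ + AUCᵅ)` that converts metabolite exposure
into the AT1-receptor blocking coefficient consumed by downstream
haemodynamic models (published coefficients E_max = 0.955,
ED₅₀ = 5304.326 nmol·h/L, α = 6.785); seeded global parameter estimation
with identifiability profiling and elasticity-type sensitivity
coefficients; and virtual populations (each parameter Normal with SD = 10%
of its median) with gated Kruskal–Wallis / Mann–Whitney / t-test group
comparisons at the Bonferroni 0.05/3 cutoff.

## Worked example

```python
from losartan_pkpd import (DoseRegimen, genotype_parameters, simulate,
                           pk_summary, REFERENCE_EMAX_COEFFICIENTS, emax_evaluate)

dose = DoseRegimen(dose_mg=50.0)
params = genotype_parameters("CYP2C9*1/CYP2C9*1", "GG/CC")
series = simulate(params, dose, t_end=48.0)
summary = pk_summary(series, dose)
print(round(summary.auc0inf_E3174, 1), round(summary.cl_over_f, 2))
print(round(emax_evaluate(REFERENCE_EMAX_COEFFICIENTS, summary.auc0inf_E3174), 3))
```

prints

```
7700.6 80.14
0.884
```

— after 50 mg, a wild-type CYP2C9 / high-efflux ABCB1 subject reaches a
metabolite exposure of ≈7.7×10³ nmol·h/L (apparent losartan clearance
≈80 L/h), which the Hill coupling maps to a blocking coefficient of ≈0.88:
well past the half-maximal exposure, approaching the E_max ceiling.

The `examples/` directory holds one short narrative script per capability
(genotype curve simulation, the PK panel, the k_block table, fitting with
identifiability, virtual-population statistics); each prints its numbers
with a line on what they mean.

A thin CLI wraps the same functions:

```bash
losartan-pkpd simulate --genotype TT/TT --dose 50 --out runs/ttt
losartan-pkpd pk runs/ttt/curve.csv --dose 50 --out runs/ttt
losartan-pkpd kblock --genotypes GG/CC,GT/CT,TT/TT --doses 50,100 --out runs
```

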