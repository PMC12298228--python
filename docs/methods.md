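# Methods

## Model structure and assumptions

The kinetic model tracks amounts (nmol) of losartan in five compartments —
stomach, intestinal lumen, enterocyte, central (plasma + well-perfused
tissue) and peripheral — plus the active metabolite E-3174 in the central
compartment. Every transfer is first-order, so the whole system is linear
in dose; plasma concentrations are algebraic assignments
`C_p = A_cc/Vp_1`, `C_m = A_m/Vm` (nM).

Assumptions worth stating explicitly:

* **Single oral dose.** No accumulation, no enterohepatic recycling, no
  multiple-dose regimens.
* **Gastric emptying** is a sinusoid `a (1 + sin 2πt/b)/2` — nonnegative,
  `b`-periodic, mean `a/2`. The functional form is pluggable
  (`valve_fn` argument) so an alternative periodic form can be substituted
  without touching the integrator.
* **ABCB1 efflux** acts only in the enterocyte, returning drug to the
  lumen. The intestine/enterocyte loop is loss-free by default, which has
  a sharp consequence: total AUC₀₋∞ of losartan is independent of the
  efflux rate — efflux reshapes the curve (lower, later peak) without
  changing total exposure. An optional first-order intestinal loss
  `k_int_ex` (default 0) is provided for topologies where genotype should
  also shift total exposure.
* **CYP2C9 conversion** occurs in the central compartment only, at rate
  `k_m` with lag `T`. Heterozygous CYP2C9 genotypes and unfitted ABCB1
  diplotypes are rejected outright rather than interpolated: the rate
  constants were estimated for homozygotes only and no interpolation rule
  is defensible from those data.

### The conversion lag

The delayed conversion admits two readings, selected by `delay_mode`:

* `"metabolite"` (default): losartan is removed at the instantaneous rate
  `k_m·A_cc(t)`, E-3174 appears at the lagged rate `k_m·A_cc(t−T)`. Drug
  "in transit" through the conversion pathway reappears after the lag;
  cumulative mass balances and all states stay nonnegative.
* `"symmetric"`: both the loss and the gain use the lagged rate. This
  conserves mass instant-by-instant, but it is not positivity-preserving:
  whenever the plasma curve falls faster than the lag, the loss keeps
  withdrawing drug based on a larger past amount and the central
  compartment goes genuinely negative (observed at the GT/CT efflux
  constant with the default parameters). The integrator raises rather than
  silently clamping. The symmetric form is retained because it is the
  natural reading of "first-order delayed conversion", but it is not the
  default for exactly this reason.

In both modes the E-3174 curve is identically zero for `t < T`.

## Numerical integration

Constant-lag systems are integrated by the **method of steps**: the time
axis is cut into segments of length `T`, each integrated with
`scipy.integrate.solve_ivp` (LSODA, rtol 1e-8 / atol 1e-10 by default,
dense output), the lagged term evaluated on the dense interpolant of the
previously completed segment. This is exact for constant delays up to
solver tolerance. Lags below 1e-6 h are treated as zero (plain ODE); a cap
of 20 000 segments guards against pathological `t_end/T` ratios. The test
suite checks the integrator against an independent fixed-step RK4 with an
explicit history buffer (agreement to rtol 1e-5) and against the
closed-form Bateman cascade for the reduced chain topology (rtol 1e-6).

Running AUC integrals (`dAUC/dt = C`) are carried as two extra states, so
AUC₀₋∞ comes from the solver rather than post-hoc quadrature; a trapezoid
route exists for curves loaded from file and agrees to rtol 1e-4 on a
1 ms grid. "Infinity" is a finite horizon, default 48 h (≈10 terminal
half-lives of the metabolite under the default parameters; the integral
changes by <0.1% from 48 h to 96 h).

Output states are clamped to zero only for negative dust below
100·atol·dose; anything larger aborts with a diagnostic.

Default output grid: 0.01 h, fine enough that t_max discretization error
(±grid step) is below reporting precision. Ties in the maximum resolve to
the earliest grid time.

## PK metrics

* Terminal half-life uses a semilog OLS line through exactly the 6, 8 and
  10 h points (cubic interpolation onto those anchors when absent from the
  grid); `t½ = ln 2 / (−slope)`. Curves flat or nonpositive at the anchors
  raise ("no terminal decline").
* CL/F applies the piecewise zero branch while plasma losartan is
  identically zero, then `dose·10⁶/(AUC·461.01)`.
* The curve-distance statistic is the Euclidean distance over time points
  common to both series (matched to 1e-9 h).

## Exposure–effect coupling

`k_block = E_max·AUCᵅ/(ED₅₀ᵅ + AUCᵅ)` with AUC the metabolite exposure.
Fitting uses unweighted least squares on k_block — the natural choice when
the anchors are point values without stated uncertainties — with ED₅₀ and
α searched in log space from ≥24 deterministic grid starts (plus seeded
jitter) because three-parameter Hill fits with free steepness have strong
local minima. The shipped reference coefficients (E_max 0.955, ED₅₀
5304.326 nmol·h/L, α 6.785) reproduce the three published anchor blocking
levels (0.1 at the placebo-equivalent 25 mg exposure, 0.886 at 50 mg,
0.954 at 100 mg); refitting the anchors recovers them within 2%. Dose→
exposure for the k_block table uses full simulation by default, with a
documented `linear_dose_scaling` shortcut that is exact for this
all-first-order model.

## Parameter estimation, identifiability, sensitivity

The loss is an ordinary least-squares sum over both analytes at the
observation times, equally weighted (relative and log weightings are
available); the authors of the source data did not publish a loss, so OLS
is the package's own choice. The optimizer is seeded
`scipy.optimize.differential_evolution` over box bounds with local polish;
positive-bounded parameters are searched on a log10 scale. Any seeded
global optimizer would do — the contract is the recovery behaviour, not
the algorithm. Two-stage genotype fitting (conversion rates first, efflux
rates with refined globals second) is supported via per-dataset "local"
parameters.

Identifiability profiles fix one parameter on a scan grid bracketing the
optimum and re-optimize the rest (L-BFGS-B from the fitted point);
"significant increase" defaults to 5% above the fitted loss plus an
absolute floor the caller sets to the noise scale. Rising on both sides ⇒
identifiable, one ⇒ partially identifiable, neither ⇒ unidentifiable.

Sensitivities are forward-difference elasticities
`SS = ΔC/Δα · α/C`. The default is an absolute perturbation Δα = 1e-6; for
parameters of magnitude ≫1 (the efflux constants reach 150 h⁻¹) that step
changes the output by less than integrator tolerance, so a
relative-perturbation mode (step = δ·α, flagged in the result) is provided
and is what the sign-structure tests use, with tightened solver
tolerances (rtol 1e-9).

## Virtual populations and statistics

Each model parameter is drawn independently `Normal(median, 0.10·median)`,
truncated to >0 **by resampling** (clipping would pile mass at zero and
distort the shape). Genotype groups draw independently by default; a
"matched" mode shares global-parameter draws across genotypes for
variance-reduction studies. Zero-median parameters stay exactly zero.

Group comparison mirrors standard gated practice: Shapiro–Wilk per group
and Levene across groups at p < 0.05 choose parametric (ANOVA + t-test) vs
nonparametric (Kruskal–Wallis + Mann–Whitney, asymptotic with continuity
correction) tests; pairwise significance uses the Bonferroni cutoff
0.05/number-of-groups. Under the null the pairwise rejection rate at the
0.0167 cutoff is level-controlled (verified over 1000 simulated datasets).

## Synthetic data

The generator emulates the structure of genotype-stratified single-dose
studies: sparse sampling (default 0.25–24 h, 12 points, including the
6/8/10 h half-life anchors), two analytes, per-subject multiplicative
lognormal noise with constant CV (default 10%; σ² = ln(1+CV²), μ = −σ²/2
so the noise is mean-unbiased), aggregated to mean ± SD curves. What it
does **not** emulate: assay quantification limits and censoring,
between-subject kinetic heterogeneity inside a genotype group (noise is
residual-only unless combined with the population module), ethnic or
covariate structure, and digitization error of figure-derived data.
Passing recovery tests therefore demonstrate estimator correctness under
the stated error model, not robustness to everything real data do.

## Default parameter values

The genotype-specific constants (`k_m`, `k_ent_int`) are the published
fitted values. The remaining eleven constants were **not** published in
machine-readable form; the shipped defaults
(`data/default_parameters_synthetic.json`) are a synthetic stand-in
calibrated analytically from steady-state exposure identities of the
topology —

    AUC_losartan = dose / (CL_p + k_m·Vp_1)
    AUC_E-3174  = k_m·Vp_1·AUC_losartan / CL_m

— so that 50 mg exposures land at the reported magnitudes for wild-type
CYP2C9 (AUC_losartan ≈ 1.35×10³, AUC_E-3174 ≈ 7.7×10³ nmol·h/L, CL/F ≈
80 L/h), with transport and valve constants chosen to give
absorption-limited kinetics on the clinical timescale (losartan t_max
1–2 h under high efflux, sub-hour without). Quantitative agreement of
C_max / t½ with any specific clinical cohort is *not* claimed and not
tested; qualitative genotype orderings and all structural properties are.

## Problem sizes used in the test suite

Simulations in tests run at 12–48 h horizons with 0.01–0.25 h output
steps; the noisy recovery study uses 20 replicates of a 9-point, 12-subject
design fitting one parameter; population checks use 20–30 subjects per
genotype; the null-calibration study uses 1000 simulated three-group
datasets of 30 values each. These sizes make the full suite run in a few
minutes while leaving every check's Monte-Carlo error comfortably inside
its assertion margin.

## Known limitations

* Heterozygotes and rare diplotypes are unsupported by design.
* The loss-free absorption loop makes total exposure genotype-independent;
  if real data show genotype-dependent AUC₀₋∞, either `k_int_ex > 0` or a
  shorter AUC horizon must carry that difference.
* The blocking coefficient is emitted, not consumed: no blood-pressure or
  cardiorenal simulation is included.
* The default parameter set is a calibrated stand-in (see above), so
  absolute concentration predictions are illustrative.
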