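# Methods

## Models

### Consecutive cruciform cleavage

The cruciform assay is modelled as an irreversible two-step first-order
chain S → N → L (supercoiled → nicked → linear) with rate constants k₁ and
k₂, starting from pure supercoiled substrate (1, 0, 0).  The closed-form
fractions are

    fS(t) = e^(−k₁t)
    fN(t) = k₁/(k₂−k₁)·(e^(−k₁t) − e^(−k₂t))
    fL(t) = 1 − fS − fN

so conservation holds identically.  The model deliberately does not
distinguish *which* strand is cut first; k₁ and k₂ are the rates of the
first and second cut regardless of identity.  Assumptions: enzyme in
excess and binding fast relative to cleavage (pseudo-first-order), no
religation, and a nicked circle that remains a substrate only while held
in the complex.

When |k₂ − k₁| < 10⁻⁸·max(k₁, k₂) the fN expression is switched to its
analytic limit k₁·t·e^(−k₁t).  The threshold is far above the cancellation
scale of the difference of exponentials yet small enough that the limit
form differs from the exact one by ≪10⁻⁸, so the branch is numerically
continuous (verified by a dedicated test at k₂ = k₁(1+10⁻⁹)).

The nicked intermediate peaks at t\* = ln(k₂/k₁)/(k₂−k₁) (1/k₁ in the
degenerate limit); `nicked_peak` exposes the time and height.

An independent numerical oracle (`ode_trajectory`, LSODA with
rtol = 10⁻¹⁰, atol = 10⁻¹²) integrates the underlying differential system
and is required by the tests to agree with the closed form to ≤10⁻⁶
absolute over rate pairs spanning four orders of magnitude.

### Single-turnover cleavage

F(t) = F_f·(1 − e^(−k_c t)), with F_f ∈ (0, 1] the endpoint amplitude
(an F_f < 1 absorbs an uncleavable or misfolded substrate fraction) and
k_c the observed single-turnover rate.  Under enzyme excess k_c reflects
events within the enzyme–substrate complex, not turnover.

### Equilibrium binding

Two isotherms for the bound junction fraction f_b(P_t) at fixed total
DNA D_t:

* **Two-state with ligand depletion** — the exact physical root of the
  mass-action quadratic.  The minus branch is taken (the plus branch
  exceeds 1), computed in the compensated form
  f_b = 2·P_t/(b + √(b² − 4·P_t·D_t)) with b = K_d+P_t+D_t, which avoids
  the catastrophic cancellation of (b − √·) when 4·P_t·D_t ≪ b²
  (titrations legitimately span pM–µM).  A property test checks that
  back-substitution into K_d = (P_t−bound)(D_t−bound)/bound reproduces
  K_d to ≤10⁻⁹ relative across realistic titration scales.
* **Hill** — f_b = P_tⁿ/(P_tⁿ + K_app), implemented exactly in this form.
  Because the denominator constant is not raised to n, K_app carries units
  of concentrationⁿ; the unit-safe summary is the half-saturation
  concentration K_app^(1/n), exposed as `hill_half_saturation` and on the
  results object.  Whether a published fit treated protein as monomer or
  dimer concentration is a convention of the titration, so containers
  carry an explicit `stoichiometry` flag that is reported unchanged —
  the package never doubles or halves concentrations silently.

### Dimer-stoichiometry mixing

With two variants A (native) and B (size-shifted fusion) and independent
assortment of subunits into the bound dimer, complex fractions are
binomial: (p², 2p(1−p), (1−p)²) with p = [A]/([A]+ρ[B]).  The single
parameter ρ captures non-equivalent incorporation (ρ < 1: the fusion
incorporates less readily, consistent with a bulky tag lowering
affinity); it acts at incorporation, not at DNA binding — the simplest
one-parameter deviation from equivalence.  The model ignores
subunit-exchange kinetics and gel mobility; its purpose is the
qualitative three-band signature and its trends, which is all the mixing
experiment supports quantitatively.

## Fitting

All fits are unweighted nonlinear least squares on fractions.  Cruciform
lanes are renormalized so S+N+L = 1 before fitting (lane-loading factors
cancel in the ratio); kinetic fractions outside [0, 1] due to noise are
*not* clipped before fitting, since clipping biases the estimator.  Bound
fractions are a ratio of two band intensities and are inherently in
[0, 1].

Parameters are estimated on the log scale (positivity by construction;
rates are scale parameters), with F_f additionally bounded above at 1.
Optimization is scipy trust-region-reflective least squares with tight
tolerances (10⁻¹⁴), started from deterministic, data-driven guesses:

* k_c — log-linear regression of −ln(1 − F/F_cap) on t;
* k₁ — log-slope of the supercoiled trace; k₂ — inversion of the
  nicked-peak time t\* = ln(k₂/k₁)/(k₂−k₁) at the observed argmax (Brent
  root bracketing), falling back to k₁;
* K_d — log-interpolated half-saturation concentration minus D_t/2.

Five restarts with a fixed multiplicative schedule (×/÷10, ×/÷√10 on
rate-like parameters) guard against local minima without introducing
randomness; the best RSS wins.  The cruciform fit is free of the A→B→C
label-swap ambiguity because the supercoiled trace decays as e^(−k₁t) and
pins k₁ structurally; a test confirms that starting from swapped rates
converges to the same (k₁, k₂).  Joint fitting over all three species is
the default; a sequential mode (k₁ from S alone, then k₂ from N with k₁
held) is available for comparison and matches the joint fit on clean
data.

Standard errors come from the Jacobian at the optimum (finite differences
in log space, delta method back to the natural scale, σ² = RSS/(n−p)).
Percentile confidence intervals come from a seeded residual-resampling
bootstrap (numpy PCG64; refits start from the point estimate; a >20%
refit-failure rate is recorded as a warning on the results object).

Degenerate inputs fail loudly and specifically: flat progress curves
raise a no-signal error, all-bound/all-free titrations an
unidentifiability error, optimizer failure a convergence error with
diagnostics — never a silent spurious estimate.

Model comparison reports ΔRSS and ΔAICc, with AICc = n·ln(RSS/n) + 2k +
2k(k+1)/(n−k−1), k = p+1 (the noise variance counts as a parameter).
AICc expresses parsimony-penalized relative support, not statistical
significance.  In the simulation study (200 seeded replicates, 11-point
titration, 3% noise), strongly cooperative data (n = 2) select the Hill
model in ≥95% of replicates while non-cooperative data select the
one-parameter two-state model in the majority.

## Synthetic data generator

The generator emulates reduced gel-densitometry tables, not gels: for
each experiment type it evaluates the exact model at the true parameters
and adds (i) Gaussian scatter on fractions, default sd 0.03 — typical
phosphorimager densitometry repeatability — and (ii) for cruciform lanes,
an optional log-normal lane-loading factor (log-sd 0.05) applied to all
three species before per-lane renormalization, mimicking pipetting and
loading variation that the real reduction cancels.  Band intensities are
truncated at zero.  It does *not* model Poisson counting statistics,
background subtraction, band overlap, partial cruciform extrusion, or
enzyme inactivation — so passing recovery tests demonstrate that the
pipeline is correct and well-conditioned at realistic noise, not that
every systematic error of real gels is harmless.

Default designs mirror the study conditions: 12 time points over 600 s
for single-turnover cleavage; 10 points over 120 min for the cruciform
course, spaced more densely early (0, 5, 10, 15, 20, 30, 45, 60, 90,
120 min) as is standard for first-order time courses and so that the
nicked transient (peak ≈ 13 min at the default rates) is sampled; an
11-point geometric protein series from 43 pM to 44 nM at 82 pM junction
for titrations.  Exact published sampling times are not available, so
these schedules are declared approximations.  All randomness flows
through `numpy.random.default_rng(seed)` and the generating truth plus
seed are embedded in the output containers and CSV headers, enabling
closed-loop tests.

## Numerical and design notes

* **Units.**  Rates and time grids carry explicit unit tags ("s", "min");
  conversion is always explicit (`convert_rate`).  Tables without a
  declared time unit are rejected — rates in this assay family are
  conventionally reported in s⁻¹ for strand cleavage and min⁻¹ for
  plasmid time courses, and silent inference would be dangerous.
* **Cruciform amplitude.**  The fit fixes the initial condition at
  (1, 0, 0); an uncleavable-fraction amplitude analogous to F_f is not
  fitted by default, keeping the model at two parameters unless data
  demand otherwise.
* **Recovery performance.**  Closed-loop tests require ≤0.1% relative
  recovery on noiseless data for all fitters.  At 3% densitometry noise
  (200 seeded replicates at the default designs) median relative errors
  are ≈2% for k₁, ≈3% for k_c, ≈4% for K_d and ≈10% for k₂ — k₂ is the
  least-determined parameter because it is constrained mainly by the
  low-amplitude nicked transient (peak fraction ≈0.07 at the default
  rates), and it dominates the error budget of the acceleration ratio.
* **Bootstrap coverage.**  On the 11-point titration design the 95%
  percentile intervals achieve ≈88–90% empirical coverage: with n = 11
  and clipped, mildly heteroscedastic noise the i.i.d.-residual
  assumption is imperfect and percentile intervals run slightly narrow,
  a known small-sample behaviour.  The Jacobian-based Wald intervals are
  close to nominal on the same design.  Intervals should be read as
  good, slightly anti-conservative summaries at these sample sizes.
* **Hill units.**  The Hill denominator is implemented exactly as
  conventionally printed (K_app, not K_appⁿ); no attempt is made to
  reinterpret it, and the half-saturation transform is provided instead.

## Limitations

No branch-migration, supercoiling-energetics or strand-identity
modelling; no linked monomer⇌dimer⇌junction equilibrium (the Hill fit is
phenomenological); no Bayesian posteriors or global multi-experiment
fits; no gel-image processing (the pipeline starts at intensity tables).
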