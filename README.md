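# junctionfit

Quantitative analysis of Holliday-junction resolvase gel assays.

Junction-resolving enzymes (resolvases, e.g. the GEN1 family) cut two
strands of a four-way DNA junction to produce duplex products.  Three
classic gel experiments characterize such an enzyme, and this package
implements the complete quantitative pipeline for all three, from
band-intensity tables to fitted rate and equilibrium constants with
uncertainties:

1. **Cruciform consecutive-cleavage kinetics.**  A cruciform extruded in a
   negatively supercoiled plasmid is cut once (supercoiled → nicked, rate
   k₁) and then again within the lifetime of the complex (nicked → linear,
   rate k₂):

       fS(t) = e^(−k₁t),
       fN(t) = k₁/(k₂−k₁) · (e^(−k₁t) − e^(−k₂t)),
       fL(t) = 1 − fS − fN.

   The ratio k₂/k₁ is the *second-strand acceleration* — the kinetic
   signature that guarantees bilateral cleavage (productive resolution)
   before the enzyme dissociates.

2. **Single-turnover strand cleavage.**  With enzyme in excess, the
   cleaved fraction follows F(t) = F_f·(1 − e^(−k_c t)).

3. **Equilibrium junction binding** (gel shift).  At junction
   concentrations comparable to K_d the exact ligand-depletion quadratic
   applies,

       f_b = [(K_d+P_t+D_t) − √((K_d+P_t+D_t)² − 4·P_t·D_t)] / (2·D_t),

   alongside the cooperative Hill form f_b = P_tⁿ/(P_tⁿ + K_app), with
   parsimony-penalized (AICc) model comparison between the two.

A binomial mixing model additionally predicts the three-band pattern
(native/native, native/fusion, fusion/fusion) seen when two protein size
variants bind as a dimer, and a seeded synthetic-densitometry generator
makes every stage testable closed-loop without gel data.

The API follows statsmodels conventions: build a model from a data
container, call `fit()`, get a results object with estimates, standard
errors, bootstrap intervals and a `summary()` table.

## Worked example

Simulate a noisy cruciform time course at known rates, refit it, and
bootstrap the uncertainties:

```python
import junctionfit as jf

traj = jf.simulate_cruciform_course(k1=0.019, k2=0.20, noise_sd=0.03, seed=7)
res = jf.fit_cruciform(traj)
res.bootstrap_ci(n_boot=500, seed=7)
print(res.summary())
print("acceleration: %.1f" % res.acceleration)
```

prints

```
CruciformResults: consecutive cruciform cleavage (S→N→L)
  method: joint least squares   nobs: 30
  RSS: 0.0136009   AICc: -224   converged: True
  parameter         estimate     std err          bootstrap 95% CI
  k1               0.0185821    0.000385   [0.0178408, 0.0193133]
  k2                0.216191      0.0266   [0.176166, 0.281874]
acceleration: 11.6
```

The joint fit over all thirty observations (supercoiled, nicked and linear
fractions at ten time points) recovers the generating rates — k₁ ≈ 0.019
min⁻¹ from the supercoiled decay, k₂ ≈ 0.20 min⁻¹ pinned by the small
transient nicked intermediate — within their bootstrap intervals; the
second strand is cut roughly eleven times faster than the first.

The same pattern works for the other experiments
(`jf.fit_exponential(curve)`, `jf.fit_binding(titration, model="hill")`),
and a `junctionfit` command-line tool wraps the pipeline
(`simulate`, `fit-cleavage`, `fit-cruciform`, `fit-binding`,
`predict-dimer`) around commented-CSV intensity tables and JSON reports.

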