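# ctrlenergy

Control-energy analysis of structural brain networks.

During adolescence the brain's white-matter network is remodeled, and a
central question in developmental network neuroscience is whether that
remodeling makes it energetically easier to activate the fronto-parietal
system that underpins executive function.  `ctrlenergy` implements the full
analysis used to ask that question: it treats each subject's structural
connectome as the coupling matrix of a linear dynamical system, computes the
optimal control energy of the transition from a resting baseline to a
fronto-parietal activation state, and then relates that energy to age and
cognition with null-network comparisons, penalized-spline regression,
multivariate brain-maturity prediction, and mediation analysis.  A seeded
synthetic-cohort generator with planted effects makes the entire pipeline
testable without any imaging data.

## The model

Brain activity `x(t)` (one value per region) evolves under noise-free linear
time-invariant dynamics constrained by the structural connectome `A`
(symmetric, nonnegative, scaled by `1 + ξ₀` with the identity subtracted so
that it is stable):

```
ẋ(t) = A x(t) + B u(t)
```

where `B` selects the control regions (identity: every region is controlled)
and `u(t)` is the control input.  The transition from `x(0) = x₀` (zeros) to
`x(T) = x_T` (ones on fronto-parietal regions) minimizes

```
∫₀ᵀ (x_T − x)ᵀ S (x_T − x) + ρ uᵀu dt,
```

with `S` a 0–1 diagonal matrix restricting the state penalty to the
fronto-parietal system and `ρ > 0` weighting the energy term.  The
Pontryagin minimum principle gives `u* = −(1/2ρ) Bᵀ p*`, with the costate
`p*` obtained by shooting through the matrix exponential of the 2N-dimensional
augmented state–costate system.  The energy of region *i* is
`E_i = ∫₀ᵀ u_i*(t)² dt`; the per-region pattern of `E_i` is the feature set
for all downstream statistics:

* **Null networks** — degree- and strength-preserving surrogates; paired
  *t*-test of null vs real whole-brain energy.
* **Developmental models** — `energy ~ s(age) + sex + handedness + motion +
  TBV + network strength` fitted with penalized cubic regression splines
  (REML, via mgcv), signed Z values, linear partial correlations with
  Fisher-z CIs, Benjamini–Hochberg FDR.
* **Brain maturity** — nested two-fold cross-validated ridge regression
  predicting age from the 64/232-region energy pattern, λ selected on an
  inner age-rank split from the 16-value grid `2⁻¹⁰ … 2⁵`, interpreted via
  the Haufe activation pattern `a = Σ_X w`.
* **Mediation** — single-mediator a/b/c/c′ scheme with case-resampling
  percentile bootstrap for the indirect effect `a·b`.

## Worked example

```python
import numpy as np
from ctrlenergy import (SyntheticCohortSpec, generate_cohort, cohort_energy,
                        fit_age_gam, NullEnsemble, real_vs_null_energy_test)

spec = SyntheticCohortSpec(n_subjects=120, n_nodes=64, seed=7)
cohort = generate_cohort(spec)
energy = cohort_energy(cohort.connectomes, cohort.phenotypes["subject_id"],
                       cohort.systems)
wb = energy.summaries["whole_brain_energy"]
print(f"mean whole-brain control energy: {wb.mean():.4f}")

res = fit_age_gam(wb, cohort.phenotypes)
print(f"energy-age GAM: Z = {res.z_value:.2f}, p = {res.p_value:.3g}, "
      f"partial r = {res.partial_r:.2f} [{res.ci_low:.2f}, {res.ci_high:.2f}]")

null_means = []
for i in range(20):
    ens = NullEnsemble(cohort.connectomes[i], n_null=10, seed=100 + i)
    null = cohort_energy(ens.surrogates, range(10), cohort.systems)
    null_means.append(null.summaries["whole_brain_energy"].mean())
test = real_vs_null_energy_test(wb[:20], null_means)
print(f"null - real energy: {test['mean_difference']:.4f} "
      f"(t = {test['t']:.1f}, df = {test['df']}, p = {test['p_value']:.2g})")
```

prints

```
mean whole-brain control energy: 0.2355
energy-age GAM: Z = -37.07, p = 0, partial r = -0.59 [-0.70, -0.46]
null - real energy: 0.0385 (t = 31.0, df = 19, p = 9.9e-18)
```

The cohort plants a multiplicative age increase in within-fronto-parietal
connectivity (γ = 0.3), so the energy needed to activate the fronto-parietal
system declines steeply with age (negative Z and partial r), and the real
modular networks are cheaper to drive than strength-preserving surrogates
(positive null − real difference).

## Command line

Every stage is also a subcommand of the `ctrlenergy` console script, driven
by a YAML config (`simulate`, `energy`, `null-test`, `age-gam`,
`cognition-gam`, `predict-age`, `mediate`, `all`, `validate`):

```sh
ctrlenergy all --config config.yaml --seed 3 --out out/
ctrlenergy energy --config config.yaml --target-vector nback_map.txt --constrain all
```

All outputs are tab-separated tables plus a run log; identical configs and
seeds give byte-identical tables.

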