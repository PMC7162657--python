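# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `ctrlenergy`.

## Linear network control model

Each subject contributes a symmetric, nonnegative, zero-diagonal weighted
adjacency matrix `A_raw` (tractography-style connection probabilities) and a
fixed a-priori partition of the N regions into cognitive systems.  Activity
evolves as `ẋ = A x + B u` with

* `A = A_raw/(1 + ξ₀) − I`, where `ξ₀` is the largest eigenvalue of
  `A_raw`.  This guarantees strict stability (all eigenvalues of `A` lie in
  `[−2, 0)`).  The literal variant `A_raw/ξ₀ − I`, which leaves one zero
  eigenvalue (marginal stability), is available behind
  `normalize_adjacency(..., literal_control=True)`; the `1 + ξ₀` form is the
  default because the analysis requires a strictly stable drift and the same
  `1 + ξ₀` convention is used for modal controllability.  Note that the
  `1 + ξ₀` scalings are *not* invariant to a uniform rescaling of the raw
  weights (only the pure-`ξ₀` scalings are); connectome weights are treated
  as probabilities on a fixed scale.
* `B = I` (every region is a control node); a restricted control set yields
  a 0–1 diagonal `B`.
* Cost `∫ (x_T−x)ᵀS(x_T−x) + ρ uᵀu dt` with hard boundary conditions
  `x(0) = x₀`, `x(T) = x_T`.  `S` is a 0–1 diagonal matrix selecting the
  constrained set — by default the fronto-parietal system, configurable to
  all nodes.  The terminal equality is imposed on the **full** state vector
  even when `S` penalizes only the fronto-parietal trajectory: the
  derivation's boundary condition is the full-state equality, and the
  empirical robustness check (whole-brain energy with `S` = FP-only versus
  `S` = all nodes correlates at r ≈ 1.0 on synthetic cohorts) shows the
  choice of `S` is not critical for the energy pattern.

### Solution method

The Pontryagin conditions couple state and costate into the affine system
`d/dt [x; p] = Ã [x; p] + b̃` with
`Ã = [[A, −BBᵀ/2ρ], [−2S, −Aᵀ]]` and `b̃ = [0; 2S x_T]`.  The boundary-value
problem is solved by shooting: one matrix exponential `e^{ÃT}` partitioned
into N×N blocks, `c = Ã⁻¹(e^{ÃT} − I)b̃` obtained by an LU solve (never an
explicit inverse; residual checked against `1e-8·‖b̃‖`), and
`p(0) = E₁₂⁻¹(x_T − E₁₁x₀ − c₁)`.  The trajectory is then propagated with
the exact one-step propagator `e^{Ã·dt}` plus the constant forcing term —
mathematically identical to evaluating the closed-form solution at every
grid time, but requiring a single expensive exponential followed by
matrix–vector products, and free of Euler discretization error.  The
condition number of `E₁₂` is recorded and the solver refuses to proceed
beyond 1e12 (the practical remedy is a larger ρ or shorter T).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `horizon_T` | 1 (dimensionless time) | transition horizon; with `dt = 0.001` the trajectory has exactly 1,000 steps |
| `dt` | 0.001 | storage/quadrature grid; must divide `T` |
| `rho` | 1 | weight of the energy term; the source analyses never state it, so 1 is the package default and all reported properties use ρ = 1 |
| `constrain` | `fp` | node set of `S` (`fp` or `all`) |

Per-node energy `E_i = ∫ u_i*(t)² dt` is computed by trapezoidal quadrature
on the stored grid (exact for constant inputs, ~1e-5 accurate for linear
ones at the default grid); no ρ factor enters `E_i`.  The trajectory
distance series is the Euclidean distance to the target over the constrained
set (configurable), and "total distance" is its sum over time points.

Correctness is established against an independent direct-transcription
oracle: piecewise-constant inputs on an exact zero-order-hold
discretization, quadratic objective and terminal equality solved as one KKT
system.  On random stable systems (N ≤ 8) the shooting energy agrees within
~1e-6 relative; tolerance in tests is 1%, dominated by the oracle's input
discretization.  The homogeneity identity `E(c·x_T) = c²E(x_T)` for
`x₀ = 0` holds to ~1e-14.

## Synthetic cohorts

The generator emulates the statistical structure of a developmental
tractography cohort at desk scale.  Defaults: 300 subjects, 64 nodes in 8
equal systems (visual, motor, dorsal/ventral attention, limbic,
fronto-parietal, default-mode, subcortex), ages uniform on [8, 23] years.

* **Edge weights** are lognormal around block means (within-system 0.2,
  between-system 0.05, lognormal σ = 0.5, unit-mean noise).  The lognormal
  multiplicative law mimics heavy-tailed connection probabilities; the
  block means are chosen so the fixed partition is clearly modular
  (Newman Q ≈ 0.2–0.3) without being disconnected.  Real tractography
  matrices motivate the (near-)complete topology.
* **Planted age effect**: within-fronto-parietal edges are multiplied by
  `1 + γ(age − 8)/15`, γ = 0.3 by default — a 30% strengthening across the
  age range, large enough to recover at n = 300 but far from deterministic.
* **Planted mediation chain**: a standardized latent `L = a·z(age) + e`
  (a = 0.6, winsorized at ±3 sd so that the edge factor below stays
  positive) multiplies all edges incident to two designated "cingulate"
  nodes inside the FP block by `1 + c·L` (c = 0.3), and the
  executive-function score is `b·L + f·z(age) + noise` (b = 0.5, f = 0.3,
  residual variance chosen for unit total variance).  The mediation is
  planted **through connectivity**, not by writing energies directly, so
  recovering it exercises the entire solver-plus-statistics pipeline.
* **Covariates**: in-scanner motion declines with age (r ≈ −0.3, stressing
  covariate adjustment), total brain volume has a sex offset, handedness is
  Bernoulli(0.85).

What the generator does **not** emulate: spatial embedding and
distance-dependent connectivity, hemispheric symmetry, realistic
streamline-count distributions, heteroscedastic age noise, or
non-multiplicative developmental remodeling.  Passing tests therefore show
that the pipeline recovers effects of the planted functional form under
realistic noise — not that the empirical developmental findings replicate.

## Null networks

Surrogates preserve the binary degree sequence exactly (Maslov–Sneppen
double-edge swaps, 10 per edge) and the weight multiset exactly, and
approximately preserve nodal strength: weights are re-placed greedily in
descending order onto the edge whose endpoints have the largest residual
target-strength product, followed by a local-search pass that swaps weight
pairs whenever that reduces the squared strength error.  For complete
graphs — the typical case for probability-weighted connectomes — topology
swaps are vacuous and the randomization lives entirely in the stochastic
weight placement (random choice among the top-10 candidate edges).
Resulting strength correlations with the source network exceed 0.999 on
dense matrices and 0.99 on sparse ones.  Real-versus-null comparisons use a
paired *t*-test on per-subject (real, mean-null) whole-brain energies;
null-distribution age-effect tests use the permutation form
`p = (k+1)/(n+1)`.

## Developmental statistics

GAMs are fitted by `mgcv::gam` (REML) through an Rscript subprocess, one R
session per feature batch: penalized cubic regression splines for age
(basis dimension 10) plus linear covariates (sex, handedness, motion, TBV,
total network strength; sensitivity covariates appended as linear terms).
mgcv is the reference implementation of REML-penalized GAMs and is invoked
rather than re-implemented.  Choices the source analyses leave open:

* **Signed Z** — GAM software reports unsigned smooth statistics, so
  `Z = sign(partial r) · Φ⁻¹(1 − p/2)`, with the sign from the linear
  partial correlation of the feature with age given the covariates.  p is
  floored at 1e-300, capping |Z| at ≈ 37.1.
* **Partial r CI** — Fisher z with `se = 1/√(n_eff − 3)`, `n_eff = n − k`
  covariates.
* **Executive-function model** — EF enters linearly alongside the age
  smooth; its partial correlation is computed between GAM residuals of the
  feature and of EF, each adjusted for the age smooth plus covariates.
* Subjects with missing values in any model variable are dropped with a
  logged count.

Type-I calibration of the whole pipeline (generator with γ = 0, c = 0 →
energies → GAM) is checked over 200 *independent replicate cohorts* — one
whole-brain energy feature per cohort — because nodal energies within a
cohort share weight-matrix noise and give far fewer effective tests than
their count suggests.

Mediation residualizes x, m, y on the nuisance covariates, standardizes to
unit variance, estimates a (m~x), b and c′ (y~m+x), c (y~x) by OLS, and
bootstraps the indirect effect a·b with case resampling (default 10,000
resamples; percentile CI; two-sided sign-proportion p).  `c = c′ + a·b`
holds exactly for nested OLS and is asserted in tests.

## Brain-maturity prediction

Nested two-fold cross-validation: subjects sorted by age (stable sort, ties
keep input order), odd ranks to subset 1, even to subset 2; each subset is
once the training set.  Features are min–max scaled to [0, 1] with
training-set parameters (constant features map to 0 with a warning; test
values may leave [0, 1]).  Ridge coefficients are the closed form
`(XᵀX + λI)⁻¹Xᵀy` on the centered scaled design with an unpenalized
intercept.  λ comes from an inner two-fold CV (same odd/even rule) over the
16-value grid `2⁻¹⁰ … 2⁵`: per λ, mean r and mean MAE over the two inner
folds; the 16 mean-r values and the 16 mean-(1/MAE) values are min–max
normalized to [0, 1] and summed (z-scoring available behind
`inner_normalization="zscore"`; min–max is the default for boundedness and
predictable ties), ties broken toward the larger λ (stronger
regularization, smaller variance).  Accuracy is summarized per fold by the
MAE and by the partial correlation of predicted and true age controlling
sex, handedness, motion, TBV and network strength.  Significance permutes
the feature-to-age correspondence and reruns the entire nested procedure
(`p = (k+1)/(n_perm+1)`, default 1,000 permutations).  The interpretive
model is refitted on all subjects (λ by inner CV on the full sample) and
reported through the Haufe transform `a = Σ_X w` on the scaled design;
|a| ranks regional importance and correctly deflates suppressor features.
A random-split mode repeats the whole procedure on random halves (default
100 repeats) and averages partial r and MAE.

No quantity derived from a test fold (scaling parameters, λ, covariance for
the Haufe pattern) ever touches training; this is asserted by mutation
tests that corrupt the test fold.

## Problem sizes and numerical choices

Shipped tests and the acceptance script run at desk scale, chosen so the
planted effects are comfortably identifiable: 300 × 64 for the planted
cohort, 100 × 64 with 20 surrogates per subject for the null comparison,
200 replicate 100 × 16 cohorts for calibration, 50 seeded 100 × 64 runs for
Haufe ranking, n = 2000 with 10,000 bootstrap resamples for mediation
recovery and 200 × (n = 500, 1,000 resamples) for its null sweep.  The
232-node, 946-subject scale of a full imaging study is supported by the same
code paths.  All randomness flows through `numpy.random.default_rng` seeds;
every pipeline stage derives its seed from the global seed by a fixed
offset, making tables byte-identical across reruns.

## Known limitations

* Linear dynamics: the control energies are those of the linearized system;
  they are interpretable as relative costs, not metabolic quantities.
* The full-state terminal equality (see above) is a modeling decision the
  derivation forces; a partial terminal constraint is not offered.
* mgcv smooth p-values are approximate; calibration was verified empirically
  at the shipped scales (≈5% type-I at α = 0.05) but small-sample behavior
  below n ≈ 100 is untested.
* The strength sequence of surrogates is preserved approximately
  (r > 0.99), not exactly — exact joint degree+strength preservation is not
  generally possible while randomizing weight placement.
* The synthetic generator's simplifications listed above mean effect sizes
  here do not transfer to empirical cohorts.
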