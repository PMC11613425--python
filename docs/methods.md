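# Methods

## Model and solver

`MultisetCCA` solves the SUMCOR form of multi-set CCA: for K standardized
views `X_i` (samples × features) and each component set `a`, maximize
`Σ_i Σ_{j≠i} w_ia' X_i' X_j w_ja` subject to the per-view blended norm
constraint `(1−c_i) w_ia' X_i' X_i w_ia + c_i w_ia' w_ia = 1` and, for
later components, zero within-view covariance with every earlier variate.
At `c = 0` the constraint pins each variate's norm, making the objective
the plain sum of pairwise canonical correlations; at `c = 1` the weights
are unit-norm and the solver maximizes summed cross-covariances. The
ridge blend keeps the constraint matrix positive definite whenever a view
has at least as many features as samples (such views are refused outright
at `c = 0` rather than pseudo-inverted).

Components are extracted sequentially. Each one starts from the leading
eigenvector of the pooled generalized eigenproblem `C w = λ B w` (C:
off-diagonal blocks `X_i' X_j`; B: block-diagonal constraint matrices),
which is the exact solution for K = 2 and a good relaxation otherwise,
and is refined by Horst-style alternating maximization: each view's
weight has the closed-form update `w_i ∝ M_i⁻¹ X_i' Σ_{j≠i} X_j w_j`
under its own constraint, which never decreases the objective, so the
iteration converges (stop when the objective changes by ≤1e-12 relative,
cap 1000 sweeps). The pooled eigenproblem alone distributes the
normalization across views and does not satisfy the per-view constraints
for K > 2; the refinement restores them exactly, and on small instances
the result matches direct SLSQP maximization of the constrained objective
to ~1e-12 (see the acceptance tests). Within-view orthogonality of later
components is enforced by restricting each view's search to the null
space of its earlier constraint vectors `X_i' X_i w_ib`, so the
orthogonality invariant holds to machine precision rather than
approximately.

Near-tied components (objectives within 1e-8) are ordered by a
lexicographic rule on the first view's weights so fits are deterministic.

### Sign convention

Canonical weight vectors are sign-indeterminate per view, but the signs
are coupled across views through the objective: flipping one view negates
its correlations with all others. Flipping every view independently to
some per-view rule (e.g. largest entry positive) can therefore silently
negate cross-view correlations. The package fixes the gauge per
component by (i) making the largest-magnitude entry of the *first* view's
weight vector positive, then (ii) flipping each remaining view so its
training variate correlates non-negatively with the first view's. This
preserves the fitted objective whenever the optimum is sign-consistent,
which holds at any local maximum for the first view's pairings.

### Standardization

Each feature is centered and scaled to unit SD on the training rows only;
hold-out rows are transformed with the training parameters (no
re-centering). Zero-variance features are dropped with a warning and
recorded on the model; serialized models carry means, scales, and the
dropped list.

## Protocol parameters

| parameter | default | role |
|---|---|---|
| `gap_threshold` | 0.41 SD | z-scored brain-age-gap cut; each extreme group holds ≈34.1% of a normal cohort (strict inequalities, boundary excluded) |
| `train_fraction` | 0.8 | stratified train/hold-out split on the group label |
| `n_folds` | 3 | stratified CV inside the training partition for selecting c |
| c grid | 7 log-spaced in [1e-4, 1] | shared across views by default; CV score = summed held-out pairwise correlations over all sets; ties → smaller c |
| `variance_threshold` | 0.90 | m = smallest PC count of the smallest view reaching this cumulative variance fraction |
| `top_k` | 5 | attribution list length per view/component |
| `n_stability_iterations` | 100 | repeated 80/20 re-splits; c re-selected per iteration by default |
| α | 0.05 | BH-FDR level over the full pairs × sets family |

The z-transform of gaps uses the population-SD convention (divide by n);
either convention satisfies every downstream contract, but one had to be
fixed.

## Synthetic data generator

The generator emulates only the second-order structure the analysis
consumes, not images or connectivity topology. Per subject, m shared
latents `z_k ~ N(0,1)`; view i sees component k at fidelity ρ[i,k]
(`s_ik = ρ z_k + √(1−ρ²) ε`), embedded through a random column-orthonormal
`Q_i` plus isotropic noise σ. Because the embedding is orthonormal, the
best attainable cross-view correlation has the closed form
`r* = ρ_i ρ_j / (1+σ²)`, which anchors the recovery tests (ρ = 0.9,
σ = 0.1 ⇒ r* ≈ 0.802). Defaults are a scaled-down four-view design
(20/30/60/9 features, n = 2,000, ρ = 0.9, σ = 0.1) mirroring three wide
"brain" views and one narrow "environment" view; full-size dimensions are
available by configuration. The group label comes from thresholding a
standard-normal gap at ±0.41; the group effect δ (default 0.2 SD on
component 2 only, echoing a group difference carried by a single
component set) is added to the latents of accelerated subjects *after*
labelling, so δ is exactly the standardized latent shift the ANOVA stage
should detect (attenuated by ρ at the view level). Cognitive composites
are linear in the component-1 latent (slope 0.3; crystallized at half
that) plus age and gender terms and site/family random intercepts
(SD 0.3 each, residual SD 1, 10 sites, ~10% siblings). All randomness
flows from one root seed through named substreams, so outputs are
bit-identical per seed and stages can be resized independently.

What passing tests on this generator do *not* show: robustness to
non-Gaussian features, missing data, view-specific confounds, or
realistic anatomical correlation structure — the environment view is
statistically identical to the brain views here, whereas real
environment batteries are discrete and skewed.

## Evaluation details

- Hold-out pairwise correlations use the exact t transform (n−2 df) and
  one BH family across all view pairs × component sets.
- Shared variance percentage is `100·corr(feature, variate)²` on the
  hold-out rows; constant features get 0 with a warning. Top-k ties break
  lexicographically on the feature name.
- Group ANOVA is one-way accelerated vs delayed; with two groups F is
  the squared pooled-variance t statistic (cross-checked in tests).
- Stability: each iteration re-splits, optionally re-selects c, refits,
  and attributes on its own hold-out set. Weights are sign-aligned to the
  first successful iteration (inner-product sign per view-component)
  before averaging; CIs are empirical 2.5/97.5 percentiles. Note that
  iterations share ~80% of subjects pairwise, so per-feature Top-k
  frequencies are strongly dependent across iterations: under a pure
  noise model a feature can legitimately reach high frequency within one
  dataset. Chance-level comparisons should average over independent
  datasets (the test suite does), while the mean frequency across
  features equals k/d exactly by construction.
- Mixed models are REML fits with a site random intercept and a
  family-within-site variance component (family labels are prefixed with
  their site, making crossed and nested parameterizations equivalent).
  L-BFGS occasionally stalls when a variance component sits at the
  boundary; the fit then falls back to Powell's method. Boundary
  variances are reported as estimated (possibly 0); fixed-effect p-values
  are the backend's normal-approximation values. With planted-zero
  variances the fixed effects agree with OLS to a fraction of a standard
  error, not exactly — REML boundary estimates keep O(1/n) sampling mass.

## Numerical choices and degenerate inputs

- Generalized eigensolver: LAPACK `eigh(C, B)`; B is positive definite by
  construction (or the fit is refused).
- Constraint satisfied exactly by construction of the per-view
  normalization; verified to 1e-8 in every fitted model.
- Zero-variance canonical variates on evaluation data raise rather than
  emitting NaN correlations.
- Stratified splits require ≥2 subjects per stratum; CV candidates that
  are infeasible (c = 0 with a wide view inside a fold) are skipped, and
  an all-infeasible grid raises.
- A low cross-view signal at CV time (best summed correlation under 10%
  of its ceiling) logs a warning instead of failing: pure-noise inputs
  are legitimate in calibration studies.

## Problem sizes used in the shipped checks

The acceptance suite runs: oracle comparisons at n = 30–60; planted
recovery at n = 5,000 × 10 seeds; null calibration on 500 datasets of
n = 500 (mixed models on 200 of them); group-effect detection on
datasets sized so ≈2,000 subjects per group reach the hold-out ANOVA
(n = 29,400 before exclusion) × 100 seeds — the detection claim is about
the ANOVA-stage sample size, since at ~400 per group the power for a
0.2 SD latent shift is only ~0.7; and a 20-iteration stability run. The
acceptance script uses the default n = 2,000 design plus one
detection-sized run, keeping a full from-scratch reproduction within a
few minutes on one CPU.

## Known limitations

- The solver targets SUMCOR via sequential deflation; for K > 2 the
  greedy per-component optimum need not be the joint optimum over all m
  components (standard for this family).
- Per-view regularization follows the printed constraint on raw `X'X`
  cross-products, so the effective ridge strength relative to the data
  scale shrinks as n grows; the CV grid spans to the covariance limit
  c = 1 regardless.
- Mixed-model inference uses asymptotic (z) p-values without small-sample
  df corrections.
- The stability protocol quantifies split-resampling variability, not
  sampling variability of the cohort itself (see the dependence note
  above).
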