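# Methods notes

## Stage-1 mixed models

Both stage-1 models are variance-component models with crossed
categorical factors, fitted by REML separately per population ×
environment — pooling across environments is deliberately avoided so
that stage-2 kernels, not stage 1, carry the cross-environment
structure.

* End-of-season model: trait = μ + Hybrid + Range + Row + Rep + ε.
  For BLUEs the hybrid is the only fixed factor (reference coding;
  reported BLUE = intercept + effect, so BLUEs sit on the trait scale);
  Range/Row/Rep are random. Treating the design factors as random is a
  choice — with a full RCBD either treatment is defensible, and random
  design effects keep the fit well-posed when a grid level is thin.
  The heritability refit makes every term random and uses the entry-mean
  form h² = σ²_H / (σ²_H + σ²_ε / r) with r the number of replications
  actually present; design-factor variances are estimated but excluded
  from the denominator, matching the entry-mean target (they cancel in
  within-trial hybrid comparisons).
* Temporal model (per VI): value = μ + H + F + H×F + Range + Row + Rep + ε,
  fully random. The exported *temporal value* of hybrid i at flight j is
  BLUP(H_i) + BLUP(H×F_ij) — the hybrid's predicted deviation at that
  flight. The package deliberately includes the hybrid main effect: the
  interaction BLUPs alone are doubly centered, which forces their
  covariance with any end-of-season trait to sum to ≈ 0 across flights;
  persistent hybrid-level signal (the thing temporal correlations,
  FPCA scores and phenomic kernels feed on) lives in H + H×F. The
  flight main effect and intercept are excluded, so values remain
  centered across hybrids at every flight, and empty cells shrink
  toward the hybrid's main effect. The complete hybrid × flight grid is
  always emitted.

### Estimator

EM-REML on Henderson's mixed-model equations. Every random factor's
Z'Z block is diagonal, so the largest block (the hybrid × flight
interaction, with thousands of levels) is absorbed via a Schur
complement; the EM trace terms come from the same small dense
factorization (tr of the big block's inverse reduces to
tr(D⁻¹) + tr(S⁻¹ B D⁻² B')), making a full-scale temporal fit a
~500-dimensional Cholesky per iteration. W'W is precomputed once per
environment and shared by all 36 VI fits, which also warm-start from
the previous VI's variance components.

Numerical policy:

* convergence: max relative change < `tol` (default 1e-6), ≤ `max_iter`
  iterations; variances floored at 1e-8 × var(y) (bounded EM — never
  negative);
* every 8 sweeps each component is extrapolated along its own geometric
  EM trajectory (Aitken step); components extrapolating through zero
  while already < 1% of var(y) are snapped to the floor (a component at
  the zero boundary otherwise decays only harmonically);
* if EM still stalls, the restricted likelihood is maximized directly
  (Nelder–Mead on log-variances, using the same factorization for the
  determinant terms) and the result marked converged only if the
  optimizer succeeds; otherwise the fit is returned flagged, not
  raised;
* the reported restricted log-likelihood uses the MME determinant
  identity log|V| + log|X'V⁻¹X| = (n−p−q)·log σ²ε + Σ q_k log σ²_k +
  log|M|, verified against the dense-covariance formula in tests;
* rows with missing responses are dropped per fit; no imputation;
* full-scale stage-1 runs (36 VIs × preset-sized environments) use the
  profile tol = 1e-5, max_iter = 60 with warm starts — the bookkeeping
  and downstream scores are insensitive to the final ×10 tolerance
  polish, and the whole four-environment stage then costs under a
  minute.

## Temporal correlations

Pearson, per flight, over hybrids, between the temporal value at that
flight and the trait BLUE; summarized as mean ± sd over flights.
Flights with zero variance on either side are excluded (correlation
undefined) rather than imputed as 0. Ranking is by mean r descending
with lexicographic tie-break, so the secondary-trait choice (argmax) is
deterministic.

## Functional PCA

The temporal BLUPs live on a common, dense per-environment DAP grid, so
the FPCA estimator is quadrature-weighted PCA of the discretized sample
covariance: with trapezoidal weights W on the grid, eigendecompose
W^{1/2} C W^{1/2}; eigenfunctions are quadrature-orthonormal; scores are
weighted inner products of centered curves with eigenfunctions. This is
exact at the observed design and coincides with sparse-data functional
estimators (PACE-style) in the dense limit, while avoiding bandwidth
and smoothing choices that nothing in the 5–20-flight design would
anchor. No pre-smoothing. Eigenfunction sign is fixed by making the
largest-magnitude grid value positive, so repeated fits are
bit-identical. The until-flowering window keeps flights with
DAP ≤ flowering start, inclusive; windows with fewer than two flights
are an error. All components are retained internally (the centered
curves reconstruct exactly on the grid); downstream score matrices use
the first two per VI, columns named `<vi>_FPCA1/2` in sorted VI order —
identical labels across environments is precisely what makes the
row-wise merge legitimate.

## Kernels

* Genomic: columns of the dosage matrix centered and scaled to unit
  population variance, G = X_c X_c'/p, so trace(G)/n = 1 exactly;
  monomorphic markers dropped with a warning.
* Phenomic: FPCA score columns centered and standardized before
  R_c R_c'/(2 · n_VI). Standardization is a package choice: raw FPCA
  scores differ in scale by orders of magnitude across VIs, and the
  divisor-by-column-count construction (exactly analogous to X X'/p)
  presumes comparable columns. Constant columns are dropped and the
  divisor reduced.
* Environment: block kernel Z_E Z_E'/n_env (environment as a random
  block effect, not fixed means).
* Interactions (reaction-norm): same-environment indicator ⊙ main
  kernel, divided by n_env (the phenomic main kernel already carries
  its 2·n_VI divisor).
* Model kernel lists: M1/M6 {E, g, g×E}; M2 {E, P1, P1×E};
  M3 {E, P2, P2×E}; M4/M5 add the phenomic pair to M1. Hybrid-level G
  is expanded to records by incidence, so its restriction to one
  environment equals G on that environment's hybrids.
* All kernels are symmetrized; eigenvalues below 1e-8 × max are
  truncated at the sampler, which also clips floating-point negatives.

## Bayesian kernel regression

Each kernel term is represented on its eigenbasis B = V Λ^{1/2}
(coefficients iid N(0, σ²_k)); because B'B is diagonal, the within-term
Gibbs update factorizes into independent univariate draws and the whole
sweep is vectorized. Variances carry scaled-inverse-χ² priors, df = 5,
with scales splitting R² = 0.5 of the response variance equally across
non-residual terms (prior mode = share). Missing responses are sampled
by data augmentation — that is the prediction mechanism for unobserved
records. Chain defaults are 12,000 iterations / 2,000 burn-in / thin 5;
the pipeline and tests use shorter, explicitly configured chains
(≈ 1,200–4,000 iterations) sized to the few-hundred-record problems
they fit, where effective sample sizes are ample. Seeded chains are
bit-reproducible; numeric parity with any particular Gibbs
implementation is not claimed, only statistical agreement (checked
against a conjugate closed form and by parameter recovery).

The multitrait model (M6) is bivariate: unstructured 2×2 covariances on
the genetic terms (g, g×E) and the residual, inverse-Wishart priors
(df 5, scales matching the univariate split); the environment term
stays trait-independent, since nothing in the model notation constrains
where the trait covariance sits and the genetic terms are where it is
identified. Missing primary values are imputed from their conditional
normal given the secondary trait — the mechanism by which an
always-observed secondary trait (VARI FPCA1) sharpens predictions for
untested material. The reported genetic correlation is taken from the
g term's covariance chain.

## Cross-validation scenarios

Folds partition hybrids, not records (5 folds; 20 repeats in the full
design, smaller counts in the fast profile), so tested/untested status
is consistent across environments within a repeat, and one fold plan
serves all four scenarios. Training responses: tested hybrids only
(untested hybrids' responses are masked everywhere — the kernel rows
remain, the likelihood contributions do not, which is equivalent to
removal and is what prevents genotype leakage); CV0/CV00 additionally
mask the held-out environment. The secondary trait stays observed for
all records in every scenario. Abilities are Pearson correlations,
computed per environment; summaries pool mean ± sd over repeats × folds
× environments (the pooling is a documented choice; per-environment
tables remain available in the long-format output). Chain seeds are
derived per (repeat, fold, model, environment) from the master seed, so
runs are reproducible and chains independent.

## Synthetic-trial generator

What it emulates: two-population maize trials in RCBD with 2
replications; marker dosages with uniform MAF in [0.05, 0.5]
(1,000 markers by default at desk scale); additive genetic values built
*from the markers* (so genomic kernels carry real signal) with
per-environment marker-driven G×E deviations (variance 0.3 × main
genetic variance by default); plot residual variance back-solved so the
entry-mean heritability hits its target (defaults 0.7 for GY, 0.8 for
PHT; genetic sd 0.8 t/ha and 10 cm around means of 10 t/ha and 220 cm);
independent Gaussian range/row/rep effects at 0.25 × residual variance
each; VI trajectories double-logistic in DAP (green-up rise, plateau
near flowering at inflection flowering−20 d, senescence decline from
flowering+25 d losing 60% of amplitude), with hybrid genetic variation
in the amplitude (CV 0.12) and green-up timing (sd 0.5 d), plot noise
at 6% of amplitude, and each VI's amplitude score constructed with a
programmed correlation to the yield genetic value (VARI = +max,
RCC = −max, bands weak, others random intermediates, max = 0.6 by
default). Timing variation and noise are kept small relative to the
amplitude signal so that the programmed correlation is recoverable by
the temporal stage — the calibration target the generator's own
invariants state. Ground truth (genetic values, G×E deviations, VI
amplitude scores, loadings) is recorded for recovery tests.

What it does not emulate — and hence what passing tests do not show
about real data: spatial autocorrelation beyond additive row/column
effects, missing plots or flights, population structure and LD (hybrids
are unrelated draws, which caps predictability of untested genotypes at
realistic-looking but structurally different levels than a structured
breeding population), weather-driven trajectory shapes, VI-specific
measurement error structure, and dominance (top-cross hybrids preclude
estimating it anyway). Absolute prediction abilities on synthetic data
are therefore not comparable to field studies; ordering properties
(CV2 ≥ CV1, CV0 ≥ CV00, multikernel competitiveness, ability rising
with heritability) are the meaningful checks.

## Problem sizes

Full-scale runs (the preset shapes: 415 hybrids × {7, 14} flights and
220 × {17, 17, 20}, 36 VIs) exercise the stage-1 and FPCA bookkeeping.
Estimator-recovery and cross-validation checks run at a few hundred
records with 2 environments and reduced repeats — sizes at which the
quantities under test (posterior means over seeds, scenario ordering
signs) are stable, chosen as the package's own desk-scale defaults.

## Known limitations

* EM-REML with the Nelder–Mead fallback targets the global REML optimum
  but, like any variance-component optimizer, can only be verified
  against oracles at small scale; full-scale fits are checked through
  warm-start stability and the downstream invariants.
* The Gibbs samplers are single-chain; diagnostics are limited to
  effective-sample-size estimates per variance chain.
* The g×E variance is weakly identified when the same hybrids appear in
  all environments (its within-environment block is collinear with g's
  diagonal); its posterior mean leans on the prior. The g and residual
  variances, and all predictions, are unaffected in recovery tests.
* Score matrices assume an identical VI panel across environments;
  partially overlapping panels are rejected rather than intersected.
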