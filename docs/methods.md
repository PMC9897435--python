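# Methods

This note documents the statistical models implemented in `gagmced`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the numerical
choices made along the way. Nothing here is an empirical claim about real
biofluid data; every number the package reports is computed by the code on
data you give it (or on synthetic data it generates).

## 1. The feature calculus

A measurement panel consists of 17 free glycosaminoglycan disaccharide
concentrations per fluid (µg/mL): eight chondroitin-sulfate (CS) species
(0s, 2s, 6s, 4s, 2s6s, 2s4s, 4s6s, tris), eight heparan-sulfate (HS)
species (0s, 2s, 6s, ns, ns6s, ns2s, 2s6s, tris), and hyaluronic acid
(HA). From these, 22 derived features are computed:

- **Totals** — `total_cs`, `total_hs`: sums of the constituent species.
- **Mass fractions** — each species as a percentage of its class total
  (16 features). Fractions are defined as 0 when the class total is 0.
- **Charge** — `charge_cs`, `charge_hs`: the average number of sulfo
  groups per disaccharide, computed as the sulfo-weight-weighted sum of
  mass fractions (weights 0 for unsulfated, 1 for mono-, 2 for di-, 3 for
  tri-sulfated species). Bounded in [0, 3] by construction.
- **Ratios** — `ratio_4s_0s`, `ratio_6s_0s` for CS; undefined (NaN) when
  the denominator is 0.

Totals, fractions and charges are scale-invariant or linear in the
concentrations, so the derived block behaves predictably under unit
changes; the test suite checks this by property-based testing.

### Detectability

A concentration feature is *detectable* in a fluid when its median across
the cohort exceeds the limit of detection (0.1 µg/mL, the default
`lod`). Derived features inherit detectability through their
dependencies:

- a total is kept if at least one constituent species is detectable, and
  is then computed over the detectable species only;
- a fraction is kept iff its species is detectable;
- a ratio is kept iff numerator and denominator species are both
  detectable;
- a charge is kept iff at least two *sulfated* species of its class are
  detectable — with a single detectable sulfated species the charge is a
  deterministic rescaling of one mass fraction and adds no information.

This dependent-feature rule, rather than a blanket "all constituents
detectable" rule, is what makes a sparse fluid (like plasma, where most
species sit below LOD) retain its total and the fractions of the species
actually measured.

### Outlier screen

A two-step robust screen: first on the total CS concentration, then per
detectable feature. A sample is flagged when it lies outside
median ± 5·MAD, with the MAD normalized by 1.4826 so the cutoff is in
σ-equivalent units; when MAD = 0 (heavily tied data) the screen falls
back to the IQR. The screen requires ≥ 10 samples and is off by default
in `training_matrix` — it is a data-hygiene device, not part of the
model.

## 2. The synthetic-cohort generator

The generator is the package's study-conditions bench: everything the
inferential code is validated against is drawn from it.

**What it emulates.** Per-fluid concentrations are skew-normal
(shape α = 3, scale set by a coefficient of variation of 0.30 around
target medians), truncated at zero and left-censored at the LOD
(values < 0.1 µg/mL recorded as 0). Medians are chosen so the default
cohort reproduces a realistic detectability pattern: a sparse plasma
panel (two CS species above LOD) and a rich urine panel (most features
detectable). Samples belong to one of 4 batches with additive
location shifts (SD 0.15 ω-units). Cancer cases (default five types, 40
each, vs 300 healthy) receive type-, fluid- and feature-specific location
shifts in ω-units; the default template concentrates signal in 0S CS
(all types, both fluids, +0.8), with smaller type-specific shifts
(plasma 4S CS −0.6 in two types; urine 2S6S CS +0.8 in one; urine 0S HS
+0.5 in one). Stage labels are tied to the latent per-subject effect
scale with a weak slope (0.4), so later stages are somewhat easier to
detect. A validation-style cohort adds two measured confounders — CRP
(log-normal) and HDL-C (normal) — that shift the 0S-CS-driven features
up and down respectively; the effect sizes (0.33, −0.17) were calibrated
once so the score–CRP and score–HDL Kendall correlations land near 0.29
and −0.16, and then frozen. Survival times are Weibull proportional
hazards with a planted hazard ratio (default 0.61 for low vs high score)
and independent uniform censoring whose horizon is solved by bisection to
hit a target event fraction (0.5). The mouse experiment generates
per-mouse plasma and per-cage pooled urine at four timepoints with
multiplicative disease trajectories (plasma ×2.48 = +148% and urine
×2.16 = +116% in 0S CS at the metastasis timepoint), log-normal
mouse-level intercepts and measurement noise, and a cage rule: pooled
urine is only valid while both cage-mates are alive.

**What it does not emulate.** No correlation structure between species
beyond what the shared latent effect induces; no assay drift within a
batch; no age/sex effects on concentrations; no missing-at-random
dropout in the human cohorts; no inter-fluid correlation beyond the
shared diagnosis; no measurement rounding. Cancer effects are pure
location shifts — no variance or shape changes unless you set
`variance_multipliers`. The generator is deliberately simple enough that
the Bayes-optimal discrimination is computable (see §7).

## 3. Differential-abundance screen (ROPE)

Each standardized feature is modeled per fluid with a skew-normal
regression: group-specific locations (healthy + one per cancer type),
additive batch effects on location, a log-linear group×batch model on the
scale, and a shared skewness α. Priors: Normal(0, w) on locations with
w = 5 by default (sensitivity checked at 2.5 and 10), Gamma(1, 2) on the
batch-effect SD and on scales, Normal(0, 5) on α.

The quantity screened is the *difference in model-implied medians*
between each cancer type and healthy (the skew-normal median is computed
from the fitted location/scale/shape, not assumed equal to the
location). A feature–type pair is called credible when the 95% credible
interval of that difference excludes 0 **and** at most 5% of posterior
draws fall inside the region of practical equivalence (half-width 0.2
standardized units). Ratio features are excluded from the screen (they
are unstable under near-zero denominators and redundant given fractions).

Identifiability choices: batch location offsets are constrained to sum
to zero (B−1 free parameters) — otherwise group locations and batch
offsets trade off along a ridge — and are parameterized non-centrally
(offset = τ·raw with raw ~ N(0, 1)), which removes the funnel between τ
and the offsets when batches are few. Groups need ≥ 5 samples; with a
single batch the batch terms degrade gracefully to zero with a warning.

## 4. Score construction (projection-predictive selection)

The any-cancer score is built in three stages.

**Reference model.** Bayesian logistic regression on all detectable
features with independent Student-t(df = 7, scale = 2.5) priors on
standardized coefficients — heavy-tailed enough to tolerate large true
effects, concentrated enough to stabilize near-separable fits. A
separation warning fires when any posterior draw exceeds |15|.

**Search.** Greedy forward selection over candidate features. Each
candidate submodel is scored by projecting the reference posterior onto
it: the projection solves a weighted logistic regression of the
reference model's fitted probabilities (soft labels) on the submodel
columns. Expected log predictive density is estimated by
Pareto-smoothed importance sampling leave-one-out (PSIS-LOO), reusing
the reference model's importance weights. The submodel size is chosen by
the one-standard-error rule on the ELPD path: the smallest size whose
ELPD is within one SE of the best.

**Final score.** 400 reference draws are projected per-draw (no
clustering) onto the selected subset; the score of a sample is the
posterior-mean linear predictor, i.e. a log-odds of cancer.
Classification cutoffs are anchored on controls: the cutoff for target
specificity s is the ⌈s·n⌉-th smallest control score, and a sample is
positive when its score is strictly greater. A pruned variant
(`prune_to_independent`) restricts candidates to the 17 directly
measured concentrations, avoiding the interpretability problems of
selecting derived features whose constituents move together.

**Honesty checks built into the design.** The identity projection (all
features) reproduces the reference predictions to numerical precision;
selection on permuted labels, run inside cross-validation so the
selection itself is validated, stays at chance AUC.

## 5. Evaluation

- **AUC** by midranks with a DeLong confidence interval.
- **Sensitivity at fixed specificity** with Wald (default) or
  Clopper-Pearson binomial CIs; the degenerate Wald case (0 or all
  detected) is flagged. Subgroup sensitivities always reuse the global
  control-anchored cutoff.
- **PPV/NPV** by the standard post-test probability identities at a
  stated prevalence.
- **Scaled Brier** = 1 − Brier/(p̄(1−p̄)), so 0 is the
  prevalence-predictor and 1 is perfect.
- **Bootstrap internal validation** re-runs the *entire* pipeline
  (reference fit with a df = 3 prior for speed/robustness, forward
  selection with cap min(one-SE size, cases/10, per-fluid cap), clustered
  projection) on each resample and reports optimism both against the
  original data (the classic optimism bootstrap) and against the
  out-of-bag assessment set; corrected metrics subtract mean optimism.
  The out-of-bag flavor is deliberately conservative — it folds the
  pessimism of assessing on the ~36.8% held-out fraction into the
  optimism estimate — so it tends to under-state performance slightly.
- **Confounder tests**: Kendall tau-b between score and covariate with a
  permutation p-value p = (1 + #{|τ*| ≥ |τ̂|})/(n_perm + 1), Holm-adjusted
  across the covariate panel.

## 6. Survival analysis

Kaplan-Meier with Greenwood log-log confidence intervals; median
follow-up by reverse KM; the log-rank test from hypergeometric moments;
Cox proportional hazards by Newton-Raphson with Efron's tie correction.
Age enters adjusted models through a restricted cubic spline with 3
knots at the 10/50/90% quantiles (2 standardized basis columns).
Proportional hazards are checked with scaled Schoenfeld residuals
against KM-transformed time (per-covariate t-tests plus a global
chi-square). Discrimination is Harrell's C / Somers' Dxy; internal
validation bootstraps the Dxy optimism, with ≤ 20% correction treated as
acceptable. `lifelines` is used in the test suite as an independent
cross-check oracle (agreement to 1e-4), never as the implementation.

Dichotomized comparisons (low vs high score at a prespecified cutoff)
error out rather than report when the cutoff leaves a single stratum.

## 7. Longitudinal mouse analysis

After the cage rule removes invalid pooled-urine rows, each feature is
standardized and fit with a normal linear mixed model — timepoint fixed
effects, unit (mouse or cage) random intercepts — by a conjugate Gibbs
sampler (flat prior on fixed effects, inverse-gamma(2, 1) and (2, 0.5)
on residual and intercept variances). Percent change per timepoint is
computed draw-by-draw on the raw scale after back-transforming,
100·(level_t − level_baseline)/level_baseline, discarding draws whose
baseline back-transform is non-positive (the discarded fraction is
reported). Timepoint structure is also summarized by PCA on z-scored
features with bivariate-t 95% ellipses (df = max(n − 2, 3)) around
timepoint centroids.

## 8. Numerical choices

- **Sampler.** Posterior sampling uses an ensemble MCMC sampler (`emcee`)
  with differential-evolution moves (80% DE, 20% DE-snooker), which mix
  far better than stretch moves on the correlated skew-normal posterior.
  Walkers are treated as chains for split-R̂/ESS diagnostics (arviz).
  Log-posteriors are fully vectorized across walkers.
- **Reference-fit initialization** at the MAP (L-BFGS), walkers scattered
  at 5% relative jitter; draws thinned by 3.
- **Projection solver**: Newton (IRLS) on the convex soft-label logistic
  objective with a backtracking (Armijo) line search — far from the
  optimum the fitted probabilities saturate, the Hessian collapses and
  fixed-length steps limit-cycle, so monotone descent is enforced;
  converged at max|grad| < 1e-9 or step < 1e-10, ≤ 100 iterations.
- **Search acceleration**: during forward selection, reference draws are
  clustered once (k-means, 20 clusters; 10 inside the bootstrap) and
  candidate projections use cluster means with cluster weights; the final
  model is always projected per-draw.
- **Efron ties** in Cox partial likelihood; Newton steps clipped at 5 to
  survive bad starts; warnings for < 10 events per covariate and |coef| > 10.
- **MAD normalization** constant 1.4826 in the outlier screen.
- **Cutoff tie-breaking** upward (strictly-greater positivity), so the
  achieved specificity is never below target on the anchoring data.
- **Seeds.** Every stochastic routine takes an explicit seed; derived
  seeds are drawn as integers below 2³¹ from a parent generator.

## 9. Problem-size defaults

Default sizes (300 healthy + 5×40 cases; 4 batches; ROPE runs of 400
burn-in + 300–400 kept steps; 400 projected draws; bootstrap B = 100;
mouse n = 20 in 10 cages) are package choices tuned to give stable
diagnostics at interactive runtimes on a single CPU, not claims about
any particular study's size. All are configurable.

## 10. Limitations

- The ensemble sampler's R̂/ESS on the skew-normal mixed model are
  adequate (R̂ ≲ 1.1 at default lengths) but not gold-standard HMC
  quality; doubling `n_steps` tightens them when a single feature's
  decision is borderline.
- The ROPE decision depends on the 0.2-SD half-width; it is a
  practical-equivalence convention, not an estimate.
- PSIS-LOO reuses reference-model importance weights for submodels; this
  is the standard projection-predictive shortcut and can be optimistic
  for very small submodels on small data.
- The generator's independence across species means multivariate
  structure (and thus the value of multi-feature scores) is milder than
  in real biofluids; the Bayes-oracle comparison calibrates expectations
  under *these* conditions only.
- Percent-change back-transformation discards non-positive baseline
  draws; with very noisy baselines the retained fraction should be
  inspected (`frac_defined`).
- The survival module assumes non-informative censoring throughout.
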