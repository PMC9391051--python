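# Methods

This note records the statistical model implemented in `phenomv`, the
defaults and numerical choices, what the simulator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Two-stage composable inference

The pipeline is deliberately composable: an arbitrarily rich univariate
(UV) stage reduces animal-level data to a matrix of effect estimates and
standard errors, and the multivariate (MV) stage consumes only that
matrix. Either stage can be swapped independently — the MV stage runs
standalone on any long-format table of (phenotype, line, estimate, SE,
null-flag) rows.

### Univariate stage

For one phenotype at one centre, the measurement on animal *i* is
modelled as

y_i = θ_pg I(i ∈ line g) + x_iᵀβ + Σ_r z_riᵀα_r + ε_i,
α_r ~ N(0, σ_r² I), ε ~ N(0, σ²_resid I).

- **Fixed terms**: genotype indicator, sex (coded ±½ so the genotype
  coefficient is the average of sex-specific effects), sex–genotype
  interaction. Aliased columns are dropped by a rank check before
  fitting; a design still singular afterwards is reported as
  non-converged with a diagnostic rather than raised.
- **Random terms**: day and litter intercepts, plus B-spline deviations
  of date around a linear trend — the mixed-model representation of a
  penalised spline (spline coefficients share one variance component, so
  the REML estimate of that variance is the smoothing parameter). The
  default basis uses 5 interior knots at date quantiles, cubic degree.
- **Estimation**: REML via `statsmodels` `MixedLM`, optimiser falling
  back lbfgs → powell → Nelder-Mead. A Bayesian multilevel fit with
  noninformative priors would return essentially the same posterior
  mean/SD; the REML point estimate and standard error are used as
  θ̂ᵖᵍᵁⱽ and ŝᵖᵍᵁⱽ. Variance components estimated at the zero
  boundary produce a warning, not an error.
- **Box–Cox**: values are transformed as (yᵏ−1)/λ (log for λ = 0) after
  a shift of 1 − min(y) when any value is nonpositive; λ defaults to 1
  (identity up to centring) and can be profiled by maximum likelihood on
  the wild-type animals. The λ-selection rule is a modelling choice, not
  forced by the data; it matters only for strongly skewed raw scales.
- **Preconditions**: at least 2 KO and 10 WT animals per fit; lines
  failing them are left missing.

### Quality control and scaling

Longitudinal artefacts (drifts in a centre's results over time that the
UV model did not absorb) are screened per centre × procedure block: the
block's line-level mean estimates are regressed on within-centre time
order with the Theil–Sen estimator, the slope standardised by a
bootstrap SE (200 resamples), and the block dropped when the
standardised slope exceeds 4 in magnitude. Blocks under 20 lines are
exempted and flagged "insufficient". The cut-off of 4 is deliberately
conservative — the statistic is approximately standard normal under no
drift, and only gross artefacts should be removed; it is configurable
because the underlying notion of "anomalous" is a judgment call.

Phenotypes observed in fewer than 500 lines (configurable) are dropped;
remaining estimates and SEs are divided by the sample SD of estimates
within each (phenotype, centre), so phenotypes are comparable across the
covariance model and z = θ̂/ŝ is unchanged. The operation is
idempotent.

### Multivariate model

With S_g = diag(ŝ·g) and observed-index restriction written `**`,

θ̂·g ~ N(θ·g, S_g R S_g),
p(θ·g) = Σ_{m=1..M} Σ_{s=1..S} π_ms N(0, ω_m Σ_s),
Σ_s = W_s W_sᵀ + Ψ_s.

The posterior given the observed subvector is the closed-form Gaussian
mixture with responsibilities proportional to the component evidences;
component means use the cross-covariance block Σ_s,·\*, which is what
imputes missing phenotypes. Validity at missing cells rests on the
missing-at-random assumption — reasonable when missingness comes from
centres systematically not running procedures, which is exactly what the
simulator emulates.

**Scale ladder.** ω defaults to the geometric grid 2⁻⁴ … 2⁴ (M = 9, the
`RunConfig` default; simulations in tests often use shorter ladders for
speed). A fixed multiscale ladder lets a single learned covariance shape
serve effects across two orders of magnitude while keeping the M-step
closed-form.

**EM.** The E-step computes responsibilities r_gms from the marginal
evidences (log-sum-exp, all solves via Cholesky of the restricted
covariance, lines batched by missingness pattern — with block-wise
missingness there are few distinct patterns, so the whole E-step is a
handful of batched P×P factorisations). The M-step updates
π_ms ∝ Σ_g r_gms and the weighted second-moment matrices

C_s = Σ_{g,m} r_gms (V_gms + μ_gms μ_gmsᵀ)/ω_m / Σ_{g,m} r_gms

with μ, V the full-P conditional moments, then re-fits each Σ_s in
factor form by minimising the Gaussian objective log|Σ| + tr(Σ⁻¹C_s)
over W_K = {WWᵀ + Ψ}. (The maximiser of that expression is unbounded;
the minimiser is the standard maximum-likelihood factor fit, and that is
what is implemented.) The inner factor-analysis EM is warm-started from
the previous (W, Ψ) — this, together with projecting the initial
covariance into W_K before the first E-step, is what guarantees a
monotone outer objective, which the code asserts every iteration.

**Initialisation.** Σ_s⁽⁰⁾ is the sample covariance of the zero-filled
training matrix (all training lines for S = 1; Gaussian-mixture
clusters with diagonal covariances and a k-means++ start, fixed seed,
for S > 1), plus 0.05·I whenever the smallest eigenvalue is not
strictly positive. A vanilla Inverse-Wishart(I, 2000) random
initialisation is provided for sensitivity checks; it is systematically
worse and not the default.

**Convergence.** tol = ε_tol · N_tra · MAD({l_g}), with ε_tol = 10⁻⁴ and
l_g the per-line log-likelihood contributions; iteration stops when the
objective changes by less than tol, capped at 1000 iterations. Whether
MAD should multiply or divide N_tra is ambiguous as a verbal rule; the
multiplicative form is the default and the alternative is a config
switch (`tol_scale_mode`). Floors: π_ms ≥ 10⁻¹², Ψ_jj ≥ 10⁻⁶ — pure
numerical guards against component collapse, not model features.

### Synthetic nulls and R

A synthetic null line resamples wild-type animals to match a template KO
line's litter structure: for each template litter (l animals, first day
d), an eligible WT litter (same centre, ≥ l animals, not yet used for
this null line) is drawn with probability ∝ 1/(1 + |Δday|) and l
animals taken from it without replacement. The decay weight implements
"closer in time is likelier" concretely; its scale is configurable.

R is the pairwise-complete correlation of null-line z-scores (z-scores
rather than raw estimates so heteroscedastic SEs cancel), with per-pair
complete-case counts recorded, entries with fewer than 5 complete cases
zeroed, and linear shrinkage toward the identity by the smallest
γ ∈ {0, 0.01, …} that makes the smallest eigenvalue ≥ 10⁻⁴ — block
missingness otherwise breaks positive definiteness. At least 30 null
lines are required.

### Error-rate control

z_pg = θ̂ᴹⱽ/ŝᴹⱽ. The threshold τ(α) is the smallest candidate (over
observed per-line max |z| values of KO ∪ null lines) at which the
estimated complete-null Fdr

Fdr̂_complete(τ) = P(H⁰) · (null exceedance fraction)/(KO exceedance
fraction)

drops to α, with P(H⁰) conservatively 1. Candidates with no KO
exceedance are skipped (selecting them would call nothing); if no
candidate qualifies, τ = +∞ and nothing is called. The single-test
variant Fdr̂_single is monitored, not controlled. A single global τ is
used by default (per-phenotype–centre thresholds are a possible
extension, not implemented as a default behaviour).

The local false sign rate lfsr_pg = min{P(θ ≥ 0 | data), P(θ ≤ 0 |
data)} is computed from the posterior mixture by component-wise normal
tails and can replace z in the calling criterion (calls then signed by
the posterior mean).

### Replicability and the false sign rate

For two conditionally independent call sets on the same (phenotype,
line) pairs, let q̂ be the discordant fraction among both-significant
pairs. Assuming false positives are sign-symmetric and the
double-false-discovery probability ψ is negligible (setting ψ = 0 makes
the estimator conservative, i.e. upward-biased),

q = 2·Fsr·(1 − Fsr)  ⟹  Fsr̂ = ½(1 − √(1 − 2q̂)).

The 95% CI maps Clopper–Pearson exact binomial bounds for q through the
same transform (an upper bound above ½ is truncated at Fsr = ½). The
interval construction can differ from other "exact binomial" variants
in the last digit; the point estimate is the reproducible quantity.

### Cross-validation and model averaging

KO and null lines are partitioned independently into C random
train/test splits (defaults C = 10, N_tra = 44% of lines at desk
scale); plans are resampled, with logged retries, until every line is a
test line at least once (a warning if the configuration makes that
impossible, e.g. C = 1). Hyperparameters are fitted per fold on KO
training lines; each line's final posterior model-averages its test
folds with weights ∝ exp(fold marginal log-likelihood of that line),
normalised in log space. The pooled covariance weights each fold's
collapsed covariance Σ̂⁽ᶜ⁾ = Σ π̂ ω Σ̂_s by the normalised exponential
of its summed test log-likelihood — by construction one fold typically
dominates when test sets are large; that is the formula's intended
behaviour, not a bug. The per-sample cross-validated log-likelihood
uses the full mixture marginal restricted to observed indices.

### Factor space

The correlation matrix underlying the pooled covariance is
eigendecomposed; the leading L (default 20) eigenvectors scaled by
√eigenvalue are varimax-rotated with Kaiser row normalisation (the
reference rotation's default), each factor rescaled so its largest
|loading| is 1, and signs flipped so a majority of significant factor
scores are positive. Factor scores are u_lg = λ_lᵀ·(posterior mean)
with SD √(λ_lᵀ V λ_l) — the square root is taken so z = u/s is
scale-correct — and score significance uses the same synthetic-null
threshold machinery as phenotype calls. Pairwise factor co-perturbation
is tested by Fisher's exact test (minimum-likelihood two-sided
convention, sample odds ratio) with Benjamini–Hochberg adjustment over
the L(L−1)/2 family; an infinite sample OR is reported as missing with
a flag.

## The simulator

`simulate_uv` draws exactly from the MV generative law: per line a
(m, s) component from π (complete-null lines get θ·g ≡ 0), θ·g from
N(0, ω_m Σ_s), lognormal standard errors (default log-mean log 0.3,
log-sd 0.3, on the unit-SD standardised scale — moderate per-cell
power, qualitatively the ~14-animals-per-line regime), noise with
covariance S R S, then block-wise masking by centre × procedure
(missing at random by construction). Defaults are P = 15, G = 400,
K = 5, M = 5, 50% complete-null lines. `simulate_animals` generates the
animal level: rolling WT baseline with sinusoidal drift, day/litter
random intercepts, sex effects, and design-matched KO cohorts.

What the simulator does **not** emulate: non-Gaussian measurement
scales (no Box–Cox misspecification stress), informative missingness,
centre-to-centre heterogeneity in the effect covariance, categorical
phenotypes, and real measurement units. Passing tests therefore
demonstrate internal correctness and calibration under the model's own
assumptions (plus MAR block missingness), not robustness to real-data
violations of them.

## Numerical choices

- All restricted-covariance solves go through Cholesky; failure names
  the offending (m, s) component.
- Log-sum-exp for all mixture weights and model-averaging weights.
- EM objective decrease beyond 10⁻⁶ relative is a hard error (bug
  guard); the factor-fit warm start is what makes the guard safe.
- Division-by-zero conventions: Fdr estimators return 0 with a flag
  when no KO line exceeds the threshold; a zero 2×2 margin reports an
  undefined odds ratio with p = 1.
- Serialization round-trips exactly (shortest-repr floats on write,
  round-trip parsing on read).

## Known limitations

- The UV stage is REML, not full Bayes; for very small cohorts the
  normal approximation to the posterior of θ_pg is optimistic in the
  tails.
- Null factor scores and null-line MV z statistics are mildly
  under-dispersed relative to standard normal (posterior shrinkage);
  this is conservative for calling, and the permutation threshold
  absorbs it, but parametric p-values computed from these z statistics
  would be miscalibrated — by design only permutation calibration is
  offered.
- The QC drift filter is a principled stand-in for what is, in
  practice, expert visual screening; its cut-off should be tuned per
  screen.
- With S > 1 the likelihood is multimodal and EM is
  initialisation-sensitive; the clustering-based initialisation
  mitigates but does not remove this.
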