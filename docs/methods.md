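# Methods

`ccmicrobiota` re-implements, as a tested library, the statistical pipeline
of a two-group, two-timepoint infant gut-microbiota cohort study: does
entry to center-based childcare (CC) at ~3 months shift the community,
relative to home care (HOME), once breastfeeding, birth mode, age and
siblings are accounted for? The original array data are not deposited, so
the package ships a synthetic-cohort generator that reproduces the study's
*statistical structure* and serves as the truth source for every
calibration and recovery test.

## The synthetic cohort

Compositions follow a logistic-normal model. For sample *s* of infant *j*,
taxon logits are

    l_s = a + u_j + Σ_c θ_c x_c(s) + ε_s,     p_s = softmax(l_s)

with base logits `a`, per-infant intercept vectors `u_j ~ N(0, σ_subj² I)`
(default σ_subj = 1.2), within-infant noise `ε_s ~ N(0, σ_noise² I)`
(default 0.8), and optional per-taxon covariate effect vectors θ_c. The
softmax closure makes covariate effects approximately additive on the clr
scale — exactly the scale on which the downstream linear models operate.

The base logits are calibrated so that the *population mean* of the
logistic-normal composition matches a target dominance profile: the
dominant Bifidobacterium-like group at 51% mean relative abundance, the
next four groups at 16.8%, 3.4%, 2.9% and 1.0%, and a geometric tail over
the remaining 125 groups. Because `E[softmax(a + σz)] ≠ softmax(a)`, the
calibration solves for `a` by iterative proportional fitting against a
fixed-seed Monte-Carlo estimate (20 000 draws, 15 iterations, cached per
configuration). With the default variances the dominant taxon's single-
sample range spans roughly 1%–99%, reproducing the "dominant yet highly
variable" regime; its across-seed mean stays within about ±1 percentage
point of 51%.

Covariates are drawn from the cohort's demographic profile: ages from
truncated normals per group × timepoint (CC infants slightly older, POST =
PRE + ~4 weeks), breastfeeding rates from truncated normals with the
PRE→POST rate a decayed, noisy copy of the birth→PRE rate, sibling and
C-section indicators as per-group Bernoullis, and weekly childcare
half-days from a discrete pmf with median 4 and IQR 3–4. Exactly 4 CC and
1 HOME infant have both breastfeeding fields blanked at both timepoints
(missing completely at random), matching the study's missingness pattern.

Optional `diversity_effects` impose *exact* additive Shannon shifts: after
composition generation, each affected sample's composition is
power-transformed (`p_i^γ / Σ p_k^γ`, γ solved by bisection) until its
Shannon index moves by the requested amount in nats. This gives recovery
tests a sharp ground truth instead of an approximate one.

What the generator does **not** emulate: probe-level array artefacts,
taxonomic correlation structure (taxa are exchangeable apart from their
means), antibiotic or illness events, and any real temporal dynamics
beyond the PRE/POST design. Passing calibration tests therefore shows the
*methods* behave correctly under the assumed data-generating process, not
that the original study's biological numbers are reproduced — its raw data
would be required for that.

## Compositional metrics

Signals are closed to relative abundance per sample; the clr transform is
`log(x + c)` minus its per-sample mean, with the pseudocount defaulting to
half the smallest positive entry when zeros are present (array-style
signals are strictly positive, so real inputs typically use c = 0).
Shannon diversity is in nats (natural log), richness counts features whose
signal strictly exceeds that feature's 80%-quantile across samples (a
constant feature is detected nowhere, making the rule well-defined), and
the coefficient of variation uses the sample (n−1) standard deviation.
Zero-mean taxa get an explicit `undefined` flag rather than a NaN.

## Redundancy analysis

RDA is computed from first principles: column-center the clr matrix,
(optionally) residualize response and predictors on conditioning
variables, take least-squares fitted values, and decompose inertia
(sums of squares / (n−1)) into constrained and residual parts;
`F = (constrained/df_x)/(residual/df_res)`. The implementation agrees with
the reference constrained-ordination implementation in R's vegan to eight
decimals on shared quantities (one test runs vegan via Rscript as an
independent oracle).

Significance uses permutation F-tests — full row permutation for simple
effects, reduced-model residual permutation for conditional effects, with
p = (1 + #{F* ≥ F}) / (1 + n_perm) and n_perm defaulting to 999. Because
each infant contributes two correlated samples, rows are **not**
exchangeable for infant-level predictors: free row permutation makes the
care-group term significant in essentially every null cohort. When subject
labels are supplied the test therefore permutes whole infants against each
other and independently swaps the two rows within each infant, which
restores the nominal error rate at both levels of the design. This is a
deliberate deviation from naive row permutation and the package's default
for the cohort analysis.

Variance partitioning fits an RDA for every nonempty subset of 2–4
column-disjoint predictor blocks and solves the linear system
`R²(S) = Σ_{cells touching S} f_cell` for the exclusive Venn fractions;
small negative uniques are reported, not clipped. Raw R² is reported by
default; Ezekiel-adjusted R² is available (`adjusted=True`) since
classical variance-partitioning software adjusts. Triplot scores
(site/species/biplot, correlation scaling) are exported numerically;
rendering is out of scope.

## PMM multiple imputation

Breastfeeding is imputed by type-1 predictive mean matching: regress the
incomplete variable on complete covariates over observed cases; draw σ²
from its scaled inverse-χ² posterior and β from the corresponding normal;
predict missing cases with the drawn β and observed cases with the
least-squares β; copy the observed value of one of the k = 5 nearest
donors (uniformly at random). The two breastfeeding variables are imputed
jointly by chained sweeps (5 iterations), each serving as a predictor for
the other, producing m = 10 completed datasets by default with a donor
audit log. Imputed values are by construction members of the observed
multiset; an all-constant observed target therefore imputes that constant
(the degenerate regression is handled, not rejected).

## The robust hierarchical model

Each outcome y (clr abundance of one taxon, or Shannon diversity) follows

    y_i ~ Student-t(ν, μ_i, σ_i)
    μ_i = β₀ + u_{j(i)} + β·(CC, time, CC×time, age, bf, sib, csec, sib×csec)
    log σ_i = γ₀ + γ·(CC, time, CC×time, sib, csec, sib×csec)

with per-infant deviations u_j ~ N(0, τ) and ν > 1. The structural
equation for σ is linear on the log scale: an unconstrained linear σ can
go negative, so the log link is the default and a literal linear link
(with rejection of nonpositive σ) is available behind
`RobustModelSpec(sigma_link="linear")`. Age and breastfeeding are centered
and scaled to unit SD so that the Normal(0, 1) prior placed on every
comparison coefficient means the same thing across outcomes — this prior
is the conservative element that pulls credible intervals toward zero.
Intercepts get wide Student-t(3) priors centered on robust data summaries
(median; log of 1.4826·MAD for log σ), τ a half-Student-t(3, 0, 2.5·MAD),
and ν − 1 a Gamma(2, 0.1). Breastfeeding enters as the period-appropriate
time-varying covariate by default; a two-column (both periods) variant is
a config option. `listwise_delete` provides the complete-case sensitivity
alternative to imputation (drop infants whose breastfeeding data are
missing and fit on the rest).

### Sampling

The posterior is sampled by a partially-collapsed Gibbs sampler built
around the normal scale-mixture representation of the t distribution
(y_i | λ_i ~ N(μ_i, σ_i²/λ_i), λ_i ~ Gamma(ν/2, ν/2)):

1. ν is updated by univariate slice sampling against the *marginal*
   Student-t likelihood (weights integrated out);
2. weights λ are refreshed from their exact Gamma conditionals;
3. the σ-coefficients and log τ are slice-sampled against the
   *subject-collapsed* conditional — the subject deviations integrate out
   in closed form, each infant contributing a 2×2 Gaussian block — which
   breaks the classic slow coupling between u, τ and the residual scale;
   γ moves along the eigendirections of (Xσ'Xσ)⁻¹ to undo the
   treatment-coding correlation;
4. the Student-t prior on the μ-intercept is expanded with its own Gamma
   mixture variable; then (β, u) is drawn jointly from its exact
   multivariate-Gaussian conditional.

Each of n_chains (default 4) independent chains feeds a split-rhat
diagnostic (via arviz); any structural parameter above 1.05 triggers a
logged warning and a `converged=False` flag — never a silent pass.
Divergence counts are a gradient-sampler concept and are reported as 0.
An affine-invariant ensemble sampler (emcee) over the identical
log-posterior is kept as an independent cross-check backend; a test
verifies both backends agree on a small instance. The log posterior itself
is verified against a hand-built scipy-density evaluation to 1e-6.

Default chains are 4 × (400 warmup + 600 kept) sweeps; calibration suites
use 2 × (150 + 250), which the recovery experiments show is already
unbiased with ~98% interval coverage at the cohort's size.

### Decision rule, pooling, prediction

A contrast is *flagged* exactly when its central 95% posterior interval
excludes zero — the flag is a pure function of the interval. The default
contrast set covers within-group temporal and between-group cell
differences of the mean, covariate slopes, and the same cell differences
of σ (evaluated at sibling = no, C-section = no; on the natural σ scale
via the log link). Multiple-imputation pooling concatenates posterior
draws across per-imputation fits (a mixture of posteriors), keeping
per-fit diagnostics and the elementwise-maximum rhat. Posterior predictive
intervals per group × timepoint cell are computed at the median age of
that timepoint, the overall median breastfeeding rate and the modal
sibling/birth-mode categories, drawing a fresh subject deviation per
posterior draw so the interval describes a new infant.

## Random-Forest classification

POST-sample relative abundances are classified CC vs HOME by a Random
Forest under repeated stratified k-fold cross-validation (default 10 folds
× 10 repeats, 500 trees, √p features per split — the conventional
defaults; stratification is the natural choice for the balanced 49/49
design). Per-repeat accuracy pools that repeat's held-out predictions;
the summary is the mean over repeats. A leakage canary test verifies that
fold-local label information cannot raise accuracy.

## Pipeline

`run_full_analysis` chains all stages into one run directory with a JSON
manifest (master seed, per-stage seeds spawned from named substreams,
config hash, package versions). Stages are cached by config hash so the
expensive Bayesian stage is not recomputed when, say, only the RF settings
change; by default the Bayesian stage fits Shannon plus the five most
abundant taxa (the full per-taxon sweep is available but costs
m × n_taxa MCMC fits). The descriptives table mirrors the usual cohort
Table-1 layout: Welch t-tests for continuous variables (zero-variance and
too-few-observation comparisons flagged explicitly), χ² tests for
categorical ones.

## Problem sizes used by the shipped test suites

Structural checks run on the default 49+49 × 130-taxon cohort. The
Shannon recovery/coverage experiment uses 100 simulated cohorts at full
size with reduced chains (2 × 400 sweeps). The null-calibration suite uses
20-taxon, 24-infants-per-group cohorts for the 200 per-taxon Bayesian fits
(the false-flag rate of an interval decision rule does not depend on n),
full-size cohorts for the RDA calibration (50 seeds, 199 permutations) and
the RF chance-level check (reduced to 3 repeats × 100 trees). These sizes
are the package's own test design; all library defaults remain at the
full study scale.

## Known limitations

- Taxa are generated independently given their means; real communities
  have correlation structure (shared niches, phylogeny) that RDA would
  partially absorb.
- The σ regression omits age and breastfeeding (as in the modeled design);
  heteroscedasticity along continuous covariates is not captured.
- The subject-collapsed Gibbs updates assume exactly two samples per
  infant — the design this package models; unbalanced designs would need
  the general block form.
- The ensemble backend is only practical at small subject counts; it
  exists as a cross-check, not an alternative for full cohorts.
- `inject_missingness` is MCAR only; missing-not-at-random sensitivity
  analyses are out of scope.
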