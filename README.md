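# ccmicrobiota

Statistical toolkit for a question in early-life microbiome research: does
entry to center-based childcare (CC) at around three months of age shift
the infant gut microbiota, compared to being cared for at home (HOME)?
The package implements the complete analysis for a two-group, two-
timepoint cohort design (a PRE stool sample before the childcare-entry
window and a POST sample four weeks later), for researchers analysing
their own abundance tables or studying the statistical behaviour of the
methods themselves.

The pipeline combines:

- **Compositional preprocessing** — closure to relative abundance, the
  centered-log-ratio transform `clr(x)_i = log x_i − mean(log x)`,
  Shannon diversity `H = −Σ p_i log p_i`, detection-threshold richness
  and per-taxon coefficients of variation.
- **Redundancy analysis (RDA)** — constrained ordination of the clr
  matrix on breastfeeding, birth mode, age, siblings and the childcare
  terms, with simple and conditional (partialled) effects, subject-aware
  permutation F-tests and a Venn partition of explained variance.
- **Predictive-mean-matching multiple imputation** for the infants whose
  breastfeeding diaries are missing entirely.
- **A Bayesian hierarchical robust model** per outcome (each taxon's clr
  abundance, and Shannon diversity):

      y_i ~ Student-t(ν, μ_i, σ_i)
      μ_i = β₀ + u_j[i] + β₁CC + β₂time + β₃CC×time + β₄age + β₅bf
            + β₆sib + β₇csec + β₈sib×csec
      log σ_i = γ₀ + γ₁CC + γ₂time + γ₃CC×time + γ₄sib + γ₅csec + γ₆sib×csec

  with per-infant intercepts u_j ~ N(0, τ), a Normal(0, 1) prior on every
  comparison coefficient, pooling over the imputed datasets, and the
  decision rule "flag an effect iff the central 95% credible interval
  excludes zero".
- **Random-Forest classification** of CC vs HOME from POST composition
  under repeated stratified 10×10 cross-validation.

Because no raw data from such cohorts are bundled, the package includes a
first-class **synthetic cohort generator** (logistic-normal compositions,
49+49 infants, 130 genus-like groups, a Bifidobacterium-like taxon
calibrated to 51% mean relative abundance, realistic covariates and the
4-CC/1-HOME missing-breastfeeding pattern) that serves both as a demo
input and as the ground-truth source for the calibration and recovery
tests. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from ccmicrobiota import (CohortConfig, generate_cohort, shannon_diversity,
                          pmm_impute, fit_diversity)

cfg = CohortConfig(seed=1, diversity_effects={"cc_x_time": -0.22})
table, metadata, truth = generate_cohort(cfg)
H = shannon_diversity(table)
imputations = pmm_impute(metadata, m=5, seed=3)
summary, predictive, draws = fit_diversity(
    H, imputations, n_chains=2, n_warmup=300, n_steps=500, seed=4)
```

The generated cohort prints (`examples/01_generate_cohort.py`):

```
samples: 196, taxa: 130, infants: 98
dominant taxon (Bifidobacterium_like): mean 52.7%, range 0.6% - 99.0%
five most abundant taxa together: 74.3%
infants with missing breastfeeding data: ['CC001', 'CC011', 'CC015', 'CC029', 'HM003']
median childcare half-days/week: 4
```

and the diversity model (`examples/05_bayes_shannon.py`) reports group
contrasts such as

```
CC PRE - HOME PRE                +0.022 [-0.368, +0.403]  (mean)
CC POST - HOME POST              -0.157 [-0.539, +0.229]  (mean)
max rhat: 1.021 (converged: True)
```

Here a −0.22 nat diversity drop was injected for CC infants at POST; the
posterior median of the CC POST − HOME POST contrast sits near that truth,
and the wide interval (this is a single cohort of 98 infants) illustrates
why the decision rule stays conservative. Each `examples/` script is a
short narrative of one capability: generation, metrics, RDA, imputation,
the Bayesian fits, Random Forest, and the end-to-end pipeline with its
run-directory outputs (`table2.csv`, `partition.csv`, `contrasts.csv`,
`cv.json`, `manifest.json`).

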