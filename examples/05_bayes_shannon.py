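"""Robust hierarchical Bayesian model for Shannon diversity.

Fits the Student-t distributional-regression model (mean and SD both
depend on covariates, per-infant intercepts, heavy-tailed likelihood) to
Shannon diversity, pooling across the multiply-imputed breastfeeding
datasets, and prints the group contrasts with the 95%-interval decision
rule and posterior predictive intervals.
"""

from ccmicrobiota import (
    CohortConfig,
    fit_diversity,
    generate_cohort,
    pmm_impute,
    shannon_diversity,
)

# generate a cohort with a -0.22 nat diversity drop in CC infants at POST
cfg = CohortConfig(seed=1, diversity_effects={"cc_x_time": -0.22})
table, metadata, truth = generate_cohort(cfg)
H = shannon_diversity(table)
imputations = pmm_impute(metadata, m=5, seed=3)

summary, predictive, pooled = fit_diversity(
    H, imputations, n_chains=2, n_warmup=300, n_steps=500, seed=4
)
print("contrast summaries (median [95% CI], * = interval excludes 0):")
for _, row in summary.iterrows():
    star = "*" if row.flagged else " "
    print(f"  {star} {row.contrast:32s} {row['median']:+.3f} "
          f"[{row.ci_lower:+.3f}, {row.ci_upper:+.3f}]  ({row.scope})")
print(f"\nmax rhat: {summary.max_rhat.iloc[0]:.3f} "
      f"(converged: {bool(summary.converged.iloc[0])})")
print("\nposterior predictive intervals at median age/breastfeeding:")
print(predictive.round(3).to_string(index=False))

# The CC POST - HOME POST contrast should sit near the injected -0.22
# truth; contrasts whose intervals include zero are left unflagged — the
# conservative Normal(0,1) prior on comparisons shrinks spurious effects.
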