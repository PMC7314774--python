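"""Robust hierarchical t model: design coding, likelihood, sampling,
contrasts, pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccmicrobiota import (
    CohortConfig,
    build_design,
    clr_transform,
    contrast_summaries,
    fit_all_taxa,
    fit_diversity,
    generate_cohort,
    pool_imputations,
    sample_posterior,
    shannon_diversity,
    to_relative_abundance,
)
from ccmicrobiota.bayes import (
    Contrast,
    ContrastSummary,
    RobustModelSpec,
    RobustTModel,
    default_contrasts,
)


def scipy_log_posterior(theta, model):
    """Independent oracle for the model's log posterior, written entirely
    with scipy.stats densities."""
    p_mu, p_s = model.p_mu, model.p_sigma
    beta = theta[:p_mu]
    gamma = theta[p_mu : p_mu + p_s]
    log_tau = theta[p_mu + p_s]
    eta = theta[p_mu + p_s + 1]
    u = theta[p_mu + p_s + 2 :]
    tau = np.exp(log_tau)
    nu = 1.0 + np.exp(eta)
    mu = model.Xmu @ beta + u[model.subject_index]
    sigma = np.exp(np.clip(model.Xs @ gamma, -30, 30))
    ll = stats.t.logpdf(model.y, df=nu, loc=mu, scale=sigma).sum()
    lp = stats.t.logpdf(beta[0], 3, loc=model.y_median,
                        scale=model.mu_intercept_scale)
    lp += stats.norm.logpdf(beta[1:]).sum()
    lp += stats.t.logpdf(gamma[0], 3, loc=model.sigma_intercept_loc,
                         scale=model.sigma_intercept_scale)
    lp += stats.norm.logpdf(gamma[1:]).sum()
    lp += np.log(2) + stats.t.logpdf(tau, 3, 0, model.tau_scale) + log_tau
    lp += stats.gamma.logpdf(nu - 1.0, a=2.0, scale=10.0) + eta
    lp += stats.norm.logpdf(u, 0, tau).sum()
    return ll + lp


@pytest.fixture(scope="module")
def shannon_case():
    cfg = CohortConfig(seed=21, n_per_group=10, n_taxa=12,
                       bf_missing_cc=0, bf_missing_home=0)
    table, md, _ = generate_cohort(cfg)
    H = shannon_diversity(table)
    y = H.loc[md.data["sample_id"]].to_numpy()
    return y, md


class TestDesign:
    def test_mu_row_coding(self, tiny_meta):
        d = build_design(tiny_meta)
        row = d.x_mu.loc["I0_POST"]
        assert row["cc"] == 1 and row["time"] == 1 and row["cc_x_time"] == 1
        assert row["sib"] == 1 and row["csec"] == 0 and row["sib_x_csec"] == 0
        assert d.x_mu.loc["I2_PRE", "cc"] == 0

    def test_age_centered(self, tiny_meta):
        d = build_design(tiny_meta)
        assert abs(d.x_mu["age"].mean()) < 1e-10
        assert d.x_mu["age"].std(ddof=0) == pytest.approx(1.0)

    def test_sigma_design_has_seven_columns(self, tiny_meta):
        d = build_design(tiny_meta)
        assert d.x_sigma.shape[1] == 7
        assert list(d.x_sigma.columns)[0] == "intercept"

    def test_two_period_bf_mode_adds_column(self, tiny_meta):
        d = build_design(tiny_meta, RobustModelSpec(bf_mode="two_period"))
        assert {"bf_before", "bf_during"} <= set(d.x_mu.columns)

    def test_missing_bf_directed_to_imputation(self, small_cohort):
        _, md, _ = small_cohort
        with pytest.raises(ValueError, match="impute"):
            build_design(md)

    def test_listwise_deletion_enables_complete_case_fit(self, small_cohort):
        from ccmicrobiota import listwise_delete

        _, md, _ = small_cohort
        sub = listwise_delete(md)
        assert sub.n_infants == md.n_infants - len(md.bf_missing_infants())
        d = build_design(sub)  # no longer raises
        assert d.x_mu.shape[0] == 2 * sub.n_infants


class TestLogPosterior:
    def test_matches_scipy_oracle(self, shannon_case):
        y, md = shannon_case
        model = RobustTModel(y, build_design(md))
        rng = np.random.default_rng(17)
        theta0 = model.initial_point()
        for _ in range(20):
            theta = theta0 + 0.5 * rng.standard_normal(model.n_params)
            ours = model.log_posterior(theta)
            oracle = scipy_log_posterior(theta, model)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_vectorized_matches_single(self, shannon_case):
        y, md = shannon_case
        model = RobustTModel(y, build_design(md))
        rng = np.random.default_rng(4)
        pts = model.initial_point()[None, :] + 0.3 * rng.standard_normal(
            (6, model.n_params)
        )
        batch = model.log_posterior(pts)
        singles = np.array([model.log_posterior(p) for p in pts])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)


class TestSampler:
    def test_deterministic_under_seed(self, shannon_case):
        y, md = shannon_case
        d = build_design(md)
        a = sample_posterior(y, d, n_chains=2, n_warmup=50, n_steps=50, seed=3)
        b = sample_posterior(y, d, n_chains=2, n_warmup=50, n_steps=50, seed=3)
        assert np.array_equal(a.draws.values, b.draws.values)

    def test_slope_recovery_from_simulated_data(self):
        """A strong simulated slope is recovered by the posterior."""
        rng = np.random.default_rng(5)
        cfg = CohortConfig(seed=31, n_per_group=25, n_taxa=8,
                           bf_missing_cc=0, bf_missing_home=0)
        _, md, _ = generate_cohort(cfg)
        d = build_design(md)
        x = d.x_mu["bf"].to_numpy()
        subj = d.subject_index
        u_true = 0.3 * rng.standard_normal(len(d.subject_ids))
        y = 0.8 * x + u_true[subj] + 0.3 * rng.standard_normal(len(x))
        draws = sample_posterior(y, d, n_chains=2, n_warmup=200, n_steps=300, seed=6)
        med = draws.draws["b_bf"].median()
        assert med == pytest.approx(0.8, abs=0.15)

    def test_heteroscedasticity_recovery(self):
        """A doubled SD in the CC group shows up in the sigma model."""
        rng = np.random.default_rng(8)
        cfg = CohortConfig(seed=33, n_per_group=30, n_taxa=8,
                           bf_missing_cc=0, bf_missing_home=0)
        _, md, _ = generate_cohort(cfg)
        d = build_design(md)
        cc = d.x_mu["cc"].to_numpy()
        sigma = np.where(cc == 1, 0.8, 0.4)
        y = sigma * rng.standard_normal(len(cc))
        draws = sample_posterior(y, d, n_chains=2, n_warmup=200, n_steps=300, seed=7)
        # posterior of the log-sigma CC coefficient should be near log(2)
        med = draws.draws["g_cc"].median()
        assert med == pytest.approx(np.log(2.0), abs=0.25 * np.log(2.0) + 0.1)

    def test_robustness_to_gross_outliers(self):
        """Slope estimates barely move when 5% gross outliers are added."""
        rng = np.random.default_rng(9)
        cfg = CohortConfig(seed=35, n_per_group=25, n_taxa=8,
                           bf_missing_cc=0, bf_missing_home=0)
        _, md, _ = generate_cohort(cfg)
        d = build_design(md)
        x = d.x_mu["age"].to_numpy()
        y_clean = 0.5 * x + 0.3 * rng.standard_t(3, len(x))
        y_out = y_clean.copy()
        idx = rng.choice(len(x), size=max(2, len(x) // 20), replace=False)
        y_out[idx] += rng.choice([-6.0, 6.0], size=idx.size)
        kw = dict(n_chains=2, n_warmup=200, n_steps=300)
        m_clean = sample_posterior(y_clean, d, seed=1, **kw).draws["b_age"].median()
        m_out = sample_posterior(y_out, d, seed=1, **kw).draws["b_age"].median()
        # ordinary least squares shifts more under the same contamination
        X1 = np.column_stack([np.ones_like(x), x])
        ols_clean = np.linalg.lstsq(X1, y_clean, rcond=None)[0][1]
        ols_out = np.linalg.lstsq(X1, y_out, rcond=None)[0][1]
        assert abs(m_out - m_clean) < 0.1
        assert abs(m_out - m_clean) < abs(ols_out - ols_clean)

    def test_gibbs_and_ensemble_backends_agree(self):
        """Both samplers target the same posterior on a small instance."""
        cfg = CohortConfig(seed=3, n_per_group=6, n_taxa=10,
                           bf_missing_cc=0, bf_missing_home=0)
        table, md, _ = generate_cohort(cfg)
        y = shannon_diversity(table).loc[md.data["sample_id"]].to_numpy()
        d = build_design(md)
        dg = sample_posterior(y, d, n_chains=2, n_warmup=300, n_steps=1500, seed=5)
        de = sample_posterior(
            y, d, n_chains=2, n_warmup=2500, n_steps=2500, thin=10,
            method="ensemble", seed=9,
        )
        struct = [p for p in dg.param_names if not p.startswith("u_")]
        for p in struct:
            sd = dg.draws[p].std()
            assert abs(dg.draws[p].mean() - de.draws[p].mean()) < 0.45 * sd
            assert de.draws[p].std() == pytest.approx(sd, rel=0.5)

    def test_unknown_method_rejected(self, shannon_case):
        y, md = shannon_case
        with pytest.raises(ValueError, match="method"):
            sample_posterior(y, build_design(md), method="nuts")


class TestContrasts:
    def _fake_draws(self, **cols):
        from ccmicrobiota.bayes import PosteriorDraws

        df = pd.DataFrame(cols)
        return PosteriorDraws(
            draws=df,
            chain_ids=np.zeros(len(df), dtype=int),
            rhat=pd.Series(1.0, index=df.columns),
            n_divergent=0,
            seed=0,
            converged=True,
            meta={"sigma_link": "log"},
        )

    def test_flag_iff_interval_excludes_zero(self):
        rng = np.random.default_rng(0)
        neg = rng.normal(-0.22, 0.05, 4000)        # interval below zero
        span = rng.normal(0.005, 0.09, 4000)       # interval straddles zero
        draws = self._fake_draws(b_cc=neg, b_cc_x_time=np.zeros(4000), b_x=span)
        cs = contrast_summaries(
            draws,
            [
                Contrast("below", "mean", {"b_cc": 1.0}),
                Contrast("straddle", "mean", {"b_x": 1.0}),
            ],
        )
        assert cs[0].flagged and cs[0].ci95[1] < 0
        assert not cs[1].flagged

    def test_null_contrast_is_zero_and_unflagged(self):
        rng = np.random.default_rng(1)
        draws = self._fake_draws(b_cc=rng.normal(0.4, 0.1, 1000))
        cs = contrast_summaries(
            draws, [Contrast("null", "mean", {"b_cc": 0.0})]
        )
        assert cs[0].median == 0.0 and not cs[0].flagged

    def test_missing_parameter_rejected(self):
        draws = self._fake_draws(b_cc=np.zeros(10))
        with pytest.raises(KeyError, match="b_zzz"):
            contrast_summaries(draws, [Contrast("bad", "mean", {"b_zzz": 1.0})])

    def test_default_contrast_set_layout(self):
        names = [c.name for c in default_contrasts()]
        assert "CC POST - HOME POST" in names
        assert "CC POST - HOME POST (SD)" in names
        assert "Breastfeeding" in names
        scopes = {c.name: c.scope for c in default_contrasts()}
        assert scopes["Age"] == "slope"
        assert scopes["CC PRE - HOME PRE (SD)"] == "sd"

    def test_flag_is_pure_function_of_interval(self):
        s = ContrastSummary("x", 0.1, (0.01, 0.3), True, "mean")
        assert s.flagged == (s.ci95[0] > 0 or s.ci95[1] < 0)


class TestPooling:
    def test_pooled_draw_count(self, shannon_case):
        y, md = shannon_case
        d = build_design(md)
        fits = [
            sample_posterior(y, d, n_chains=1, n_warmup=50, n_steps=100, seed=s)
            for s in range(3)
        ]
        pooled = pool_imputations(fits)
        assert pooled.n_draws == sum(f.n_draws for f in fits)

    def test_degenerate_pooling_matches_single_fit(self, shannon_case):
        y, md = shannon_case
        d = build_design(md)
        fit = sample_posterior(y, d, n_chains=2, n_warmup=100, n_steps=200, seed=2)
        pooled = pool_imputations([fit, fit])
        a = contrast_summaries(fit)[0]
        b = contrast_summaries(pooled)[0]
        assert a.median == pytest.approx(b.median, abs=1e-9)

    def test_mismatched_parameters_rejected(self, shannon_case):
        y, md = shannon_case
        d = build_design(md)
        fit = sample_posterior(y, d, n_chains=1, n_warmup=30, n_steps=30, seed=0)
        other = sample_posterior(
            y, build_design(md, RobustModelSpec(bf_mode="two_period")),
            RobustModelSpec(bf_mode="two_period"),
            n_chains=1, n_warmup=30, n_steps=30, seed=0,
        )
        with pytest.raises(ValueError, match="differ"):
            pool_imputations([fit, other])


class TestOutcomeTables:
    def test_single_taxon_gives_one_block_of_rows(self, small_complete_cohort):
        table, md, _ = small_complete_cohort
        clr = clr_transform(to_relative_abundance(table))
        out = fit_all_taxa(
            clr, md, taxa=1, n_chains=1, n_warmup=60, n_steps=80, seed=0
        )
        assert out["taxon"].nunique() == 1
        assert set(out["contrast"]) == {c.name for c in default_contrasts()}

    def test_diversity_fit_outputs(self, small_complete_cohort):
        table, md, _ = small_complete_cohort
        H = shannon_diversity(table)
        summ, predictive, pooled = fit_diversity(
            H, md, n_chains=2, n_warmup=80, n_steps=120, seed=1
        )
        assert len(predictive) == 4
        assert {"group", "timepoint", "pred_lower", "pred_upper"} <= set(
            predictive.columns
        )
        assert (predictive["pred_upper"] > predictive["pred_lower"]).all()
        med = summ.set_index("contrast")["median"]
        lo = summ.set_index("contrast")["ci_lower"]
        hi = summ.set_index("contrast")["ci_upper"]
        assert ((lo <= med) & (med <= hi)).all()

    def test_predictive_interval_covers_new_observations(self):
        """~95% of fresh samples at a covariate profile fall inside the
        posterior predictive interval."""
        cfg = CohortConfig(seed=41, n_per_group=25, n_taxa=40,
                           bf_missing_cc=0, bf_missing_home=0)
        table, md, _ = generate_cohort(cfg)
        H = shannon_diversity(table)
        summ, predictive, pooled = fit_diversity(
            H, md, n_chains=2, n_warmup=150, n_steps=250, seed=2
        )
        # fresh cohorts from the same generator act as new observations
        fresh = []
        for s in range(4):
            t2, m2, _ = generate_cohort(
                CohortConfig(seed=900 + s, n_per_group=25, n_taxa=40,
                             bf_missing_cc=0, bf_missing_home=0)
            )
            H2 = shannon_diversity(t2)
            df2 = m2.data.set_index("sample_id")
            fresh.append(pd.DataFrame({"H": H2, "group": df2["group"],
                                       "timepoint": df2["timepoint"]}))
        fresh = pd.concat(fresh)
        rates = []
        for _, row in predictive.iterrows():
            sub = fresh[(fresh.group == row.group) & (fresh.timepoint == row.timepoint)]
            inside = (sub.H >= row.pred_lower) & (sub.H <= row.pred_upper)
            rates.append(inside.mean())
        assert np.mean(rates) == pytest.approx(0.95, abs=0.06)
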