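"""Redundancy analysis: oracles, permutation behavior, variance partition."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from ccmicrobiota import (
    default_blocks,
    effects_table,
    fit_rda,
    permutation_test,
    variance_partition,
)
from ccmicrobiota.rda import adjusted_r2, covariate_frame


def _random_case(seed, n=12, k=4, p=2):
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((n, k))
    X = rng.standard_normal((n, p))
    return Y, X


def brute_force_r2_f(Y, X):
    """Independent oracle: centered least squares + explicit sums of squares."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    Xd = np.hstack([np.ones((len(Y), 1)), Xc])
    B, *_ = np.linalg.lstsq(Xd, Yc, rcond=None)
    fitted = Xd @ B
    ss_fit = np.sum(fitted**2)
    ss_tot = np.sum(Yc**2)
    ss_res = ss_tot - ss_fit
    df_x = X.shape[1]
    df_res = len(Y) - 1 - df_x
    return ss_fit / ss_tot, (ss_fit / df_x) / (ss_res / df_res)


class TestFitOracle:
    def test_self_explanation_r2_one(self):
        Y, _ = _random_case(0)
        res = fit_rda(Y[:, :1], Y[:, :1])
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor_zero_inertia(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((20, 3))
        Yc = Y - Y.mean(axis=0)
        x = rng.standard_normal(20)
        xc = x - x.mean()
        # project out every response column to force orthogonality
        coef, *_ = np.linalg.lstsq(Yc, xc, rcond=None)
        x_orth = xc - Yc @ coef
        res = fit_rda(Y, x_orth[:, None])
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        Y, X = _random_case(seed)
        res = fit_rda(Y, X)
        r2, f = brute_force_r2_f(Y, X)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.f_stat == pytest.approx(f, abs=1e-10)
        assert res.total_inertia == pytest.approx(
            res.constrained_inertia + res.residual_inertia, rel=1e-10
        )

    def test_binary_predictor_equals_group_means_fit(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((12, 4))
        g = np.repeat([0.0, 1.0], 6)
        res = fit_rda(Y, g[:, None])
        Yc = Y - Y.mean(axis=0)
        fitted = np.where(g[:, None] == 1, Yc[g == 1].mean(axis=0), Yc[g == 0].mean(axis=0))
        r2 = np.sum(fitted**2) / np.sum(Yc**2)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_single_response_reduces_to_ols_r2(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 3))
        res = fit_rda(y[:, None], X)
        Xd = np.hstack([np.ones((30, 1)), X - X.mean(axis=0)])
        beta, *_ = np.linalg.lstsq(Xd, y - y.mean(), rcond=None)
        resid = (y - y.mean()) - Xd @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        Y, X = _random_case(2)
        Xdup = np.hstack([X, X[:, :1]])
        with pytest.raises(ValueError, match="x2"):
            fit_rda(Y, Xdup)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestVeganCrossCheck:
    def test_simple_and_partial_match_vegan(self, tmp_path):
        rng = np.random.default_rng(42)
        Y = rng.standard_normal((20, 6))
        X = pd.DataFrame({"a": rng.standard_normal(20),
                          "b": (rng.random(20) < 0.5).astype(float)})
        Z = pd.DataFrame({"c": rng.standard_normal(20)})
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        X.to_csv(tmp_path / "X.csv", index=False)
        Z.to_csv(tmp_path / "Z.csv", index=False)
        script = f"""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
        X <- read.csv("{tmp_path}/X.csv"); Z <- read.csv("{tmp_path}/Z.csv")
        m <- rda(Y ~ a + b, data=X)
        d <- cbind(X, Z)
        mp <- rda(Y ~ a + b + Condition(c), data=d)
        cat(sprintf("%.12f", c(m$tot.chi, m$CCA$tot.chi, mp$CCA$tot.chi)), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True,
            check=True,
        )
        tot_r, constr_r, partial_r = map(float, out.stdout.split())
        res = fit_rda(Y, X)
        resp = fit_rda(Y, X, Z)
        assert res.total_inertia == pytest.approx(tot_r, rel=1e-8)
        assert res.constrained_inertia == pytest.approx(constr_r, rel=1e-8)
        assert resp.constrained_inertia == pytest.approx(partial_r, rel=1e-8)


class TestPermutation:
    def test_maximal_evidence_hits_p_floor(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 1))
        Y = np.hstack([X * 2.0, X * -1.0])
        _, p = permutation_test(Y, X, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_same_seed_reproducible(self):
        Y, X = _random_case(3, n=20)
        r1 = permutation_test(Y, X, n_perm=99, seed=7)
        r2 = permutation_test(Y, X, n_perm=99, seed=7)
        assert r1 == r2

    def test_nperm_validation(self):
        Y, X = _random_case(3)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(Y, X, n_perm=0)

    def test_null_rejection_rate_is_nominal(self):
        """Under independence, rejection at 0.05 happens 5% of the time."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 400
        for rep in range(n_rep):
            Y = rng.standard_normal((24, 4))
            X = rng.standard_normal((24, 1))
            _, p = permutation_test(Y, X, n_perm=999, seed=rep)
            rejections += p <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_block_permutation_calibrates_subject_level_predictor(self):
        """Free permutation is anti-conservative for a subject-level
        predictor under repeated measures; block permutation is not."""
        rng = np.random.default_rng(2)
        n_subj = 30
        p_block = []
        for rep in range(25):
            subj_eff = rng.standard_normal((n_subj, 3))
            Y = np.repeat(subj_eff, 2, axis=0) + 0.3 * rng.standard_normal((2 * n_subj, 3))
            cc = np.repeat(rng.random(n_subj) < 0.5, 2).astype(float)
            blocks = np.repeat(np.arange(n_subj), 2)
            _, pb = permutation_test(Y, cc[:, None], n_perm=199, seed=rep, blocks=blocks)
            p_block.append(pb)
        assert np.mean(np.array(p_block) <= 0.05) <= 0.2
        assert np.mean(p_block) > 0.3


class TestEffectsTable:
    def test_single_block_simple_equals_conditional(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((16, 3))
        cov = pd.DataFrame({"x": rng.standard_normal(16)})
        tab = effects_table(Y, cov, blocks={"X": ["x"]}, n_perm=49, seed=0)
        simple = tab[tab["mode"] == "simple"].iloc[0]
        cond = tab[tab["mode"] == "conditional"].iloc[0]
        assert simple["F"] == pytest.approx(cond["F"])
        assert simple["r2"] == pytest.approx(cond["r2"])

    def test_default_layout_on_cohort(self, default_cohort):
        table, md, _ = default_cohort
        from ccmicrobiota import clr_transform, to_relative_abundance

        clr = clr_transform(to_relative_abundance(table))
        covs = covariate_frame(md)
        tab = effects_table(
            clr, covs, n_perm=49, seed=0,
            subjects=md.data["infant_id"].to_numpy(),
        )
        assert set(tab["effect"]) == set(default_blocks())
        bf = tab[(tab.effect == "Breastfeeding") & (tab["mode"] == "simple")]
        assert bf["df"].iloc[0] == 2
        cct = tab[(tab.effect == "CC x Time") & (tab["mode"] == "simple")]
        assert cct["df"].iloc[0] == 3
        # complete cases only: 93 infants x 2 samples
        assert (tab["p"] > 0).all() and (tab["p"] <= 1).all()

    def test_recovers_strong_breastfeeding_effect(self):
        from ccmicrobiota import CohortConfig, clr_transform, generate_cohort, to_relative_abundance

        eff = np.zeros(20)
        eff[:6] = [1.2, -0.9, 0.8, -0.6, 0.5, -0.4]
        cfg = CohortConfig(
            seed=4, n_per_group=30, n_taxa=20, effects={"bf": eff},
            bf_missing_cc=0, bf_missing_home=0,
        )
        table, md, _ = generate_cohort(cfg)
        clr = clr_transform(to_relative_abundance(table))
        covs = covariate_frame(md)
        tab = effects_table(
            clr, covs, n_perm=99, seed=0,
            subjects=md.data["infant_id"].to_numpy(),
        )
        cond = tab[tab["mode"] == "conditional"].set_index("effect")["r2"]
        assert cond.idxmax() == "Breastfeeding"


class TestVariancePartition:
    def test_orthogonal_blocks_no_shared_fraction(self):
        n = 32
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(9)
        Y = np.outer(a, [1, 0.5]) + np.outer(b, [-0.3, 1]) + 0.1 * rng.standard_normal((n, 2))
        cov = pd.DataFrame({"a": a, "b": b})
        part = variance_partition(Y, cov, {"A": ["a"], "B": ["b"]})
        assert part.fractions[("A", "B")] == pytest.approx(0.0, abs=1e-6)
        assert part.unique_r2["A"] == pytest.approx(part.simple_r2["A"], abs=1e-6)

    def test_duplicated_information_fully_shared(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(20)
        Y = np.outer(x, [1.0, -0.5]) + 0.2 * rng.standard_normal((20, 2))
        cov = pd.DataFrame({"x1": x, "x2": 2.0 * x + 1.0})
        # identical information in both blocks (affine copies)
        part = variance_partition(Y, cov, {"A": ["x1"], "B": ["x2"]})
        assert part.unique_r2["A"] == pytest.approx(0.0, abs=1e-8)
        assert part.unique_r2["B"] == pytest.approx(0.0, abs=1e-8)
        assert part.fractions[("A", "B")] == pytest.approx(
            part.simple_r2["A"], abs=1e-8
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_inclusion_exclusion_identity(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((25, 5))
        cov = pd.DataFrame(rng.standard_normal((25, 4)), columns=list("abcd"))
        blocks = {"A": ["a"], "B": ["b"], "C": ["c", "d"]}
        part = variance_partition(Y, cov, blocks)
        total = sum(part.fractions.values())
        full = fit_rda(Y, cov[["a", "b", "c", "d"]]).r2
        assert total == pytest.approx(full, abs=1e-8)
        # reconstructing every subset model's R2 from the fractions
        for S, r2_expected in part.simple_r2.items():
            covered = sum(
                v for k, v in part.fractions.items() if S in k
            )
            assert covered == pytest.approx(r2_expected, abs=1e-8)

    def test_block_count_guard(self):
        Y, _ = _random_case(1)
        cov = pd.DataFrame({"a": np.arange(12.0)})
        with pytest.raises(ValueError, match="2 to 4"):
            variance_partition(Y, cov, {"A": ["a"]})

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(0.5, 101, 10) == pytest.approx(1 - 0.5 * 100 / 90)
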