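import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycogrowth.community import CommunityMatrix, TaxaSelection, hellinger_transform
from mycogrowth.model import (
    ModelData,
    ModelParams,
    PriorConfig,
    build_design,
    dic,
    fit_mcmc,
    log_likelihood,
    log_prior,
    summarize,
)

LOG2PI = np.log(2 * np.pi)


def _alpha_data(bai, x_cols, ln_dbh_raw=None):
    """ModelData with an intercept plus arbitrary extra alpha-block columns."""
    bai = np.asarray(bai, dtype=float)
    n = bai.size
    cols = [np.ones(n)] + [np.asarray(c, dtype=float) for c in x_cols]
    data = ModelData.minimal(bai, ln_dbh_raw)
    data.blocks = {"alpha": np.column_stack(cols)}
    data.names = {"alpha": ["alpha0_intercept"] + [f"alpha_x{i}" for i in range(len(x_cols))]}
    return data


def _params(alpha=(0.0,), beta=(), gamma=(), mu=(), a=1.0, b=0.0, omega=None):
    return ModelParams(
        alpha=np.asarray(alpha, float),
        beta=np.asarray(beta, float),
        gamma=np.asarray(gamma, float),
        mu=np.asarray(mu, float),
        a=a,
        b=b,
        omega=omega,
    )


class TestBuildDesign:
    def test_row_count_drops_first_year_per_tree(self, mid_study, mid_design):
        years = mid_study.growth_table.groupby("tree_id").year.nunique()
        assert mid_design.n_rows == int((years - 1).sum())

    def test_standardized_columns_have_unit_moments(self, mid_design):
        x = mid_design.blocks["alpha"]
        for j in (1, 2, 4, 5):  # ln dbh, Nmin, age, min May T
            assert abs(x[:, j].mean()) < 1e-9
            assert x[:, j].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        for j in range(mid_design.blocks["beta"].shape[1]):
            col = mid_design.blocks["beta"][:, j]
            assert abs(col.mean()) < 1e-9
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_and_interaction_derive_from_standardized(self, mid_design):
        np.testing.assert_allclose(
            mid_design.blocks["gamma"], mid_design.blocks["beta"] ** 2, atol=1e-12
        )
        nmin = mid_design.blocks["alpha"][:, 2]
        np.testing.assert_allclose(
            mid_design.blocks["mu"], nmin[:, None] * mid_design.blocks["beta"], atol=1e-12
        )

    def test_tree_with_two_years_yields_one_row(self):
        growth = pd.DataFrame(
            {
                "tree_id": ["T1", "T1", "T2", "T2", "T3", "T3"],
                "year": [2000, 2001] * 3,
                "location": "L1",
                "species": "s",
                "dbh": [10.5, 11.0, 12.5, 13.0, 9.5, 10.0],
                "dbh_prev": [10.0, 10.5, 12.0, 12.5, 9.0, 9.5],
                "bai": [3.0, 3.5, 4.0, 4.5, 2.0, 2.5],
                "bais": [-1.0, 1.0, -1.0, 1.0, -1.0, 1.0],
                "age": [50, 51, 60, 61, 55, 56],
                "nmin": [2.0, 2.0, 5.0, 5.0, 8.0, 8.0],
                "min_may_t": [4.0, 5.0, 4.0, 5.0, 4.5, 5.5],
            }
        )
        hel = CommunityMatrix(
            ["T1", "T2", "T3"],
            list("abcdefg"),
            np.sqrt(np.full((3, 7), 1 / 7)) + np.diag(np.full(3, 0.01))[:, :7] @ np.eye(3, 7),
            "counts",  # bypass strict norm check; treated as numbers
        )
        hel.state = "hellinger"
        sel = TaxaSelection(
            selected=list("abcdefg"),
            importance_scores=pd.Series(dtype=float),
            coverage=pd.Series(np.ones(3), index=["T1", "T2", "T3"]),
        )
        data = build_design(growth, hel, sel)
        assert data.n_rows == 3

    def test_missing_tree_raises_with_ids(self, mid_study):
        hel = hellinger_transform(mid_study.community)
        dropped = CommunityMatrix(
            hel.tree_ids[1:], hel.taxon_ids, hel.values[1:], "hellinger"
        )
        sel = TaxaSelection(
            selected=hel.taxon_ids[:7],
            importance_scores=pd.Series(dtype=float),
            coverage=pd.Series(dtype=float),
        )
        with pytest.raises(ValueError, match=hel.tree_ids[0]):
            build_design(mid_study.growth_table, dropped, sel)


class TestLogLikelihood:
    def test_standard_lognormal_at_one(self):
        data = ModelData.minimal(np.array([1.0]))
        assert log_likelihood(_params(), data) == pytest.approx(-0.5 * LOG2PI, abs=1e-10)

    def test_nonpositive_variance_hits_sentinel(self):
        data = ModelData.minimal(np.array([1.0, 2.0]), ln_dbh_raw=np.array([2.0, 3.0]))
        assert log_likelihood(_params(a=0.1, b=-0.5), data) == -np.inf

    def test_doubling_data_doubles_loglik(self, rng):
        bai = rng.lognormal(1.0, 0.3, size=40)
        one = ModelData.minimal(bai)
        two = ModelData.minimal(np.concatenate([bai, bai]))
        p = _params(alpha=(0.8,), a=0.2)
        assert log_likelihood(p, two) == pytest.approx(2 * log_likelihood(p, one), rel=1e-12)

    def test_row_permutation_invariance(self, rng):
        bai = rng.lognormal(1.0, 0.3, size=50)
        x = rng.standard_normal(50)
        perm = rng.permutation(50)
        p = _params(alpha=(0.5, 0.2), a=0.3)
        d1 = _alpha_data(bai, [x])
        d2 = _alpha_data(bai[perm], [x[perm]])
        assert log_likelihood(p, d1) == pytest.approx(log_likelihood(p, d2), rel=1e-12)

    def test_matches_scipy_lognorm(self, rng):
        bai = rng.lognormal(0.5, 0.4, size=30)
        p = _params(alpha=(0.7,), a=0.09)
        expected = stats.lognorm.logpdf(bai, s=0.3, scale=np.exp(0.7)).sum()
        assert log_likelihood(p, ModelData.minimal(bai)) == pytest.approx(expected, rel=1e-10)


class TestLogPrior:
    def test_alpha_at_mode_contributes_normal_constant(self):
        # alpha0 = 0, b = 0, a = e (at the logNormal meanlog): every Gaussian
        # factor contributes its normalizing constant only
        lp = log_prior(_params(alpha=(0.0,), a=np.e))
        expected = (
            -0.5 * np.log(2 * np.pi * 1000)  # alpha0
            - 0.5 * np.log(2 * np.pi * 1000)  # b
            - 1.0
            - 0.5 * np.log(2 * np.pi * 1000)  # a (logNormal at exp(meanlog))
        )
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_identity_omega_reduces_to_iid_normals(self, rng):
        beta1 = rng.standard_normal(7)
        beta2 = rng.standard_normal(7)
        base = _params(beta=np.zeros(7), omega=np.eye(7))
        diff = log_prior(_params(beta=beta1, omega=np.eye(7))) - log_prior(
            _params(beta=beta2, omega=np.eye(7))
        )
        expected = stats.norm.logpdf(beta1).sum() - stats.norm.logpdf(beta2).sum()
        assert diff == pytest.approx(expected, abs=1e-10)
        assert np.isfinite(log_prior(base))

    def test_nonpositive_a_unsupported(self):
        assert log_prior(_params(a=-1.0)) == -np.inf
        assert log_prior(_params(a=0.0)) == -np.inf

    def test_precision_reading_shrinks_prior_variance(self):
        wide = log_prior(_params(alpha=(3.0,)), PriorConfig(scale_is_variance=True))
        tight = log_prior(_params(alpha=(3.0,)), PriorConfig(scale_is_variance=False))
        # under the precision reading Normal(0, 1000) is very concentrated
        assert tight < wide


class TestFitMcmc:
    def test_same_master_seed_reproduces_draws(self, rng):
        bai = rng.lognormal(1.0, 0.3, size=60)
        data = ModelData.minimal(bai)
        kw = dict(chains=2, iterations=400, burn_in=200, thin=2, seed=11,
                  fix_variance=(0.09, 0.0))
        a = fit_mcmc(data, **kw)
        b = fit_mcmc(data, **kw)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_conjugate_posterior_recovered(self, rng):
        """With sigma2 fixed and only the intercept free, the MCMC posterior
        must match the closed-form normal posterior."""
        n = 50
        ln_bai = 1.5 + rng.standard_normal(n)
        data = ModelData.minimal(np.exp(ln_bai))
        post = fit_mcmc(
            data, chains=3, iterations=4000, burn_in=1000, thin=2, seed=5,
            prior=PriorConfig(normal_scale=1e6), fix_variance=(1.0, 0.0),
        )
        draws = post.stacked[:, 0]
        tau2 = 1e6
        exact_var = 1 / (n + 1 / tau2)
        exact_mean = exact_var * ln_bai.sum()
        ess = float(post.ess.loc["alpha0_intercept"])
        mc_se = draws.std(ddof=1) / np.sqrt(ess)
        assert abs(draws.mean() - exact_mean) < 3 * mc_se
        assert draws.std(ddof=1) == pytest.approx(np.sqrt(exact_var), rel=0.1)

    def test_stored_loglik_matches_recomputation(self, mid_design):
        """The sampler's cached log-likelihood at retained draws equals an
        independent evaluation (posterior = likelihood x prior audit)."""
        post = fit_mcmc(
            mid_design, chains=2, iterations=300, burn_in=300, thin=3, seed=9
        )
        rng = np.random.default_rng(0)
        n_stored = post.draws.shape[1]
        for _ in range(100):
            c = int(rng.integers(post.draws.shape[0]))
            i = int(rng.integers(n_stored))
            params = post.params_at(c, i)
            assert log_likelihood(params, mid_design) == pytest.approx(
                post.loglik_draws[c, i], abs=1e-8
            )

    def test_acceptance_rates_in_adapted_band(self, mid_design):
        post = fit_mcmc(
            mid_design, chains=2, iterations=1500, burn_in=1500, thin=5, seed=13
        )
        for block, rates in post.acceptance.items():
            assert 0.10 < rates.mean() < 0.60, block

    def test_covariance_reading_of_wishart_runs(self, mid_design):
        """The alternative reading (Wishart on the coefficient covariance,
        Metropolis update) samples without degenerate output."""
        post = fit_mcmc(
            mid_design, chains=2, iterations=300, burn_in=300, thin=3, seed=17,
            prior=PriorConfig(wishart_on="covariance"),
        )
        assert np.isfinite(post.stacked).all()
        assert post.omega_draws is not None
        # sampled covariance matrices stay symmetric positive definite
        for om in post.omega_draws[0, ::10]:
            assert np.allclose(om, om.T)
            assert np.linalg.eigvalsh(om).min() > 0

    def test_single_observation_posterior_matches_prior(self):
        """Unidentified fungal coefficients revert to their prior."""
        n_taxa = 7
        rng = np.random.default_rng(3)
        data = ModelData.minimal(np.array([5.0]))
        data.blocks = {
            "alpha": np.ones((1, 1)),
            "beta": rng.standard_normal((1, n_taxa)) * 0.1,
        }
        data.names = {
            "alpha": ["alpha0_intercept"],
            "beta": [f"beta_t{j}" for j in range(n_taxa)],
        }
        data.taxa = [f"t{j}" for j in range(n_taxa)]
        post = fit_mcmc(
            data, chains=3, iterations=20000, burn_in=2000, thin=10, seed=21,
            fix_variance=(1.0, 0.0),
        )
        beta1 = post.stacked[:, post.names.index("beta_t1")]
        prior_rng = np.random.default_rng(99)
        prior_draws = np.empty(6000)
        for i in range(prior_draws.size):
            om = stats.wishart.rvs(df=n_taxa, scale=np.eye(n_taxa), random_state=prior_rng)
            prior_draws[i] = prior_rng.multivariate_normal(
                np.zeros(n_taxa), np.linalg.inv(om)
            )[1]
        ks = stats.ks_2samp(beta1, prior_draws).statistic
        assert ks < 0.1


class TestSummaries:
    def _toy_posterior(self, draws_matrix, names):
        from mycogrowth.model import PosteriorSamples

        return PosteriorSamples(
            draws=draws_matrix,
            names=names,
            omega_draws=None,
            loglik_draws=np.zeros(draws_matrix.shape[:2]),
            rhat=None,
            ess=None,
            acceptance={},
            seed=0,
            settings={},
        )

    def test_quantiles_of_standard_normal_draws(self):
        rng = np.random.default_rng(2024)
        draws = rng.standard_normal((1, 100000, 3))
        draws[:, :, 1] = 0.0  # stands in for a fixed parameter
        post = self._toy_posterior(draws, ["beta_x", "a", "b"])
        summ = summarize(post)
        assert summ.table.loc["beta_x", "ci_2.5"] == pytest.approx(-1.96, abs=0.05)
        assert summ.table.loc["beta_x", "ci_97.5"] == pytest.approx(1.96, abs=0.05)
        assert not summ.table.loc["beta_x", "significant"]

    def test_correlation_matrix_unit_diagonal(self, mid_design):
        post = fit_mcmc(
            mid_design, chains=2, iterations=400, burn_in=400, thin=4, seed=30
        )
        summ = summarize(post, mid_design)
        np.testing.assert_allclose(np.diag(summ.fungal_corr), 1.0, atol=1e-12)
        assert summ.fungal_corr.shape == (21, 21)

    def test_significance_flag_requires_zero_exclusion(self):
        rng = np.random.default_rng(5)
        draws = np.stack(
            [rng.standard_normal(4000), 5 + 0.1 * rng.standard_normal(4000)], axis=-1
        )[None, :, :]
        post = self._toy_posterior(draws, ["beta_sym", "a"])
        summ = summarize(post)
        assert not summ.table.loc["beta_sym", "significant"]
        assert summ.table.loc["a", "significant"]

    def test_degenerate_posterior_has_zero_pd(self, rng):
        bai = rng.lognormal(1.0, 0.3, size=30)
        data = ModelData.minimal(bai)
        vec = np.array([0.9, 0.2, 0.0])
        draws = np.tile(vec, (2, 50, 1))
        post = self._toy_posterior(draws, ["alpha0_intercept", "a", "b"])
        post.data = data
        res = dic(post, data)
        assert res.p_d == pytest.approx(0.0, abs=1e-8)
        p = _params(alpha=(0.9,), a=0.2)
        assert res.dic == pytest.approx(-2 * log_likelihood(p, data), abs=1e-8)


@pytest.mark.timeout(300)
def test_posterior_matches_jags_reference(tmp_path, rng):
    """Cross-check against the independent JAGS implementation of the same
    log-normal regression (fixed-variance reduced model)."""
    n = 120
    x = rng.standard_normal(n)
    lnb = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(n)
    bai = np.exp(lnb)

    data = _alpha_data(bai, [x])
    post = fit_mcmc(
        data, chains=3, iterations=6000, burn_in=2000, thin=3, seed=8,
        prior=PriorConfig(normal_scale=1e6), fix_variance=(0.09, 0.0),
    )
    mine = summarize(post).table

    np.savetxt(tmp_path / "y.txt", bai)
    np.savetxt(tmp_path / "x.txt", x)
    script = textwrap.dedent(
        """
        library(rjags)
        y <- scan("y.txt"); x <- scan("x.txt")
        model_str <- "model {
          for (i in 1:N) { y[i] ~ dlnorm(mu[i], tau); mu[i] <- b0 + b1 * x[i] }
          b0 ~ dnorm(0, 1e-6); b1 ~ dnorm(0, 1e-6)
        }"
        m <- jags.model(textConnection(model_str),
                        data=list(y=y, x=x, N=length(y), tau=1/0.09),
                        n.chains=2, n.adapt=500, quiet=TRUE)
        update(m, 2000)
        s <- coda.samples(m, c("b0","b1"), n.iter=8000)
        sm <- summary(s)$statistics
        cat(sm["b0","Mean"], sm["b0","SD"], sm["b1","Mean"], sm["b1","SD"], "\\n")
        """
    )
    (tmp_path / "model.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "model.R"], capture_output=True, text=True, cwd=tmp_path, timeout=240
    )
    assert out.returncode == 0, out.stderr
    b0_mean, b0_sd, b1_mean, b1_sd = map(float, out.stdout.split())

    for name, jm, jsd in [
        ("alpha0_intercept", b0_mean, b0_sd),
        ("alpha_x0", b1_mean, b1_sd),
    ]:
        mean, sd = mine.loc[name, "mean"], mine.loc[name, "sd"]
        assert abs(mean - jm) < 4 * sd / np.sqrt(200)  # generous joint MC error
        assert sd == pytest.approx(jsd, rel=0.15)
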