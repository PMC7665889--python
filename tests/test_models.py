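"""The two testing engines against independent likelihood oracles, and
dispersion estimation recovery."""

import numpy as np
import pytest
from scipy import optimize, special, stats
from scipy.stats import betabinom as scipy_betabinom
import statsmodels.api as sm

from imprintcall.models import (BetaBinomialModel, PairedAlleleModel,
                                _betabin_loglik_grad, estimate_dispersions)


def nb_loglik(y, mu, alpha):
    """Hand-written NB2 log-likelihood (independent of statsmodels)."""
    if alpha <= 0:
        return np.sum(stats.poisson.logpmf(y, mu))
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(np.sum(stats.nbinom.logpmf(y, r, p)))


class TestPairedNB:
    groups = np.array(["wt"] * 4 + ["matD"] * 4, dtype=object)

    def test_identical_patterns_give_null_result(self):
        m = np.array([30, 40, 50, 60, 30, 40, 50, 60])
        p = np.array([10, 15, 20, 25, 10, 15, 20, 25])
        res = PairedAlleleModel(m, p, self.groups, dispersion=0.05).fit()
        assert res.params["allele:group[matD]"] == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue > 0.5

    def test_poisson_limit_agrees_with_binomial_logit_lrt(self):
        """With dispersion 0 the paired design's totals are ancillary and
        the LRT reduces to a binomial logistic LRT on the proportions."""
        m = np.array([80, 70, 40, 35])
        p = np.array([20, 30, 60, 65])
        groups = np.array(["wt", "wt", "matD", "matD"], dtype=object)
        res = PairedAlleleModel(m, p, groups, dispersion=0.0).fit()
        endog = np.column_stack([m, p]).astype(float)
        X = np.column_stack([np.ones(4), (groups == "matD").astype(float)])
        full = sm.GLM(endog, X, family=sm.families.Binomial()).fit(tol=1e-12)
        null = sm.GLM(endog, X[:, :1],
                      family=sm.families.Binomial()).fit(tol=1e-12)
        binom_stat = 2 * (full.llf - null.llf)
        assert res.lrt_statistic == pytest.approx(binom_stat, abs=1e-6)

    def test_maximized_likelihood_matches_direct_optimizer(self):
        """llf of the IRLS fit equals a Nelder-Mead maximization of a
        hand-written NB likelihood on a 1-gene, 4-sample instance."""
        m = np.array([55, 20, 80, 33])
        p = np.array([45, 28, 25, 30])
        groups = np.array(["wt", "wt", "matD", "matD"], dtype=object)
        alpha = 0.08
        model = PairedAlleleModel(m, p, groups, dispersion=alpha)
        res = model.fit()

        def neg(beta):
            mu = np.exp(model.exog @ beta)
            return -nb_loglik(model.endog, mu, alpha)

        start = np.zeros(model.exog.shape[1])
        start[:4] = np.log((m + p) / 2.0)
        opt = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 20000, "maxfev": 20000})
        assert res.llf == pytest.approx(-opt.fun, abs=1e-4)
        assert res.llf >= -opt.fun - 1e-4

    def test_missing_group_is_not_identifiable(self):
        m = np.array([5, 5, 0, 0])
        p = np.array([5, 5, 0, 0])
        groups = np.array(["wt", "wt", "matD", "matD"], dtype=object)
        with pytest.raises(ValueError):
            PairedAlleleModel(m, p, groups, dispersion=0.1)

    def test_cre_strata_add_interaction_columns(self):
        m = np.array([30, 30, 30, 30])
        p = np.array([10, 10, 10, 10])
        groups = np.array(["wt", "wt", "matD", "matD"], dtype=object)
        strata = np.array(["MMTV", "Zp3", "MMTV", "Zp3"], dtype=object)
        model = PairedAlleleModel(m, p, groups, strata=strata, dispersion=0.1)
        assert "allele:stratum[Zp3]" in model.term_names
        assert model.df_test == 1

    def test_summary_reports_the_test(self):
        m = np.array([30, 40, 10, 9])
        p = np.array([10, 15, 30, 28])
        res = PairedAlleleModel(m, p, np.array(["wt", "wt", "matD", "matD"],
                                               dtype=object),
                                dispersion=0.05).fit()
        text = res.summary()
        assert "LRT" in text and "allele:group[matD]" in text


class TestBetaBinomial:
    def test_loglik_matches_scipy_betabinom(self):
        """The internal likelihood agrees with scipy's beta-binomial pmf
        under the (mean, intraclass-correlation) reparametrization."""
        rho, pi = 0.05, 0.3
        s = (1 - rho) / rho
        a, b = pi * s, (1 - pi) * s
        succ = np.array([3.0, 10.0, 0.0])
        fail = np.array([7.0, 10.0, 12.0])
        X = np.ones((3, 1))
        beta = np.array([special.logit(pi)])
        ll, _ = _betabin_loglik_grad(beta, X, succ, fail, rho)
        ref = scipy_betabinom.logpmf(succ, (succ + fail).astype(int), a, b).sum()
        assert ll == pytest.approx(ref, abs=1e-8)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(6), rng.integers(0, 2, 6)])
        succ = rng.poisson(20, 6).astype(float)
        fail = rng.poisson(30, 6).astype(float)
        beta = np.array([0.3, -0.5])
        _, grad = _betabin_loglik_grad(beta, X, succ, fail, 0.02)
        for j in range(2):
            e = np.zeros(2)
            e[j] = 1e-6
            up, _ = _betabin_loglik_grad(beta + e, X, succ, fail, 0.02)
            dn, _ = _betabin_loglik_grad(beta - e, X, succ, fail, 0.02)
            assert grad[j] == pytest.approx((up - dn) / 2e-6, rel=1e-4)

    def test_identical_balanced_counts_give_p_one(self):
        m = np.array([10, 12, 10, 12])
        p = np.array([10, 12, 10, 12])
        groups = np.array(["wt", "wt", "matD", "matD"], dtype=object)
        res = BetaBinomialModel(m, p, groups, phi=0.01).fit()
        assert res.lrt_statistic == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue > 0.999

    def test_maximum_matches_dense_grid(self):
        """MLE log-likelihood beats/equals a dense 2-D grid over
        (intercept, group effect) to 1e-4."""
        m = np.array([40, 35, 10, 12, 9])
        p = np.array([10, 18, 30, 28, 31])
        groups = np.array(["wt", "wt", "matD", "matD", "matD"], dtype=object)
        model = BetaBinomialModel(m, p, groups, phi=0.01)
        res = model.fit()

        def grid_max(c0, c1, half, k):
            best, arg = -np.inf, (c0, c1)
            for x in np.linspace(c0 - half, c0 + half, k):
                for yv in np.linspace(c1 - half, c1 + half, k):
                    ll, _ = _betabin_loglik_grad(
                        np.array([x, yv]), model.exog, model.success,
                        model.failure, 0.01)
                    if ll > best:
                        best, arg = ll, (x, yv)
            return best, arg

        best, (x, yv) = grid_max(0.5, -1.5, 3.0, 121)   # coarse sweep
        best, _ = grid_max(x, yv, 0.05, 101)            # refine
        assert res.llf >= best - 1e-6
        assert res.llf == pytest.approx(best, abs=1e-4)

    def test_group_without_informative_samples_rejected(self):
        m = np.array([10, 10, 0, 0])
        p = np.array([10, 10, 0, 0])
        groups = np.array(["wt", "wt", "matD", "matD"], dtype=object)
        with pytest.raises(ValueError):
            BetaBinomialModel(m, p, groups, phi=0.01)

    def test_phi_domain_enforced(self):
        with pytest.raises(ValueError):
            BetaBinomialModel([1], [1], ["wt"], phi=1.0)


class TestDispersionEstimation:
    @staticmethod
    def _paired_obs(rng, n_genes, dispersion, n_per_group=4):
        groups = np.array(["wt"] * n_per_group + ["matD"] * n_per_group,
                          dtype=object)
        obs = []
        for _ in range(n_genes):
            mu = rng.lognormal(4.0, 0.7)
            if dispersion > 0:
                r = 1.0 / dispersion
                m = rng.negative_binomial(r, r / (r + mu), 2 * n_per_group)
                p = rng.negative_binomial(r, r / (r + mu), 2 * n_per_group)
            else:
                m = rng.poisson(mu, 2 * n_per_group)
                p = rng.poisson(mu, 2 * n_per_group)
            model = PairedAlleleModel(m[:2 * n_per_group], p, groups,
                                      dispersion=0.0)
            obs.append((model.endog, model.exog))
        return obs

    def test_common_recovers_true_dispersion(self):
        rng = np.random.default_rng(42)
        obs = self._paired_obs(rng, 200, 0.1)
        d = estimate_dispersions(obs, mode="common")
        assert 0.07 <= d[0] <= 0.13
        assert np.ptp(d) == 0.0  # constant vector

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(7)
        obs = self._paired_obs(rng, 60, 0.0)
        d = estimate_dispersions(obs, mode="common")
        assert d[0] <= 0.01

    def test_tagwise_shrinks_toward_common(self):
        rng = np.random.default_rng(3)
        obs = self._paired_obs(rng, 80, 0.1)
        tag = estimate_dispersions(obs, mode="tagwise", prior_weight=10.0)
        common = estimate_dispersions(obs, mode="common")[0]
        assert tag.std() < 0.1            # pulled together
        assert abs(np.median(tag) - common) < 0.05
        loose = estimate_dispersions(obs, mode="tagwise", prior_weight=1.0)
        assert loose.std() > tag.std()    # weaker prior spreads out

    def test_all_zero_rejected(self):
        obs = [(np.zeros(4), np.ones((4, 1)))]
        with pytest.raises(ValueError):
            estimate_dispersions(obs)
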