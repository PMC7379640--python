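import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, special

import phylopaths as pp
from phylopaths.tree import PhyloCovariance

from conftest import phylo_noise


def firth_logistic_oracle(y, X):
    """Direct maximization of the Firth-penalized logistic likelihood.

    Independent of the package's IRLS path: generic quasi-Newton on the
    penalized objective l(b) + 0.5 log|X'W(b)X| with its analytic gradient.
    """
    D = np.column_stack([np.ones(len(y)), X])

    def neg(b):
        eta = D @ b
        mu = special.expit(eta)
        w = mu * (1 - mu)
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        _, ld = np.linalg.slogdet(D.T @ (D * w[:, None]))
        return -(ll + 0.5 * ld)

    def grad(b):
        eta = D @ b
        mu = special.expit(eta)
        w = mu * (1 - mu)
        info_inv = np.linalg.inv(D.T @ (D * w[:, None]))
        h = w * np.einsum("ij,jk,ik->i", D, info_inv, D)
        return -(D.T @ (y + h * (0.5 - mu) - mu))

    res = optimize.minimize(neg, np.zeros(D.shape[1]), jac=grad,
                            method="BFGS", options={"gtol": 1e-12})
    return res.x


class TestPGLS:
    def test_star_tree_equals_ols(self, star_cov):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 2))
        y = 0.5 * X[:, 0] + rng.standard_normal(40)
        fit = pp.fit_pgls(y, X, star_cov, lambda_mode="fixed", fixed_lambda=1.0)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coefficients, ols.params, atol=1e-8)
        assert np.allclose(fit.se, ols.bse, atol=1e-8)
        assert np.allclose(fit.p_values, ols.pvalues, atol=1e-8)

    def test_lambda_zero_equals_ols_on_any_tree(self):
        tree = pp.simulate_tree(35, seed=8)
        cov = pp.vcv(tree)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((35, 1))
        y = rng.standard_normal(35)
        fit = pp.fit_pgls(y, X, cov, lambda_mode="fixed", fixed_lambda=0.0)
        # lambda=0 leaves a diagonal (not identity) V: weighted least squares
        w = 1.0 / np.diag(cov.base_matrix)
        wls = sm.WLS(y, sm.add_constant(X), weights=w).fit()
        assert np.allclose(fit.coefficients, wls.params, atol=1e-8)

    def test_exact_linear_data_interpolated(self, star_cov):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 2))
        y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        fit = pp.fit_pgls(y, X, star_cov, lambda_mode="fixed")
        assert np.allclose(fit.coefficients, [1.0, 2.0, -0.5], atol=1e-8)

    def test_invariant_to_branch_length_scaling(self):
        tree = pp.simulate_tree(40, seed=4)
        rng = np.random.default_rng(4)
        cov = pp.vcv(tree)
        y = phylo_noise(cov, rng)
        X = phylo_noise(cov, rng)
        f1 = pp.fit_pgls(y, X, cov)
        f2 = pp.fit_pgls(y, X, pp.vcv(tree.scale_branch_lengths(137.0)))
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-8)
        assert np.allclose(f1.statistic, f2.statistic, atol=1e-8)
        assert np.allclose(f1.p_values, f2.p_values, atol=1e-8)

    def test_ml_lambda_recovers_brownian_signal(self):
        # traits simulated as pure Brownian motion: lambda-hat should
        # concentrate near 1
        lams = []
        for seed in range(30):
            tree = pp.simulate_tree(100, seed=100 + seed)
            cov = pp.vcv(tree)
            rng = np.random.default_rng(200 + seed)
            y = phylo_noise(cov, rng)
            x = phylo_noise(cov, rng)
            lams.append(pp.fit_pgls(y, x, cov).lambda_or_alpha)
        assert np.median(lams) > 0.8

    def test_collinear_design_rejected(self, star_cov):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            pp.fit_pgls(rng.standard_normal(40), X, star_cov)


class TestPhyloLogistic:
    def test_identity_covariance_equals_firth_logistic(self, star_cov):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 2))
        y = (X[:, 0] + rng.standard_normal(40) > 0).astype(float)
        fit = pp.fit_phylo_logistic(y, X, star_cov)
        oracle = firth_logistic_oracle(y, X)
        assert np.allclose(fit.coefficients, oracle, atol=1e-6)

    def test_separated_data_stays_finite(self):
        n = 20
        cov = PhyloCovariance([f"s{i}" for i in range(n)], np.eye(n))
        x = np.linspace(-1, 1, n)
        y = (x > 0).astype(float)
        fit = pp.fit_phylo_logistic(y, x, cov)
        assert np.all(np.isfinite(fit.coefficients))
        assert np.all(np.isfinite(fit.se))
        assert fit.converged

    def test_single_class_rejected(self, star_cov):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="single class"):
            pp.fit_phylo_logistic(np.zeros(40), rng.standard_normal(40),
                                  star_cov)

    def test_effect_recovery_under_liability_model(self):
        # moderate-scale parameter recovery; the threshold (probit-like)
        # liability truth maps onto the logit latent scale by pi/sqrt(3)
        betas = []
        for seed in range(25):
            tree = pp.simulate_tree(150, seed=300 + seed)
            cov = pp.vcv(tree)
            rng = np.random.default_rng(400 + seed)
            x = phylo_noise(cov, rng)
            x = (x - x.mean()) / x.std(ddof=1)
            latent = 1.0 * x + phylo_noise(cov, rng)
            y = (latent > np.quantile(latent, 0.7)).astype(float)
            betas.append(pp.fit_phylo_logistic(y, x, cov).coefficients[1])
        logit_scale = np.pi / np.sqrt(3)
        assert abs(np.mean(betas) / logit_scale - 1.0) < 0.25

    def test_wald_pvalues_match_statistics(self, star_cov):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 1))
        y = (rng.standard_normal(40) > 0.5).astype(float)
        fit = pp.fit_phylo_logistic(y, X, star_cov)
        from scipy import stats
        assert np.allclose(
            fit.p_values, 2 * stats.norm.sf(np.abs(fit.statistic)), atol=1e-12)


class TestEstimatorAPI:
    def test_sklearn_params_round_trip(self):
        est = pp.PGLS(lambda_mode="fixed", fixed_lambda=0.5)
        assert est.get_params()["fixed_lambda"] == 0.5
        est.set_params(fixed_lambda=0.25)
        assert est.fixed_lambda == 0.25

    def test_fitted_attributes_and_predict(self, star_cov):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 1))
        y = 2 * X[:, 0] + rng.standard_normal(40)
        est = pp.PGLS(lambda_mode="fixed").fit(X, y, cov=star_cov)
        assert est.coef_.shape == (1,)
        pred = est.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.5
        clf = pp.PhyloLogisticRegression().fit(
            X, (y > 0).astype(float), cov=star_cov)
        proba = clf.predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
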