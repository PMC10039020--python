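import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sedanet as sn
from sedanet.copula import _glasso_admm
from sedanet.io import InputError


def _poisson_data(n, beta, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta) - 1))
    eta = beta[0] + X @ beta[1:]
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame({"y": y}), pd.DataFrame(X, columns=["c1", "c2"])


class TestFitMarginals:
    def test_poisson_coefficient_recovery(self):
        beta = np.array([1.0, 0.5, -0.3])
        counts, cov = _poisson_data(200, beta, seed=0)
        fit = sn.fit_marginals(counts, cov, family_model="poisson")[0]
        se = np.sqrt(np.diag(np.linalg.inv(
            (np.column_stack([np.ones(200), cov]).T
             * fit.mu) @ np.column_stack([np.ones(200), cov]))))
        assert np.all(np.abs(fit.params - beta) < 3 * se)

    def test_constant_covariates_mean_matching(self):
        counts = pd.DataFrame({"y": [3, 5, 4, 6, 2]})
        cov = pd.DataFrame({"c": np.ones(5)})
        fit = sn.fit_marginals(counts, cov, family_model="poisson")[0]
        np.testing.assert_allclose(fit.mu, counts["y"].mean())

    def test_nb_dispersion_recovery(self):
        """NB2 data with dispersion 2.0: estimate within 50% at n=200."""
        rng = np.random.default_rng(4)
        n, alpha = 200, 2.0
        X = rng.normal(size=(n, 1))
        mu = np.exp(1.5 + 0.4 * X[:, 0])
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu))
        fits = sn.fit_marginals(pd.DataFrame({"y": y}),
                                pd.DataFrame(X, columns=["c"]))
        fit = fits[0]
        assert fit.kind == "nb"
        assert abs(fit.alpha - alpha) < 0.5 * alpha

    def test_rank_deficient_design(self):
        counts = pd.DataFrame({"y": np.arange(6)})
        cov = pd.DataFrame({"a": np.arange(6.0), "b": 2 * np.arange(6.0)})
        with pytest.raises(InputError, match="rank-deficient"):
            sn.fit_marginals(counts, cov)


class TestDunnSmythResiduals:
    def _fit_and_scores(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(120, 1))
        mu = np.exp(1.0 + 0.5 * X[:, 0])
        y = rng.poisson(mu)
        counts = pd.DataFrame({"y": y})
        cov = pd.DataFrame(X, columns=["c"])
        fits = sn.fit_marginals(counts, cov, family_model="poisson")
        return sn.dunn_smyth_residuals(fits, counts, seed=seed)["y"]

    def test_calibration_normality(self):
        """Residuals of a correctly specified model are standard normal:
        Shapiro passes at alpha=0.01 in >=95% of 100 seeds."""
        passed = sum(stats.shapiro(self._fit_and_scores(s)).pvalue > 0.01
                     for s in range(100))
        assert passed >= 95

    def test_deterministic_under_seed(self):
        a = self._fit_and_scores(7)
        b = self._fit_and_scores(7)
        np.testing.assert_array_equal(a, b)

    def test_median_count_scores_near_zero(self):
        # symmetric fitted marginal, observation at the median: the
        # randomised PIT interval straddles 0.5
        counts = pd.DataFrame({"y": [50] * 30})
        cov = pd.DataFrame({"c": np.ones(30)})
        fits = sn.fit_marginals(counts, cov, family_model="poisson")
        scores = sn.dunn_smyth_residuals(fits, counts, seed=0)["y"]
        assert np.abs(scores.mean()) < 0.2


class TestGraphicalLasso:
    def test_full_shrinkage_empty_edges(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.normal(size=(50, 6)))
        S = np.corrcoef(scores.to_numpy(), rowvar=False)
        lam = np.abs(S - np.eye(6)).max() + 0.01
        g = sn.graphical_lasso(scores, lam)
        assert g.edges == []
        assert np.allclose(g.precision - np.diag(np.diag(g.precision)), 0)

    def test_unpenalized_limit_matches_inverse(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(400, 10)))
        S = np.corrcoef(scores.to_numpy(), rowvar=False)
        g = sn.graphical_lasso(scores, 0.0)
        direct = np.linalg.inv(S)
        rel = np.linalg.norm(g.precision - direct) / np.linalg.norm(direct)
        assert rel < 1e-3

    def test_matches_sklearn_solver(self):
        """Independent cross-check against scikit-learn's graphical lasso."""
        from sklearn.covariance import graphical_lasso as sk_glasso
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 8))
        X[:, 1] += 0.8 * X[:, 0]
        S = np.corrcoef(X, rowvar=False)
        import warnings as _w
        for lam in (0.05, 0.2):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                _, sk_prec = sk_glasso(S, alpha=lam, tol=1e-8, max_iter=2000)
            theta, _ = _glasso_admm(S, lam)
            assert np.abs(theta - sk_prec).max() < 1e-3

    def test_precision_positive_definite(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(size=(60, 12)))
        for lam in (0.0, 0.1, 0.5):
            g = sn.graphical_lasso(scores, lam)
            np.linalg.cholesky(g.precision)  # raises if not PD
            np.testing.assert_allclose(np.diag(g.partial_corr), 1.0)

    def test_partial_corr_definition(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(rng.normal(size=(80, 5)))
        g = sn.graphical_lasso(scores, 0.1)
        P = g.precision
        d = np.sqrt(np.diag(P))
        expect = -P / np.outer(d, d)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(g.partial_corr, expect, atol=1e-12)

    def test_covariate_induced_correlation_removed(self):
        """Two taxa driven only by a shared covariate are marginally
        correlated, but lose their direct edge once the covariate enters
        the marginal regressions."""
        rng = np.random.default_rng(5)
        n = 150
        z = rng.normal(size=n)  # shared environmental driver
        mu1, mu2 = np.exp(2 + 0.8 * z), np.exp(2 - 0 + 0.8 * z)
        counts = pd.DataFrame({"t1": rng.poisson(mu1), "t2": rng.poisson(mu2),
                               "t3": rng.poisson(np.exp(2 + rng.normal(
                                   size=n) * 0.1))})
        marginal_rho = stats.spearmanr(counts["t1"], counts["t2"])[0]
        assert marginal_rho > 0.3  # induced co-occurrence is there
        cov = pd.DataFrame({"z": z})
        fits = sn.fit_marginals(counts, cov, family_model="poisson")
        scores = sn.dunn_smyth_residuals(fits, counts, seed=0)
        g = sn.graphical_lasso(scores, 0.3)
        assert frozenset(("t1", "t2")) not in g.edge_set()


class TestLambdaPath:
    def test_single_lambda_equals_direct_call(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(40, 5)))
        path = sn.lambda_path(scores, grid=[0.2])
        direct = sn.graphical_lasso(scores, 0.2)
        assert [e[:2] for e in path[0].edges] == [e[:2] for e in direct.edges]

    def test_default_grid_contains_headline(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(rng.normal(size=(30, 4)))
        path = sn.lambda_path(scores)
        lams = [g.lam for g in path]
        assert 0.51 in lams
        assert lams == sorted(lams) and lams[0] == 0.1 and lams[-1] == 1.0

    def test_edge_count_nonincreasing(self, small_community):
        cm, _, _ = small_community
        rng = np.random.default_rng(8)
        # correlated scores: shared factor + noise
        f = rng.normal(size=(30, 1))
        scores = pd.DataFrame(f @ rng.normal(size=(1, 8))
                              + rng.normal(size=(30, 8)))
        counts = [len(g.edges) for g in sn.lambda_path(scores)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_unsorted_grid_rejected(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(rng.normal(size=(30, 4)))
        with pytest.raises(InputError):
            sn.lambda_path(scores, grid=[0.5, 0.1])
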