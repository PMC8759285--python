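import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrs_kit import io_formats as io
from ptrs_kit import prs, ptrs
from ptrs_kit.transcriptome import PredictedExpression
from oracles import cd_elastic_net, en_objective


def _pe(vals, state="standardized"):
    vals = np.asarray(vals, float)
    return PredictedExpression(
        [f"s{i}" for i in range(vals.shape[0])],
        [f"g{j}" for j in range(vals.shape[1])],
        vals,
        state,
    )


def _pheno(y, C=None):
    tab = pd.DataFrame({"trait": y}, index=pd.Index([f"s{i}" for i in range(len(y))], name="sample_id"))
    cov = []
    if C is not None:
        for k in range(C.shape[1]):
            tab[f"c{k}"] = C[:, k]
            cov.append(f"c{k}")
    return io.PhenotypeTable(tab, ["trait"], cov)


def _std(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestLambdaMax:
    def test_constant_trait_gives_zero(self, rng):
        X = _std(rng.standard_normal((50, 4)))
        assert ptrs.lambda_max(np.full(50, 3.0), X) == 0.0

    def test_two_point_hand_gradient(self):
        X = np.array([[-1.0], [1.0]])
        Y = np.array([-1.0, 1.0])
        assert ptrs.lambda_max(Y, X, alpha=0.1) == pytest.approx(20.0)

    def test_alpha_zero_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            ptrs.lambda_max(rng.standard_normal(10), rng.standard_normal((10, 2)), alpha=0.0)

    def test_subsample_rule(self, rng):
        Y = rng.standard_normal(3000)
        X = _std(rng.standard_normal((3000, 5)))
        sub = ptrs.lambda_max(Y, X, n_subsample=1000)
        full = ptrs.lambda_max(Y[:1000], X[:1000], n_subsample=None)
        assert sub == full

    def test_solution_above_lambda_max_is_zero(self, rng):
        X = _std(rng.standard_normal((60, 8)))
        Y = X[:, 0] * 0.7 + rng.standard_normal(60)
        lm = ptrs.lambda_max(Y, X, n_subsample=None)
        fit = ptrs.fit_elastic_net_path(Y, X, None, grid=np.array([1.01 * lm]))
        assert np.all(fit.coefs == 0)
        assert fit.intercepts[0] == pytest.approx(Y.mean())


class TestLambdaGrid:
    def test_printed_grid_rule(self):
        g = ptrs.lambda_grid(1.0)
        assert len(g) == 20
        assert g[0] == pytest.approx(1.5)
        assert g[-1] == pytest.approx(1e-4)

    def test_log_equispacing(self):
        g = ptrs.lambda_grid(2.7)
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, (1.5e4) ** (-1 / 19))

    def test_zero_lambda_max_rejected(self):
        with pytest.raises(ValueError, match="signal"):
            ptrs.lambda_grid(0.0)


class TestElasticNetPath:
    def _problem(self, rng, n=100, m=12):
        T = _std(rng.standard_normal((n, m)))
        beta = np.zeros(m)
        beta[:3] = [1.0, -0.5, 0.8]
        y = T @ beta + rng.standard_normal(n)
        return y, T

    def test_matches_coordinate_descent_oracle(self, rng):
        y, T = self._problem(rng)
        lm = ptrs.lambda_max(y, T, n_subsample=None)
        grid = ptrs.lambda_grid(lm, n=8)
        fit = ptrs.fit_elastic_net_path(y, T, None, grid=grid)
        for k, lam in enumerate(grid):
            b, b0 = cd_elastic_net(T, y, lam, 0.1)
            assert fit.objectives[k] == pytest.approx(
                en_objective(T, y, b, b0, lam, 0.1), rel=1e-6
            )

    def test_unregularized_limit_approaches_ols(self, rng):
        y, T = self._problem(rng, n=50, m=5)
        fit = ptrs.fit_elastic_net_path(y, T, None, grid=np.array([1e-8]))
        X1 = np.column_stack([np.ones(50), T])
        ols = np.linalg.lstsq(X1, y, rcond=None)[0]
        assert np.abs(fit.coefs[0] - ols[1:]).max() < 1e-3

    def test_warm_start_no_worse_than_cold(self, rng):
        y, T = self._problem(rng)
        grid = ptrs.lambda_grid(ptrs.lambda_max(y, T, n_subsample=None), n=10)
        warm = ptrs.fit_elastic_net_path(y, T, None, grid=grid)
        for k, lam in enumerate(grid):
            cold = ptrs.fit_elastic_net_path(y, T, None, grid=np.array([lam]))
            assert warm.objectives[k] <= cold.objectives[0] + 1e-8

    def test_kkt_certificate(self, rng):
        y, T = self._problem(rng)
        grid = ptrs.lambda_grid(ptrs.lambda_max(y, T, n_subsample=None), n=10)
        fit = ptrs.fit_elastic_net_path(y, T, None, grid=grid)
        assert ptrs.kkt_violation(fit, y, T, None).max() < 1e-4

    def test_objective_matches_sklearn_parameterization(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        y, T = self._problem(rng, n=120, m=10)
        lam = 0.05
        alpha = 0.1
        fit = ptrs.fit_elastic_net_path(y, T, None, alpha=alpha, grid=np.array([lam]))
        sk = sklearn.ElasticNet(
            alpha=lam * (1 - alpha / 2), l1_ratio=alpha / (2 - alpha), tol=1e-12,
            max_iter=100000,
        ).fit(T, y)
        obj_sk = en_objective(T, y, sk.coef_, sk.intercept_, lam, alpha)
        assert fit.objectives[0] <= obj_sk + 1e-8

    def test_unpenalized_covariates_switch(self, rng):
        n = 80
        T = _std(rng.standard_normal((n, 6)))
        C = _std(rng.standard_normal((n, 2)))
        y = C @ np.array([1.0, -2.0]) + rng.standard_normal(n)
        lm = ptrs.lambda_max(y, np.column_stack([T, C]), n_subsample=None)
        fit = ptrs.fit_elastic_net_path(
            y, T, C, grid=np.array([2.0 * lm]), penalize_covariates=False
        )
        assert np.all(fit.coefs[0, :6] == 0)
        X1 = np.column_stack([np.ones(n), C])
        ols = np.linalg.lstsq(X1, y, rcond=None)[0]
        assert np.abs(fit.coefs[0, 6:] - ols[1:]).max() < 1e-5

    def test_mini_batch_reaches_full_batch_solution(self, rng):
        y, T = self._problem(rng)
        grid = ptrs.lambda_grid(ptrs.lambda_max(y, T, n_subsample=None), n=5)
        a = ptrs.fit_elastic_net_path(y, T, None, grid=grid)
        b = ptrs.fit_elastic_net_path(y, T, None, grid=grid, batch_size=32)
        assert np.allclose(a.objectives, b.objectives, rtol=1e-6)


class TestSelectNondegenerate:
    def test_zero_path_yields_empty_selection(self, caplog):
        fit = ptrs.ElasticNetFit(
            lambdas=np.array([1.0, 0.5]), alpha=0.1, intercepts=np.zeros(2),
            coefs=np.zeros((2, 3)), objectives=np.zeros(2),
            n_iters=np.zeros(2, int), converged=np.ones(2, bool),
            n_transcriptome=3, feature_ids=["g0", "g1", "g2"],
        )
        with caplog.at_level("WARNING"):
            path = ptrs.select_nondegenerate(fit)
        assert path.hyperparameters == [] and "non-degenerate" in caplog.text

    def test_strong_signal_keeps_exactly_eleven(self, rng):
        n, m = 300, 40
        T = _std(rng.standard_normal((n, m)))
        y = T @ (rng.standard_normal(m) * 0.5) + 0.3 * rng.standard_normal(n)
        fit = ptrs.fit_elastic_net_path(
            y, T, None, grid=ptrs.lambda_grid(ptrs.lambda_max(y, T, n_subsample=None))
        )
        path = ptrs.select_nondegenerate(fit, k=11)
        assert len(path.hyperparameters) == 11
        assert path.hyperparameters == sorted(path.hyperparameters, reverse=True)


class TestPredixcan:
    def test_strongest_gene_has_smallest_p(self, rng):
        T = _pe(_std(rng.standard_normal((200, 15))))
        y = 3.0 * T.values[:, 4] + 0.1 * rng.standard_normal(200)
        res = ptrs.predixcan_assoc(T, _pheno(y), "trait")
        assert res.loc[res["p"].idxmin(), "gene"] == "g4"

    def test_permutation_null_uniform(self, rng):
        T = _pe(_std(rng.standard_normal((100, 5))))
        ps = []
        for _ in range(100):
            y = rng.permutation(rng.standard_normal(100))
            ps.extend(ptrs.predixcan_assoc(T, _pheno(y), "trait")["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shares_gwas_regression_engine(self):
        # the PrediXcan association is literally the GWAS marginal engine
        assert ptrs.marginal_regression is prs.marginal_regression


class TestGeneClump:
    def test_duplicate_gene_keeps_more_significant(self, rng):
        x = rng.standard_normal(100)
        T = _pe(np.column_stack([x, x]))
        assocs = pd.DataFrame({"gene": ["g0", "g1"], "beta": [1, 1], "se": [1, 1],
                               "p": [1e-5, 1e-3]})
        assert ptrs.gene_clump(assocs, T) == ["g0"]

    def test_uncorrelated_genes_all_kept(self, rng):
        T = _pe(_std(rng.standard_normal((500, 8))))
        assocs = pd.DataFrame({"gene": [f"g{j}" for j in range(8)], "beta": 1.0,
                               "se": 1.0, "p": rng.uniform(size=8)})
        assert len(ptrs.gene_clump(assocs, T)) == 8

    def test_kept_set_max_r2_below_threshold(self, rng):
        # block-correlated expression
        n, blocks, per = 300, 10, 4
        cols = []
        for b in range(blocks):
            f = rng.standard_normal(n)
            for _ in range(per):
                cols.append(np.sqrt(0.7) * f + np.sqrt(0.3) * rng.standard_normal(n))
        T = _pe(_std(np.column_stack(cols)))
        assocs = pd.DataFrame({"gene": T.feature_ids, "beta": 1.0, "se": 1.0,
                               "p": rng.uniform(size=blocks * per)})
        kept = ptrs.gene_clump(assocs, T)
        idx = [T.feature_ids.index(g) for g in kept]
        corr = np.corrcoef(T.values[:, idx], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert (corr**2).max() < 0.1


class TestCtPath:
    def _assoc(self):
        return pd.DataFrame(
            {"gene": ["g0", "g1", "g2"], "beta": [0.3, -1.0, 0.2], "se": 1.0,
             "p": [1e-7, 0.02, 0.9]}
        )

    def test_thirteen_thresholds_and_nesting(self):
        path = ptrs.build_ptrs_ct_path(self._assoc(), ["g0", "g1", "g2"])
        assert len(path.hyperparameters) == 13
        for t1, t2 in zip(path.hyperparameters, path.hyperparameters[1:]):
            assert set(path.support(t1)) <= set(path.support(t2))
        assert path.support(1.0) == ["g0", "g1", "g2"]

    def test_weights_are_predixcan_betas(self):
        path = ptrs.build_ptrs_ct_path(self._assoc(), ["g0", "g1"])
        assert path.weights[1.0]["g1"] == pytest.approx(-1.0)
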