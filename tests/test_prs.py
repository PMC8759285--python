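import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrs_kit import io_formats as io
from ptrs_kit import prs
from ptrs_kit.simulate import SimConfig, simulate_cohort
from oracles import ols_variant_stats


def _geno(dosages):
    d = np.asarray(dosages, float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(d.shape[1])],
            "chrom": "1",
            "pos": np.arange(d.shape[1]) * 1000 + 1,
            "ref": "A",
            "effect": "G",
        }
    )
    return io.GenotypeMatrix([f"s{i}" for i in range(d.shape[0])], variants, d)


def _pheno(y, C=None, ids=None):
    n = len(y)
    tab = pd.DataFrame({"trait": y}, index=pd.Index(ids or [f"s{i}" for i in range(n)], name="sample_id"))
    cov_cols = []
    if C is not None:
        for k in range(C.shape[1]):
            tab[f"c{k}"] = C[:, k]
            cov_cols.append(f"c{k}")
    return io.PhenotypeTable(tab, ["trait"], cov_cols)


class TestRunGwas:
    def test_near_noiseless_recovers_effect(self, rng):
        d = rng.binomial(2, 0.4, 200).astype(float)
        y = 2.0 * d + rng.standard_normal(200) * 1e-6
        res = prs.run_gwas(_geno(d[:, None]), _pheno(y), "trait")
        assert res["beta"].iloc[0] == pytest.approx(2.0, abs=1e-6)
        assert res["p"].iloc[0] < 1e-100

    def test_matches_full_design_ols_oracle(self, rng):
        n = 80
        D = rng.binomial(2, rng.uniform(0.1, 0.5, 5), size=(n, 5)).astype(float)
        C = rng.standard_normal((n, 3))
        y = D[:, 0] * 0.5 + C @ np.array([1.0, -1.0, 0.3]) + rng.standard_normal(n)
        res = prs.run_gwas(_geno(D), _pheno(y, C), "trait")
        for j in range(5):
            b, se, p = ols_variant_stats(y, C, D[:, j])
            assert res["beta"].iloc[j] == pytest.approx(b, abs=1e-10)
            assert res["se"].iloc[j] == pytest.approx(se, abs=1e-10)
            assert res["p"].iloc[j] == pytest.approx(p, rel=1e-8)

    def test_null_pvalues_uniform(self, rng):
        n, p = 400, 300
        D = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = rng.standard_normal(n)
        res = prs.run_gwas(_geno(D), _pheno(y), "trait")
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_variant_skipped(self, rng, caplog):
        D = np.column_stack([np.full(50, 1.0), rng.binomial(2, 0.5, 50).astype(float)])
        with caplog.at_level("INFO"):
            res = prs.run_gwas(_geno(D), _pheno(rng.standard_normal(50)), "trait")
        assert list(res["variant_id"]) == ["v1"]


class TestFilterVariants:
    def _assoc(self, maf, hwe):
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(maf))], "chrom": "1",
             "pos": range(len(maf)), "beta": 0.0, "se": 1.0, "p": 0.5,
             "maf": maf, "hwe_p": hwe}
        )

    def test_maf_below_cutoff_removed(self):
        out = prs.filter_variants(self._assoc([0.0005, 0.001, 0.2], [1, 1, 1]))
        assert list(out["variant_id"]) == ["v1", "v2"]

    def test_monomorphic_removed(self):
        out = prs.filter_variants(self._assoc([0.0, 0.3], [1, 1]))
        assert list(out["variant_id"]) == ["v1"]

    def test_hwe_outlier_removed(self):
        out = prs.filter_variants(self._assoc([0.3, 0.3], [1e-12, 1e-9]))
        assert list(out["variant_id"]) == ["v1"]

    def test_perfect_equilibrium_counts_retained(self):
        calls = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        hwe = prs.hwe_pvalues(calls[:, None])
        assert hwe[0] == pytest.approx(1.0)

    def test_extreme_disequilibrium_detected(self):
        calls = np.full(500, 1.0)  # all heterozygous
        hwe = prs.hwe_pvalues(calls[:, None])
        assert hwe[0] < 1e-10


class TestLdClump:
    def test_hand_traced_greedy_example(self, rng):
        n = 2000
        a = rng.binomial(1, 0.5, n).astype(float) + rng.binomial(1, 0.5, n)
        # b correlated with a (r^2 about 0.5), c independent
        mask = rng.random(n) < 0.72
        b = np.where(mask, a, rng.binomial(2, 0.5, n)).astype(float)
        c = rng.binomial(2, 0.5, n).astype(float)
        G = _geno(np.column_stack([a, b, c]))
        r2_ab = np.corrcoef(a, b)[0, 1] ** 2
        assert 0.3 < r2_ab < 0.7
        assoc = pd.DataFrame(
            {"variant_id": ["v0", "v1", "v2"], "chrom": "1", "pos": [1, 1001, 2001],
             "p": [1e-8, 1e-6, 1e-4]}
        )
        assert prs.ld_clump(assoc, G) == ["v0", "v2"]

    def test_independent_variants_all_kept(self, rng):
        D = rng.binomial(2, 0.5, size=(3000, 10)).astype(float)
        G = _geno(D)
        assoc = pd.DataFrame(
            {"variant_id": [f"v{j}" for j in range(10)], "chrom": "1",
             "pos": np.arange(10) * 1000 + 1, "p": rng.uniform(size=10)}
        )
        assert len(prs.ld_clump(assoc, G)) == 10

    def test_kept_set_satisfies_r2_bound_exhaustively(self):
        cfg = SimConfig(n_per_population=500, n_variants=150, n_genes=10,
                        ld_rho=0.9, seed=31, variant_spacing_bp=1000)
        co = simulate_cohort(cfg)
        G = co.genotypes["pop1"]
        ph = co.phenotypes["pop1"]
        assoc = prs.run_gwas(G, ph, "trait")
        kept = prs.ld_clump(assoc, G)
        assert len(kept) < G.n_variants  # LD actually pruned something
        D = G.mean_imputed()
        idx = {v: j for j, v in enumerate(G.variants["variant_id"])}
        pos = G.variants.set_index("variant_id")["pos"]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if abs(pos[a] - pos[b]) <= 250_000:
                    r2 = np.corrcoef(D[:, idx[a]], D[:, idx[b]])[0, 1] ** 2
                    assert r2 <= 0.1 + 1e-12

    def test_input_order_invariance(self, rng):
        D = rng.binomial(2, 0.5, size=(500, 20)).astype(float)
        G = _geno(D)
        assoc = pd.DataFrame(
            {"variant_id": [f"v{j}" for j in range(20)], "chrom": "1",
             "pos": np.arange(20) * 1000 + 1, "p": rng.uniform(size=20)}
        )
        a = prs.ld_clump(assoc, G)
        b = prs.ld_clump(assoc.sample(frac=1, random_state=5), G)
        assert a == b


class TestPrsPath:
    def _assoc(self):
        return pd.DataFrame(
            {"variant_id": ["v0", "v1", "v2"], "chrom": "1", "pos": [1, 2, 3],
             "beta": [0.5, -0.25, 1.0], "se": 1.0, "p": [1e-9, 1e-4, 0.2],
             "maf": 0.3, "hwe_p": 1.0}
        )

    def test_threshold_semantics_and_nesting(self):
        path = prs.build_prs_path(self._assoc(), ["v0", "v1", "v2"])
        assert len(path.hyperparameters) == 11
        assert path.support(5e-8) == ["v0"]
        assert path.support(1.0) == ["v0", "v1", "v2"]
        sizes = [len(path.support(t)) for t in path.hyperparameters]
        assert sizes == sorted(sizes)
        for t1, t2 in zip(path.hyperparameters, path.hyperparameters[1:]):
            assert set(path.support(t1)) <= set(path.support(t2))

    def test_empty_threshold_scores_zero(self):
        assoc = self._assoc()
        assoc["p"] = [1e-4, 1e-3, 0.2]
        path = prs.build_prs_path(assoc, list(assoc["variant_id"]))
        G = _geno(np.array([[1.0, 2.0, 0.0]]))
        sc = prs.score(G, path)
        assert sc[5e-8].iloc[0] == 0.0

    def test_json_round_trip_exact(self, tmp_path):
        path = prs.build_prs_path(self._assoc(), ["v0", "v1"])
        path.to_json(tmp_path / "p.json")
        back = prs.ScorePath.from_json(tmp_path / "p.json")
        assert back.hyperparameters == path.hyperparameters
        for hp in path.hyperparameters:
            pd.testing.assert_series_equal(
                back.weights[hp], path.weights[hp], check_names=False
            )


class TestScore:
    def test_dot_product_example(self):
        path = prs.ScorePath(
            "variant", [1.0], {1.0: pd.Series({"v0": 0.5, "v1": -0.25})}
        )
        sc = prs.score(_geno(np.array([[2.0, 1.0]])), path)
        assert sc[1.0].iloc[0] == pytest.approx(0.75)

    def test_matches_naive_loop(self, rng):
        from oracles import naive_score

        D = rng.binomial(2, 0.4, size=(20, 6)).astype(float)
        G = _geno(D)
        w = pd.Series(rng.standard_normal(4), index=["v0", "v2", "v3", "v5"])
        path = prs.ScorePath("variant", [0.5], {0.5: w})
        sc = prs.score(G, path)
        oracle = naive_score(D, [f"v{j}" for j in range(6)], w)
        assert np.allclose(sc[0.5].to_numpy(), oracle, atol=1e-12)

    def test_linearity(self, rng):
        D = rng.binomial(2, 0.4, size=(30, 4)).astype(float)
        G = _geno(D)
        w = pd.Series(rng.standard_normal(4), index=[f"v{j}" for j in range(4)])
        a = prs.score(G, prs.ScorePath("variant", [1.0], {1.0: w}))
        b = prs.score(G, prs.ScorePath("variant", [1.0], {1.0: 2.0 * w}))
        assert np.allclose(2 * a.to_numpy(), b.to_numpy())

    def test_low_coverage_warning(self, rng, caplog):
        D = rng.binomial(2, 0.4, size=(10, 1)).astype(float)
        G = _geno(D)
        w = pd.Series({"v0": 0.1, "missing1": 5.0, "missing2": 3.0})
        with caplog.at_level("WARNING"):
            prs.score(G, prs.ScorePath("variant", [1.0], {1.0: w}))
        assert "weight mass unmatched" in caplog.text


def test_gwas_effect_ranking_tracks_truth():
    """|b̂| should rank-correlate with the true direct effect sizes."""
    cfg = SimConfig(
        n_per_population=2000, n_variants=300, n_genes=30, mediated_h2=0.0,
        direct_h2=0.5, n_causal_variants=50, seed=41, population_labels=("pop1",),
        n_genotype_pcs=0,
    )
    co = simulate_cohort(cfg)
    assoc = prs.run_gwas(co.genotypes["pop1"], co.phenotypes["pop1"], "trait")
    truth = co.truth.variant_effects["pop1"]
    sub = assoc.set_index("variant_id").loc[truth.index]
    rho = stats.spearmanr(np.abs(sub["beta"]), np.abs(truth)).statistic
    assert rho > 0.5
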