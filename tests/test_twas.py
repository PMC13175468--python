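"""TWAS components: HWE chi-square, QC filters, cis-window selection,
residualization, elastic-net models, and the summary-statistic Z score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcratl.twas import (
    ExpressionModel,
    QcConfig,
    bonferroni_report,
    cis_predictors,
    filter_models,
    hwe_test,
    qc_filter,
    residualize_expression,
    train_expression_model,
    twas_z,
    TwasResult,
)


class TestHwe:
    def test_exact_equilibrium(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        # chi-square = n = 100 exactly; P ~ 1.5e-23
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(float(stats.chi2.sf(100, 1)), rel=1e-12)
        assert p < 1e-6

    def test_monomorphic_cannot_depart(self):
        assert hwe_test(100, 0, 0) == 1.0
        assert hwe_test(0, 0, 77) == 1.0

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)


class TestQcFilter:
    def _geno(self):
        rng = np.random.default_rng(0)
        n = 400
        cols = {
            "ok": rng.binomial(2, 0.3, n).astype(float),
            "rare": rng.binomial(2, 0.004, n).astype(float),
            "missing": rng.binomial(2, 0.3, n).astype(float),
            "hwe_bad": np.concatenate([np.zeros(n // 2), np.full(n // 2, 2.0)]),
        }
        cols["missing"][: int(0.15 * n)] = np.nan
        return pd.DataFrame(cols)

    def test_rules_and_reasons(self):
        passing, log = qc_filter(self._geno())
        assert passing == ["ok"]
        reasons = dict(zip(log["variant"], log["reasons"]))
        assert "maf" in reasons["rare"]
        assert "missingness" in reasons["missing"]
        assert "hwe" in reasons["hwe_bad"]

    def test_idempotent(self):
        g = self._geno()
        passing, _ = qc_filter(g)
        passing2, log2 = qc_filter(g[passing])
        assert passing2 == passing and log2.empty

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            QcConfig(maf_min=0.0)


class TestCisPredictors:
    variants = pd.DataFrame({
        "id": ["v1", "v2", "v3", "v4"],
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "pos": [1_000_000, 2_000_000, 3_000_001, 2_000_000],
    })

    def test_window_bound_is_closed(self):
        # TSS 2,000,000: v1 is exactly 1 Mb away -> included
        ids = cis_predictors("chr1", 2_000_000, self.variants, None)
        assert ids == ["v1", "v2"]

    def test_other_chromosome_excluded(self):
        ids = cis_predictors("chr2", 2_000_000, self.variants, None)
        assert ids == ["v4"]

    def test_prioritized_set_restriction(self):
        ids = cis_predictors("chr1", 2_000_000, self.variants, {"v2"})
        assert ids == ["v2"]

    def test_matches_distance_scan_oracle(self):
        rng = np.random.default_rng(1)
        v = pd.DataFrame({
            "id": [f"v{i}" for i in range(500)],
            "chrom": rng.choice(["chr1", "chr2"], 500),
            "pos": rng.integers(1, 5_000_000, 500),
        })
        tss = 2_500_000
        got = set(cis_predictors("chr1", tss, v, None))
        brute = {r.id for r in v.itertuples() if r.chrom == "chr1"
                 and abs(r.pos - tss) <= 1e6}
        assert got == brute

    def test_superset_monotonicity(self):
        small = set(cis_predictors("chr1", 2_000_000, self.variants, {"v1"}))
        big = set(cis_predictors("chr1", 2_000_000, self.variants, {"v1", "v2"}))
        assert small <= big


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(residualize_expression(y, None), y - 3.0)

    def test_exact_linear_gives_zero(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(50, 3))
        y = C @ [1.0, -2.0, 0.5] + 4.0
        assert np.abs(residualize_expression(y, C)).max() < 1e-8

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        r = residualize_expression(y, C)
        assert np.abs(C.T @ r).max() < 1e-8

    def test_rank_deficiency_rejected(self):
        C = np.ones((20, 2))
        with pytest.raises(ValueError):
            residualize_expression(np.zeros(20), C)


class TestExpressionModel:
    def _data(self, n=500, p=10, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        geno = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
        return geno

    def test_planted_signal_recovered(self):
        geno = self._data()
        y = 2.0 * geno["v0"].to_numpy() + np.random.default_rng(5).normal(0, 0.1, 500)
        m = train_expression_model(geno, y, list(geno.columns), "g", seed=0)
        assert m.cv_r2 > 0.9
        assert abs(m.weights.get("v0", 0.0)) > 2 * m.weights.drop("v0", errors="ignore").abs().max()

    def test_null_expression_low_cv_r2(self):
        fails = 0
        for seed in range(6):
            geno = self._data(n=200, p=20, seed=10 + seed)
            y = np.random.default_rng(20 + seed).normal(size=200)
            m = train_expression_model(geno, y, list(geno.columns), "g", seed=seed)
            fails += m.cv_r2 >= 0.05
        assert fails <= 1

    def test_deterministic_under_seed(self):
        geno = self._data()
        y = geno["v1"].to_numpy() + np.random.default_rng(6).normal(0, 0.5, 500)
        m1 = train_expression_model(geno, y, list(geno.columns), "g", seed=3)
        m2 = train_expression_model(geno, y, list(geno.columns), "g", seed=3)
        pd.testing.assert_series_equal(m1.weights, m2.weights)
        assert m1.cv_r2 == m2.cv_r2

    def test_too_few_predictors_rejected(self):
        geno = self._data(p=1)
        with pytest.raises(ValueError):
            train_expression_model(geno, np.zeros(500), ["v0"], "g")


class TestFilterModels:
    def _model(self, r2):
        return ExpressionModel("g", 0, "chr1", pd.Series(dtype=float), r2,
                               pd.Series(dtype=float), 0.0, 1.0)

    def test_boundary_is_strict(self):
        kept = filter_models([self._model(0.01), self._model(0.0100001),
                              self._model(0.5)])
        assert [m.cv_r2 for m in kept] == [0.0100001, 0.5]


class TestTwasZ:
    def _single(self, w, sigma_i=1.3):
        weights = pd.Series({"v0": w})
        sigma = pd.Series({"v0": sigma_i})
        sigma_g = abs(w) * sigma_i  # sqrt(w^2 * sigma_i^2)
        return ExpressionModel("g", 0, "chr1", weights, 0.5, sigma, sigma_g, 1.0)

    def test_single_predictor_identity(self):
        ss = pd.DataFrame({"id": ["v0"], "beta": [0.12], "se": [0.03]})
        for w in (0.7, -0.4):
            res = twas_z(self._single(w), ss)
            assert res.z == pytest.approx(np.sign(w) * 0.12 / 0.03, rel=1e-12)

    def test_all_beta_zero(self):
        ss = pd.DataFrame({"id": ["v0"], "beta": [0.0], "se": [0.05]})
        res = twas_z(self._single(1.0), ss)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_two_predictor_hand_case(self):
        w = pd.Series({"a": 0.5, "b": -0.25})
        rng = np.random.default_rng(7)
        G = pd.DataFrame({"a": rng.binomial(2, 0.3, 200).astype(float),
                          "b": rng.binomial(2, 0.4, 200).astype(float)})
        sigma_i = G.std(ddof=1)
        Sigma = np.cov(G.to_numpy(), rowvar=False, ddof=1)
        sigma_g = float(np.sqrt(w.to_numpy() @ Sigma @ w.to_numpy()))
        model = ExpressionModel("g", 0, "chr1", w, 0.3, sigma_i, sigma_g, 1.0)
        ss = pd.DataFrame({"id": ["a", "b"], "beta": [0.1, -0.05], "se": [0.02, 0.04]})
        res = twas_z(model, ss, reference_genotypes=G)
        expected = (0.5 * sigma_i["a"] / sigma_g * (0.1 / 0.02)
                    + (-0.25) * sigma_i["b"] / sigma_g * (-0.05 / 0.04))
        assert res.z == pytest.approx(expected, rel=1e-12)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(expected)), rel=1e-12)

    def test_missing_predictor_dropped_with_warning(self):
        w = pd.Series({"a": 0.5, "b": -0.25})
        rng = np.random.default_rng(8)
        G = pd.DataFrame({"a": rng.binomial(2, 0.3, 100).astype(float),
                          "b": rng.binomial(2, 0.4, 100).astype(float)})
        model = ExpressionModel("g", 0, "chr1", w, 0.3, G.std(ddof=1), 1.0, 1.0)
        ss = pd.DataFrame({"id": ["a"], "beta": [0.1], "se": [0.02]})
        with pytest.warns(UserWarning, match="dropped"):
            res = twas_z(model, ss, reference_genotypes=G)
        assert res.dropped == ["b"] and res.n_predictors == 1


class TestBonferroni:
    def _res(self, gene, p):
        return TwasResult(gene, 1.0, p, 1, [])

    def test_single_gene(self):
        out = bonferroni_report([self._res("g", 0.04)])
        assert bool(out["significant"].iloc[0])

    def test_hundred_gene_threshold_arithmetic(self):
        results = [self._res(f"g{i}", 0.5) for i in range(99)] + [self._res("gx", 0.0006)]
        out = bonferroni_report(results)
        # 0.0006 > 0.05/100 = 0.0005 -> NOT significant
        assert not out.loc[out["gene"] == "gx", "significant"].iloc[0]
        out2 = bonferroni_report(results[:-1] + [self._res("gx", 0.0004)])
        assert bool(out2.loc[out2["gene"] == "gx", "significant"].iloc[0])

    def test_no_testable_genes_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_report([TwasResult("g", np.nan, np.nan, 0, [], untestable=True)])
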