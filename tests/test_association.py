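import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omibone.association import (
    MetaboliteImputer,
    ZeroSumElasticNet,
    adjusted_linear_model,
    bh_fdr,
    partial_spearman,
    pls_vip,
)
from omibone.simulate import generate_reference_pairs


class TestZeroSumElasticNet:
    def test_huge_l1_gives_zero_vector(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        res = ZeroSumElasticNet(X, y).fit(1e9, 1.0)
        assert (res.params == 0).all()

    def test_p2_matches_grid_oracle(self):
        # Σβ = 0 forces β2 = -β1: 1-D brute force over the objective
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 2))
        X[:, 1] = -0.3 * X[:, 0] + rng.standard_normal(50)
        y = X @ np.array([1.0, -1.0]) + 0.5 * rng.standard_normal(50)
        res = ZeroSumElasticNet(X, y).fit(5.0, 2.0)
        Xc, yc = X - X.mean(0), y - y.mean()
        grid = np.linspace(-3, 3, 60001)
        oracle = min(
            float(((yc - Xc @ np.array([b, -b])) ** 2).sum()
                  + 5.0 * 2 * abs(b) + 2.0 * 2 * b * b)
            for b in grid
        )
        assert res.objective <= oracle + 1e-4

    def test_p3_matches_constrained_grid_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        y = X @ np.array([0.8, -0.8, 0.0]) + 0.3 * rng.standard_normal(50)
        res = ZeroSumElasticNet(X, y).fit(3.0, 1.0)
        Xc, yc = X - X.mean(0), y - y.mean()
        grid = np.linspace(-2, 2, 161)
        oracle = np.inf
        for b1 in grid:
            for b2 in grid:
                b = np.array([b1, b2, -b1 - b2])
                o = float(((yc - Xc @ b) ** 2).sum()
                          + 3.0 * np.abs(b).sum() + float(b @ b))
                oracle = min(oracle, o)
        assert res.objective <= oracle + 1e-4

    def test_zero_sum_holds_exactly(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 12))
        y = rng.standard_normal(80)
        res = ZeroSumElasticNet(X, y).fit(0.5, 0.1)
        assert abs(res.params.sum()) < 1e-8

    def test_cv_recovers_planted_support(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 40))
        X -= X.mean(axis=1, keepdims=True)
        beta = np.zeros(40)
        beta[:3], beta[3:6] = 0.9, -0.9
        y = X @ beta + rng.standard_normal(300)
        res = ZeroSumElasticNet(X, y).fit_cv(cv=5, seed=0)
        assert set(range(6)) <= set(res.selected)
        assert res.cv_table.shape[0] == 50

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ZeroSumElasticNet(np.array([[1.0, np.nan]]), np.array([1.0]))

    def test_summary_mentions_selection(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 4))
        y = X[:, 0] - X[:, 1] + 0.1 * rng.standard_normal(40)
        s = ZeroSumElasticNet(X, y).fit(0.5, 0.5).summary()
        assert "Zero-sum elastic net" in s and "selected" in s


class TestPartialSpearman:
    def test_reduces_to_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        rho, _ = partial_spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        z = rng.standard_normal(50)
        r1, p1 = partial_spearman(x, y, z)
        r2, p2 = partial_spearman(np.exp(x), y, z)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_confounder_only_association_removed(self):
        # x and y related only through z: adjusted rho is near zero
        for s in range(20):
            rng = np.random.default_rng(s)
            z = rng.standard_normal(2000)
            x = z + rng.standard_normal(2000)
            y = z + rng.standard_normal(2000)
            rho, _ = partial_spearman(x, y, z)
            assert abs(rho) < 0.08

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.standard_normal(80)
        z = rng.standard_normal((80, 2))
        y = x + z @ [0.5, -0.5] + rng.standard_normal(80)
        rho, p = partial_spearman(x, y, z)
        frame = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(frame, x="x", y="y", covar=["z1", "z2"],
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(20), np.arange(20.0))


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_identity(self):
        assert bh_fdr([0.07])[0] == pytest.approx(0.07)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        order = np.argsort(p)
        fdr = bh_fdr(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        assert (fdr >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPlsVip:
    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 1))
        y = x[:, 0] + 0.1 * rng.standard_normal(50)
        res = pls_vip(x, y, n_components=1)
        assert res.vip.iloc[0] == pytest.approx(1.0)

    def test_squared_vips_sum_to_feature_count(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 9))
        y = X @ rng.standard_normal(9) + rng.standard_normal(60)
        res = pls_vip(X, y, n_components=3)
        assert float((res.vip**2).sum()) == pytest.approx(9.0, abs=1e-8)

    def test_planted_feature_attains_max_vip_above_two(self):
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((500, 21))
            y = X[:, 0] + 0.5 * rng.standard_normal(500)
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            res = pls_vip(Xs, y, seed=s)
            assert res.vip.idxmax() == 0
            assert res.vip.iloc[0] > 2.0

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pls_vip(np.random.default_rng(0).standard_normal((20, 3)),
                    np.ones(20))


class TestAdjustedLinearModel:
    def test_standardized_slope_equals_pearson_r(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        y = 0.4 * x + rng.standard_normal(100)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        beta, _ = adjusted_linear_model(xs, ys)
        assert beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_duplicated_covariate_raises(self):
        x = np.arange(10.0)
        y = x + 1
        with pytest.raises(ValueError, match="rank"):
            adjusted_linear_model(x, y, covariates=x)

    def test_eight_point_normal_equations(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        z = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.8, 12.1, 14.0, 16.2])
        design = np.column_stack([np.ones(8), x, z])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        beta, _ = adjusted_linear_model(x, y, z)
        assert beta == pytest.approx(coef[1], abs=1e-10)


class TestImputer:
    def test_noiseless_linear_metabolites_perfectly_retained(self):
        ref = generate_reference_pairs(n_ref=60, n_genes=40,
                                       n_fecal_metabolites=12, seed=1,
                                       noise_sd=0.0)
        model = MetaboliteImputer.train(ref.genes, ref.metabolites, seed=0)
        linear = ref.linear_mask[ref.linear_mask].index
        assert (model.training_rho[linear] > 0.95).all()
        assert set(linear) <= set(model.retained)

    def test_pure_noise_rarely_retained(self):
        kept = []
        for s in range(10):
            ref = generate_reference_pairs(n_ref=155, n_genes=40,
                                           n_fecal_metabolites=10, seed=s,
                                           frac_linear=0.0)
            model = MetaboliteImputer.train(ref.genes, ref.metabolites, seed=s)
            kept.append(len(model.retained) / 10)
        assert np.mean(kept) < 0.05

    def test_prediction_is_the_linear_map(self):
        ref = generate_reference_pairs(n_ref=40, n_genes=20,
                                       n_fecal_metabolites=8, seed=2,
                                       noise_sd=0.1)
        model = MetaboliteImputer.train(ref.genes, ref.metabolites, seed=0)
        pred = model.predict(ref.genes)
        W = model.weights.loc[:, pred.columns].to_numpy()
        expected = ref.genes.to_numpy() @ W + model.intercepts[pred.columns].to_numpy()
        np.testing.assert_allclose(pred.to_numpy(), expected, atol=1e-10)

    def test_doubled_genes_shift_predictions_linearly(self):
        ref = generate_reference_pairs(n_ref=40, n_genes=20,
                                       n_fecal_metabolites=6, seed=3,
                                       noise_sd=0.1)
        model = MetaboliteImputer.train(ref.genes, ref.metabolites, seed=0)
        base = model.predict(ref.genes)
        doubled = model.predict(2.0 * ref.genes)
        shift = ref.genes.to_numpy() @ model.weights.loc[:, base.columns].to_numpy()
        np.testing.assert_allclose(
            doubled.to_numpy() - base.to_numpy(), shift, atol=1e-10
        )

    def test_missing_genes_warn_and_zero_fill(self):
        ref = generate_reference_pairs(n_ref=40, n_genes=10,
                                       n_fecal_metabolites=4, seed=4,
                                       noise_sd=0.0)
        model = MetaboliteImputer.train(ref.genes, ref.metabolites, seed=0)
        partial = ref.genes.iloc[:, :5]
        with pytest.warns(UserWarning, match="zero-filled"):
            model.predict(partial)
        with pytest.raises(ValueError, match="overlapping"):
            model.predict(ref.genes.rename(columns=lambda c: "x" + c))

    def test_too_few_reference_samples_rejected(self):
        ref = generate_reference_pairs(n_ref=5, n_genes=4,
                                       n_fecal_metabolites=3, seed=0)
        with pytest.raises(ValueError, match="10 reference"):
            MetaboliteImputer.train(ref.genes, ref.metabolites)
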