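"""Weight training: model fits, cross-validation, selection, ImpG weights."""

import numpy as np
import pytest

from sumtwas import (
    ArchitectureConfig,
    CisWeightsRegressor,
    InputError,
    LocusConfig,
    UntestableGeneError,
    cross_validate,
    fit_model,
    marginal_impg_weights,
    select_model,
    simulate_expression,
    simulate_genotypes,
    train_weight_set,
)


class TestFitModel:
    def test_noiseless_single_eqtl_lasso_puts_mass_on_that_snp(self, small_panel):
        expr = small_panel.standardized()[:, 3]
        w = fit_model(small_panel, expr, "lasso", random_state=0)
        assert w[3] > 0.9
        others = np.delete(np.abs(w), 3)
        assert others.max() < 0.05

    def test_null_expression_lasso_shrinks_to_zero(self, small_panel, rng):
        expr = rng.standard_normal(small_panel.n_individuals)
        w = fit_model(small_panel, expr, "lasso", random_state=0)
        assert np.abs(w).max() < 0.02

    def test_top1_selects_best_marginal_eqtl(self, small_panel, rng):
        x = small_panel.standardized()
        expr = 0.8 * x[:, 5] + 0.2 * rng.standard_normal(small_panel.n_individuals)
        w = fit_model(small_panel, expr, "top1")
        assert np.count_nonzero(w) == 1 and w[5] != 0

    @pytest.mark.parametrize("model", ["lasso", "enet", "blup_ridge", "top1"])
    def test_weights_invariant_to_affine_rescaling_of_expression(
        self, small_panel, model, rng
    ):
        x = small_panel.standardized()
        expr = x[:, 2] - 0.5 * x[:, 7] + rng.standard_normal(small_panel.n_individuals)
        w1 = fit_model(small_panel, expr, model, random_state=1)
        w2 = fit_model(small_panel, 3.7 * expr - 11.0, model, random_state=1)
        assert np.allclose(w1, w2, atol=1e-10)

    def test_single_replicate_recovery_is_reasonable(self):
        cfg = LocusConfig(n_snps=20, ld_rho=0.3, seed=31)
        panel = simulate_genotypes(cfg, 500)
        arch = ArchitectureConfig(n_causal_eqtl=3, cis_h2=0.5, scenario="A")
        expr, w_true, _ = simulate_expression(panel, arch, seed=31)
        w_hat = fit_model(panel, expr, "lasso", random_state=31)
        assert np.corrcoef(w_true, w_hat)[0, 1] > 0.6

    def test_unknown_model_rejected(self, small_panel, rng):
        with pytest.raises(InputError):
            fit_model(small_panel, rng.standard_normal(small_panel.n_individuals), "bslmm")


class TestCrossValidate:
    def test_noiseless_single_eqtl_gives_cv_r2_near_one(self, small_panel):
        expr = small_panel.standardized()[:, 3]
        assert cross_validate(small_panel, expr, "lasso") > 0.98

    def test_null_expression_gives_cv_r2_near_zero(self, small_panel, rng):
        expr = rng.standard_normal(small_panel.n_individuals)
        assert cross_validate(small_panel, expr, "lasso") < 0.05

    def test_mean_cv_r2_tracks_cis_h2(self):
        # at cis_h2=0.5 the CV R² of the lasso should land just below the
        # heritability ceiling
        arch = ArchitectureConfig(n_causal_eqtl=3, cis_h2=0.5, scenario="A")
        r2s = []
        for seed in range(20):
            cfg = LocusConfig(n_snps=20, ld_rho=0.3, seed=seed)
            panel = simulate_genotypes(cfg, 500)
            expr, _, _ = simulate_expression(panel, arch, seed=seed)
            r2s.append(cross_validate(panel, expr, "lasso", n_folds=5, random_state=seed))
        mean = np.mean(r2s)
        assert 0.40 <= mean <= 0.50

    def test_more_individuals_than_folds_required(self, rng):
        cfg = LocusConfig(n_snps=3, seed=1)
        panel = simulate_genotypes(cfg, 4)
        with pytest.raises(InputError):
            cross_validate(panel, rng.standard_normal(4), "top1", n_folds=5)


class TestSelectModel:
    W = np.array([0.0, 1.0])

    def test_argmax_by_cv_r2(self):
        label, r2, _ = select_model([("top1", 0.30, self.W), ("lasso", 0.45, self.W)])
        assert label == "lasso" and r2 == 0.45

    def test_exact_tie_broken_by_precedence(self):
        label, _, _ = select_model([("top1", 0.40, self.W), ("lasso", 0.40, self.W)])
        assert label == "lasso"

    def test_all_below_floor_is_untestable(self):
        with pytest.raises(UntestableGeneError):
            select_model([("lasso", 0.005, self.W), ("top1", -0.2, self.W)])

    def test_all_zero_weights_unusable(self):
        with pytest.raises(UntestableGeneError):
            select_model([("lasso", 0.9, np.zeros(3))])

    def test_selected_cv_r2_at_least_top1(self, small_panel, rng):
        x = small_panel.standardized()
        expr = 0.5 * x[:, 1] + 0.4 * x[:, 8] + rng.standard_normal(
            small_panel.n_individuals
        )
        est = CisWeightsRegressor(model="auto", random_state=0)
        est.fit(small_panel.dosages, expr)
        assert est.cv_r2_ >= est.candidates_["top1"][0]


class TestMarginalImpG:
    def test_identity_ld_reduces_to_marginal_covariances(self, rng):
        n, m = 4000, 6
        x = rng.standard_normal((n, m))
        x = (x - x.mean(0)) / x.std(0)
        y = x[:, 1] * 0.5 + rng.standard_normal(n)
        w = marginal_impg_weights(x, y, ld_ridge=0.0)
        y_std = (y - y.mean()) / y.std()
        cov = x.T @ y_std / n
        # sample LD of independent SNPs is near identity
        assert np.allclose(w, cov, atol=0.05)

    def test_scalar_case_returns_the_covariance(self, rng):
        n = 500
        x = rng.standard_normal((n, 1))
        x = (x - x.mean()) / x.std()
        y = 0.3 * x[:, 0] + rng.standard_normal(n)
        w = marginal_impg_weights(x, y, ld_ridge=0.0)
        y_std = (y - y.mean()) / y.std()
        c = float(x[:, 0] @ y_std / n)
        assert w[0] == pytest.approx(c, abs=1e-10)

    def test_matches_direct_linear_solve(self, small_panel, rng):
        x = small_panel.standardized()[:, :3]
        y = x @ np.array([0.4, -0.2, 0.1]) + rng.standard_normal(x.shape[0])
        y_std = (y - y.mean()) / y.std()
        n = x.shape[0]
        S = x.T @ x / n
        cov = x.T @ y_std / n
        lam = 0.1
        expected = np.linalg.solve(S + lam * np.eye(3), cov)
        w = marginal_impg_weights(x, y, ld_ridge=lam)
        assert np.allclose(w, expected, atol=1e-12)

    def test_zero_ridge_equals_ols(self, small_panel, rng):
        x = small_panel.standardized()
        y = x[:, 0] - x[:, 4] + rng.standard_normal(x.shape[0])
        w = marginal_impg_weights(small_panel, y, ld_ridge=0.0)
        y_std = (y - y.mean()) / y.std()
        ols, *_ = np.linalg.lstsq(x, y_std, rcond=None)
        assert np.allclose(w, ols, atol=1e-8)


class TestTrainWeightSet:
    def test_packaged_winner_carries_metadata(self, small_panel):
        expr = small_panel.standardized()[:, 2]
        wset = train_weight_set(small_panel, expr, gene="G1", tissue="T1")
        assert wset.gene == "G1" and wset.tissue == "T1"
        assert wset.model in ("lasso", "enet", "blup_ridge", "top1")
        assert len(wset.snp_ids) == small_panel.n_snps
        assert wset.cv_r2 > 0.9

    def test_null_gene_marked_untestable(self, small_panel, rng):
        expr = rng.standard_normal(small_panel.n_individuals)
        with pytest.raises(UntestableGeneError):
            train_weight_set(small_panel, expr, gene="G0", tissue="T1")

    def test_sklearn_get_set_params_roundtrip(self):
        est = CisWeightsRegressor(model="lasso", n_folds=3)
        params = est.get_params()
        assert params["model"] == "lasso" and params["n_folds"] == 3
        est.set_params(n_folds=4)
        assert est.n_folds == 4
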