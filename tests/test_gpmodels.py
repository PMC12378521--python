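"""Prediction models: mixed-model-equation, ridge and conjugate oracles."""

import numpy as np
import pytest

import gpeval as gp
from gpeval.gpmodels import _vanraden_blocks


def _toy(n=30, p=100, h2=0.5, seed=0):
    layout = gp.random_layout([("chr1", 10**6)], p, seed=seed)
    g = gp.simulate_genotypes(n, layout, ld_decay=0.0, seed=seed + 1)
    ph = gp.simulate_phenotypes(g, gp.TraitArchitecture(n_qtl=min(20, p), h2=h2, seed=seed + 2))
    return g, ph


class TestGblup:
    def test_matches_dense_mme_solve(self):
        # independent oracle: direct dense solve of the mixed-model equations
        # [[1'1, 1'], [1, I + lam*Ginv]] [mu, u] = [1'y, y]
        g, ph = _toy(30, 100, seed=10)
        x = g.values.astype(float)
        fit = gp.fit_gblup(ph.y, x)
        vc = fit.vc
        gmat = fit.gblup_solution["g_train"]
        lam = vc.sigma_e2 / vc.sigma_g2
        n = 30
        ginv = np.linalg.inv(gmat + 1e-10 * np.eye(n))
        lhs = np.zeros((n + 1, n + 1))
        lhs[0, 0] = n
        lhs[0, 1:] = 1.0
        lhs[1:, 0] = 1.0
        lhs[1:, 1:] = np.eye(n) + lam * ginv
        rhs = np.concatenate([[ph.y.sum()], ph.y])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(fit.gblup_solution["mu"], sol[0], atol=1e-8)
        np.testing.assert_allclose(fit.gblup_solution["u_train"], sol[1:], atol=1e-8)

    def test_equals_ridge_regression_on_markers(self):
        # RR-BLUP equivalence: GEBVs = W beta_ridge with penalty
        # sigma_e2 * denominator / sigma_g2 on training-centered markers
        g, ph = _toy(30, 100, seed=20)
        x = g.values.astype(float)
        fit = gp.fit_gblup(ph.y, x)
        vc, sol = fit.vc, fit.gblup_solution
        w = x - 2.0 * sol["x_train_freq"]
        lam_rr = vc.sigma_e2 * sol["denominator"] / vc.sigma_g2
        beta = np.linalg.solve(w.T @ w + lam_rr * np.eye(100), w.T @ (ph.y - sol["mu"]))
        np.testing.assert_allclose(sol["u_train"], w @ beta, atol=1e-6)

    def test_no_signal_limit(self):
        g, ph = _toy(40, 60, seed=30)
        vc = gp.VarianceComponents(sigma_g2=1e-12, sigma_e2=1.0, loglik=0.0)
        x = g.values.astype(float)
        fit = gp.fit_gblup(ph.y, x, vc=vc)
        assert np.max(np.abs(fit.gblup_solution["u_train"])) < 1e-6
        assert fit.gblup_solution["mu"] == pytest.approx(ph.y.mean(), rel=1e-6)

    def test_shift_invariance(self):
        g, ph = _toy(40, 60, seed=40)
        x = g.values.astype(float)
        f1 = gp.fit_gblup(ph.y, x)
        f2 = gp.fit_gblup(ph.y + 100.0, x)
        np.testing.assert_allclose(
            f1.gblup_solution["u_train"], f2.gblup_solution["u_train"], atol=1e-5
        )
        assert f2.gblup_solution["mu"] - f1.gblup_solution["mu"] == pytest.approx(100.0, abs=1e-5)

    def test_prediction_consistency_between_routes(self):
        # kinship regression on the cross block equals sigma_g2*G_ct*Vinv*resid
        g, ph = _toy(50, 80, seed=50)
        x = g.values.astype(float)
        tr, va = np.arange(35), np.arange(35, 50)
        fit = gp.fit_gblup(ph.y[tr], x[tr])
        pred = gp.predict_gblup(fit, genotypes_test=x[va], x_train=x[tr])
        vc, sol = fit.vc, fit.gblup_solution
        g_tt, g_ct, _, _ = _vanraden_blocks(x[tr], x[va])
        v = vc.sigma_g2 * g_tt + vc.sigma_e2 * np.eye(35)
        direct = vc.sigma_g2 * g_ct @ np.linalg.solve(v, ph.y[tr] - sol["mu"])
        np.testing.assert_allclose(pred, direct, atol=1e-6)


class TestBayesSamplers:
    def test_brr_fixed_variances_matches_ridge_posterior(self):
        # conjugate oracle: with both variances clamped, the stationary
        # posterior mean of beta is the closed-form ridge solution
        g, ph = _toy(20, 50, h2=0.6, seed=60)
        x = g.values.astype(float)
        sigma_e2, sigma_b2 = 0.4 * np.var(ph.y), 0.6 * np.var(ph.y) / 50
        cfg = gp.McmcConfig(n_iter=4000, burn_in=1000, seed=61)
        fit = gp.fit_bayes("BRR", ph.y, x, cfg, fixed_sigma_e2=sigma_e2, fixed_sigma_b2=sigma_b2)
        w = x - x.mean(axis=0)
        ridge = np.linalg.solve(
            w.T @ w + sigma_e2 / sigma_b2 * np.eye(50), w.T @ (ph.y - ph.y.mean())
        )
        post_sd = np.sqrt(
            sigma_e2 * np.diag(np.linalg.inv(w.T @ w + sigma_e2 / sigma_b2 * np.eye(50)))
        )
        mc_se = 3.0 * post_sd / np.sqrt(cfg.n_iter - cfg.burn_in) * 10  # autocorrelation margin
        assert np.all(np.abs(fit.effects.beta - ridge) < np.maximum(3 * mc_se, 5e-3))

    def test_constant_response_degenerates(self):
        g, _ = _toy(25, 40, seed=70)
        y = np.full(25, 7.5)
        cfg = gp.McmcConfig(n_iter=1500, burn_in=500, seed=71)
        for model in gp.BAYES_MODELS:
            fit = gp.fit_bayes(model, y, g.values.astype(float), cfg)
            assert np.max(np.abs(fit.effects.beta)) < 1e-2
            assert fit.effects.mu == pytest.approx(7.5, abs=1e-2)

    def test_seed_reproducibility_bitwise(self):
        g, ph = _toy(25, 40, seed=80)
        cfg = gp.McmcConfig(n_iter=500, burn_in=100, seed=81)
        f1 = gp.fit_bayes("BayesB", ph.y, g.values.astype(float), cfg)
        f2 = gp.fit_bayes("BayesB", ph.y, g.values.astype(float), cfg)
        np.testing.assert_array_equal(f1.effects.beta, f2.effects.beta)
        np.testing.assert_array_equal(f1.effects.inclusion_prob, f2.effects.inclusion_prob)

    def test_inclusion_probabilities_only_for_spike_slab(self):
        g, ph = _toy(25, 40, seed=90)
        cfg = gp.McmcConfig(n_iter=300, burn_in=100, seed=91)
        x = g.values.astype(float)
        for model in ("BayesA", "BL", "BRR"):
            assert gp.fit_bayes(model, ph.y, x, cfg).effects.inclusion_prob is None
        for model in ("BayesB", "BayesC"):
            ip = gp.fit_bayes(model, ph.y, x, cfg).effects.inclusion_prob
            assert ip is not None and np.all((ip >= 0) & (ip <= 1))

    def test_column_order_near_invariance(self):
        # the Gibbs scan order changes with the columns, so invariance is
        # statistical: posterior-mean predictions agree within MC error
        g, ph = _toy(40, 60, h2=0.6, seed=100)
        x = g.values.astype(float)
        cfg = gp.McmcConfig(n_iter=3000, burn_in=1000, seed=101)
        perm = np.random.default_rng(102).permutation(60)
        f1 = gp.fit_bayes("BRR", ph.y, x, cfg)
        f2 = gp.fit_bayes("BRR", ph.y, x[:, perm], cfg)
        p1 = gp.predict_bayes(f1, x)
        p2 = gp.predict_bayes(f2, x[:, perm])
        assert np.corrcoef(p1, p2)[0, 1] > 0.99

    def test_prediction_centers_by_training_frequencies(self):
        g, ph = _toy(40, 30, seed=110)
        x = g.values.astype(float)
        cfg = gp.McmcConfig(n_iter=300, burn_in=100, seed=111)
        fit = gp.fit_bayes("BRR", ph.y[:30], x[:30], cfg)
        np.testing.assert_allclose(fit.effects.allele_freq, x[:30].mean(0) / 2.0)
        pred = gp.predict_bayes(fit, x[30:])
        manual = (x[30:] - 2.0 * fit.effects.allele_freq) @ fit.effects.beta
        np.testing.assert_allclose(pred, manual)

    def test_unknown_model_and_bad_config(self):
        g, ph = _toy(20, 10, seed=120)
        with pytest.raises(ValueError, match="unknown Bayesian model"):
            gp.fit_bayes("BayesZ", ph.y, g.values.astype(float))
        with pytest.raises(ValueError):
            gp.McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            gp.McmcConfig(pi0=1.0)


class TestAccuracy:
    def test_identity_and_antipodal(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert gp.accuracy(y, y) == pytest.approx(1.0)
        assert gp.accuracy(-y, y) == pytest.approx(-1.0)

    def test_hand_computed_pairs(self):
        # pairs (1,2),(2,4),(3,5): r = 1 / sqrt((2/3)*(14/9)) = sqrt(27/28)
        r = gp.accuracy(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 5.0]))
        assert r == pytest.approx(np.sqrt(27.0 / 28.0))

    def test_degenerate_cases_are_missing(self):
        assert gp.accuracy(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])) is None
        assert gp.accuracy(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0])) is None
        assert gp.accuracy(np.array([1.0, 2.0]), np.array([1.0, 2.0])) is None
        with pytest.raises(ValueError):
            gp.accuracy(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0]))


class TestFitSerialization:
    def test_marker_effect_fit_round_trip(self, tmp_path):
        g, ph = _toy(30, 40, seed=130)
        cfg = gp.McmcConfig(n_iter=300, burn_in=100, seed=131)
        x = g.values.astype(float)
        fit = gp.fit_bayes("BayesC", ph.y, x, cfg)
        prefix = str(tmp_path / "bc_fit")
        gp.save_fit(fit, prefix)
        back = gp.load_fit(prefix)
        np.testing.assert_allclose(back.effects.beta, fit.effects.beta)
        np.testing.assert_allclose(
            gp.predict_bayes(back, x), gp.predict_bayes(fit, x)
        )

    def test_gblup_archive_is_summary_only(self, tmp_path):
        g, ph = _toy(30, 40, seed=140)
        fit = gp.fit_gblup(ph.y, g.values.astype(float))
        prefix = str(tmp_path / "gblup_fit")
        gp.save_fit(fit, prefix)
        with pytest.raises(ValueError, match="refit"):
            gp.load_fit(prefix)
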