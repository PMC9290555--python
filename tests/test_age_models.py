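"""Identity-link Poisson age regression and longevity model comparison."""

import numpy as np
import pytest

from dnmpipe import age_models
from dnmpipe.glm import brute_force_mle, fit_poisson_identity
from dnmpipe.model import LongevityConfig, TrioCallability, TrioRecord


class TestGlmCore:
    def test_saturated_single_row_closed_form(self):
        fit = fit_poisson_identity(np.array([[1e9]]), np.array([10.0]))
        assert fit.beta[0] == pytest.approx(1e-8, rel=1e-8)

    def test_two_rows_exact_linear_solve(self):
        """With n = p the MLE interpolates: y_i = beta . x_i exactly."""
        X = np.array([[2e9, 8e9], [1.5e9, 3e9]])
        y = np.array([24.0, 13.0])
        fit = fit_poisson_identity(X, y)
        expected = np.linalg.solve(X, y)
        assert fit.beta == pytest.approx(expected, rel=1e-8)

    def test_matches_brute_force_grid_on_tiny_instances(self):
        """Scoring iteration vs likelihood grid search, 4 significant digits."""
        X = np.array([[1.0, 2.0], [1.0, 5.0], [1.0, 9.0]])
        y = np.array([3.0, 8.0, 11.0])
        fit = fit_poisson_identity(X, y)
        grid = brute_force_mle(X, y, lo=np.array([0.1, 0.1]), hi=np.array([6.0, 3.0]))
        assert fit.beta == pytest.approx(grid, rel=5e-4)

    def test_matches_statsmodels_glm(self, trio_records):
        sm = pytest.importorskip("statsmodels.api")
        design = age_models.build_design(trio_records)
        X = design[["N_sites", "Z_p"]].to_numpy()
        y = design["y"].to_numpy(dtype=float)
        ours = fit_poisson_identity(X, y)
        theirs = sm.GLM(
            y, X, family=sm.families.Poisson(sm.families.links.Identity())
        ).fit(start_params=ours.beta * 1.3, maxiter=200)
        assert ours.beta == pytest.approx(theirs.params, rel=1e-6)
        assert ours.se == pytest.approx(theirs.bse, rel=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_identity(np.array([[1.0]]), np.array([-1.0]))


class TestBuildDesign:
    def test_fixture_drops_the_ageless_trio(self, trio_records):
        design = age_models.build_design(trio_records)
        assert len(design) == 10
        assert "679" not in set(design["trio"])

    def test_exposure_arithmetic(self):
        trio = TrioRecord(
            proband="t", paternal_age=4.0, maternal_age=2.0, n_mutations=10,
            callability=TrioCallability(0.5, 1.0, 1.0), haploid_span_bp=2_000_000_000,
        )
        row = age_models.build_design([trio]).iloc[0]
        assert row["N_sites"] == pytest.approx(2e9)
        assert row["Z_p"] == pytest.approx(8e9)

    def test_order_invariance(self, trio_records):
        a = age_models.fit_identity_poisson(age_models.build_design(trio_records))
        b = age_models.fit_identity_poisson(
            age_models.build_design(list(reversed(trio_records)))
        )
        assert a.beta_N == pytest.approx(b.beta_N, rel=1e-9)
        assert a.beta_p == pytest.approx(b.beta_p, rel=1e-9)

    def test_all_ageless_rejected(self):
        trio = TrioRecord(
            proband="t", n_mutations=5,
            callability=TrioCallability(1, 1, 1), haploid_span_bp=10**9,
        )
        with pytest.raises(ValueError):
            age_models.build_design([trio])


class TestScaleAndPredict:
    def test_zero_slope_scales_to_zero(self):
        fit = age_models.AgeRegressionFit(
            beta_N=1e-8, beta_p=0.0, beta_m=None,
            cov=np.zeros((2, 2)), loglik=0.0, n_obs=5,
        )
        eff, _ = age_models.scale_effect(fit)
        assert eff == 0.0

    def test_wald_arithmetic(self):
        cov = np.diag([0.0, (2.35e-10) ** 2])
        fit = age_models.AgeRegressionFit(
            beta_N=5e-9, beta_p=6.2e-10, beta_m=None, cov=cov, loglik=0.0, n_obs=10
        )
        eff, (lo, hi) = age_models.scale_effect(fit)
        assert eff == pytest.approx(3.1)
        assert lo == pytest.approx(3.1 - 1.96 * 2.35e-10 * 5e9, rel=1e-9)
        assert hi == pytest.approx(3.1 + 1.96 * 2.35e-10 * 5e9, rel=1e-9)

    def test_rate_at_age_zero_is_baseline(self):
        fit = age_models.AgeRegressionFit(
            beta_N=7e-9, beta_p=5e-10, beta_m=None,
            cov=np.zeros((2, 2)), loglik=0.0, n_obs=5,
        )
        rate, _ = age_models.predict_rate_at_age(fit, 0.0)
        assert rate == pytest.approx(7e-9)

    def test_scale_equivariance(self, trio_records):
        """Multiplying exposures by k divides coefficients by k and leaves
        fitted means and scaled effects unchanged."""
        design = age_models.build_design(trio_records)
        fit = age_models.fit_identity_poisson(design)
        scaled = design.copy()
        for col in ("N_sites", "Z_p"):
            scaled[col] = scaled[col] * 1000.0
        fit_k = age_models.fit_identity_poisson(scaled)
        assert fit_k.beta_N == pytest.approx(fit.beta_N / 1000, rel=1e-6)
        assert fit_k.beta_p == pytest.approx(fit.beta_p / 1000, rel=1e-6)
        eff, _ = age_models.scale_effect(fit)
        eff_k, _ = age_models.scale_effect(fit_k, diploid_genome_bp=5e9 * 1000)
        assert eff_k == pytest.approx(eff, rel=1e-6)

    def test_maternal_term_fitted_when_requested(self, trio_records):
        design = age_models.build_design(trio_records)
        fit = age_models.fit_identity_poisson(design, include_maternal=True)
        assert fit.beta_m is not None
        assert fit.cov.shape == (3, 3)


class TestParameterRecovery:
    def test_coverage_of_wald_intervals(self, trio_records):
        """y ~ Poisson(bN*N + bp*Z) at the fixture's exposures: nominal 95%
        intervals cover the truth at close-to-nominal frequency."""
        design = age_models.build_design(trio_records)
        X = design[["N_sites", "Z_p"]].to_numpy()
        bN, bp = 5.4e-9, 6.4e-10
        mu = X @ np.array([bN, bp])
        rng = np.random.default_rng(404)
        cover_N = cover_p = 0
        reps = 400
        for _ in range(reps):
            y = rng.poisson(mu).astype(float)
            fit = fit_poisson_identity(X, y)
            se = fit.se
            cover_N += abs(fit.beta[0] - bN) < 1.96 * se[0]
            cover_p += abs(fit.beta[1] - bp) < 1.96 * se[1]
        assert 0.90 <= cover_N / reps <= 0.98
        assert 0.90 <= cover_p / reps <= 0.98


class TestLongevityModels:
    def make_fit(self, beta_N=4e-9, beta_p=2e-10):
        return age_models.AgeRegressionFit(
            beta_N=beta_N, beta_p=beta_p, beta_m=None,
            cov=np.zeros((2, 2)), loglik=0.0, n_obs=10,
        )

    def test_reproductive_model_at_target_puberty_equals_reference_puberty(self):
        fit = self.make_fit()
        cfg = LongevityConfig(puberty_age_target=0.5, puberty_age_reference=13.0)
        (pred,) = age_models.longevity_predictions(fit, [0.5], cfg)
        ref_at_puberty, _ = age_models.predict_rate_at_age(fit, 13.0)
        assert pred.reproductive_model_rate == pytest.approx(ref_at_puberty)

    def test_age_mapping_arithmetic(self):
        fit = self.make_fit()
        cfg = LongevityConfig(0.5, 13.0)
        (pred,) = age_models.longevity_predictions(fit, [4.68], cfg)
        expected, _ = age_models.predict_rate_at_age(fit, 4.68 - 0.5 + 13.0)
        assert pred.reproductive_model_rate == pytest.approx(expected)
        total, _ = age_models.predict_rate_at_age(fit, 4.68)
        assert pred.total_model_rate == pytest.approx(total)

    def test_zero_slope_models_coincide(self):
        fit = self.make_fit(beta_p=0.0)
        preds = age_models.longevity_predictions(fit, [1.0, 3.0, 7.0])
        for p in preds:
            assert p.total_model_rate == pytest.approx(p.reproductive_model_rate)

    def test_identical_predictions_give_null_test(self):
        fit = self.make_fit(beta_p=0.0)
        preds = age_models.longevity_predictions(fit, [1.0, 2.0, 3.0])
        obs = [(1.0, 4e-9), (2.0, 5e-9), (3.0, 3e-9)]
        t, p = age_models.compare_models_residuals(obs, preds)
        assert (t, p) == (0.0, 1.0)

    def test_detects_better_model_on_synthetic_data(self):
        """When one model's residuals are uniformly half the other's, the
        paired test on absolute residuals rejects at n = 10."""
        fit = self.make_fit()
        ages = list(np.linspace(1, 10, 10))
        preds = age_models.longevity_predictions(fit, ages, LongevityConfig(0.5, 13.0))
        rng = np.random.default_rng(7)
        obs = []
        for p in preds:
            # observations centered on the reproductive prediction
            err = rng.normal(0, 2e-10)
            obs.append((p.age, p.reproductive_model_rate + err))
        t, pval = age_models.compare_models_residuals(obs, preds)
        assert pval < 0.05
        assert t > 0  # total-model residuals larger

    def test_too_few_pairs_rejected(self):
        fit = self.make_fit()
        preds = age_models.longevity_predictions(fit, [1.0, 2.0])
        with pytest.raises(ValueError):
            age_models.compare_models_residuals([(1.0, 1e-9), (2.0, 1e-9)], preds)


class TestPhasedModel:
    def test_slope_rescaled_by_phased_fraction(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(2, 12, 80)
        counts = rng.poisson(2.0 + 1.0 * ages)
        b0, b1, (lo, hi) = age_models.fit_phased_age_model(counts, ages, phased_fraction=0.5)
        b0f, b1f, _ = age_models.fit_phased_age_model(counts, ages, phased_fraction=1.0)
        assert b1 == pytest.approx(2 * b1f, rel=1e-9)
        assert lo < b1 < hi
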