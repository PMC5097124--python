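"""Visitation model: transforms, sampler correctness, diagnostics, effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elevisits.config import ImputationConfig, PipelineConfig
from elevisits.model import (PosteriorFit, build_design, check_convergence,
                             effect_size_percent, fit_visitation_model,
                             fit_within_site, impute_population_sd,
                             marginal_visits, model_fit_r2, predict_visits,
                             range_to_normal, FitError, TransformError)
from elevisits.synth import (SyntheticParams, generate_pa_table,
                             generate_within_site_panel)
from tests.conftest import fast_config
from tests.test_io import make_record


class TestRangeToNormal:
    def test_midpoint_and_95ci_width(self):
        mean, sd = range_to_normal(800, 1200)
        assert mean == pytest.approx(1000.0)
        assert sd == pytest.approx(102.04, abs=0.01)

    def test_degenerate_range(self):
        assert range_to_normal(7.0, 7.0) == (7.0, 0.0)

    def test_unit_sd_at_inverse_quantile(self):
        _, sd = range_to_normal(0.0, 3.919928)
        assert sd == pytest.approx(1.0, rel=1e-6)

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            range_to_normal(10.0, 5.0)

    @given(lo=st.floats(0, 1e5), width=st.floats(0, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_mean_between_bounds_and_sd_nonnegative(self, lo, width):
        mean, sd = range_to_normal(lo, lo + width)
        assert lo <= mean <= lo + width
        assert sd >= 0


class TestImputation:
    @pytest.mark.parametrize("mean,expected", [
        (10_000, 1412.0), (0, 192.0), (1_000, 314.0),
    ])
    def test_point_imputation_on_the_line(self, mean, expected):
        assert impute_population_sd(mean) == pytest.approx(expected)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            impute_population_sd(-1.0)


class TestEffectArithmetic:
    def test_semi_elasticity_at_study_coefficient(self):
        assert round(effect_size_percent(1.55)) == 371

    def test_zero_beta_zero_percent(self):
        assert effect_size_percent(0.0) == 0.0

    def test_doubling(self):
        assert effect_size_percent(np.log(2)) == pytest.approx(100.0)

    def test_marginal_visits_at_study_median(self):
        assert marginal_visits(1883, 1.55, 0.1) == pytest.approx(698.87, abs=0.01)

    def test_marginal_visits_zero_delta(self):
        assert marginal_visits(1883, 1.55, 0.0) == 0.0

    def test_marginal_visits_doubling_adds_baseline(self):
        assert marginal_visits(1000, np.log(2), 1.0) == pytest.approx(1000.0)


class TestBuildDesign:
    def test_log_transforms(self):
        rec = make_record(area_km2=100.0)
        d = build_design([rec])
        assert d.X[0, d.names.index("log_area")] == pytest.approx(np.log(100))
        assert d.y[0] == pytest.approx(np.log(rec.visits))

    def test_interaction_column_is_density_times_forest(self):
        rec = make_record(forest=True, elephant_pop_mean=2000.0,
                          censused_area_km2=1000.0)
        d = build_design([rec])
        assert d.X[0, d.names.index("density_forest")] == pytest.approx(2.0)
        assert d.X[0, d.names.index("elephant_density")] == pytest.approx(2.0)

    def test_nonpositive_visits_error_names_pa_id(self):
        rec = make_record(pa_id="PA_ZERO", visits=0.0)
        with pytest.raises(TransformError, match="PA_ZERO"):
            build_design([rec])

    def test_range_form_converted_to_density_observation(self):
        rec = make_record(elephant_pop_sd=None, elephant_pop_lo=800.0,
                          elephant_pop_hi=1200.0, censused_area_km2=1000.0)
        d = build_design([rec])
        assert d.d_obs[0] == pytest.approx(1.0)
        assert d.s_obs[0] == pytest.approx(102.04 / 1000.0, abs=1e-4)


def degenerate_fit(beta: dict, names=None) -> PosteriorFit:
    """Two 'chains' of one identical draw each, for closed-form checks."""
    from elevisits.model import FULL_PREDICTORS
    names = tuple(names or FULL_PREDICTORS)
    b = np.array([[beta.get(n, 0.0) for n in names]] * 2)[:, None, :]
    means = np.zeros(len(names))
    means[names.index("intercept")] = 1.0
    return PosteriorFit(
        names=names, beta=b, sigma=np.full((2, 1), 0.1),
        latent_density=np.zeros((2, 1, 0)), imputed_sd=np.zeros((2, 1, 0)),
        latent_pa_ids=[], imputed_pa_ids=[],
        covariate_means=means, seed=0)


class TestPredictVisits:
    def test_intercept_only_fit_predicts_constant(self):
        fit = degenerate_fit({"intercept": np.log(1000.0)})
        for dens in (0.0, 0.5, 2.0):
            assert predict_visits(fit, dens).median == pytest.approx(1000.0)

    def test_closed_form_density_effect(self):
        fit = degenerate_fit({"intercept": np.log(1883.0), "elephant_density": 1.55})
        pred = predict_visits(fit, 0.1, forest=False)
        assert pred.median == pytest.approx(1883 * np.exp(0.155), rel=1e-12)

    def test_monotone_in_density_on_savannah(self, fitted):
        meds = [predict_visits(fitted, d, forest=False).median
                for d in (0.0, 0.5, 1.0, 1.5)]
        assert all(a < b for a, b in zip(meds, meds[1:]))

    def test_negative_density_rejected(self, fitted):
        with pytest.raises(ValueError):
            predict_visits(fitted, -0.1)


class TestFitVisitationModel:
    def test_recovers_density_coefficient(self, fitted):
        d = fitted.coefficient("elephant_density")
        lo, hi = np.quantile(d, [0.025, 0.975])
        assert lo <= 1.55 <= hi

    def test_null_density_effect_recovered(self):
        coeffs = dict(SyntheticParams().true_coefficients)
        coeffs["elephant_density"] = 0.0
        coeffs["density_forest"] = 0.0
        records, _ = generate_pa_table(SyntheticParams(seed=21, true_coefficients=coeffs))
        fit = fit_visitation_model(records, fast_config(seed=2))
        lo, hi = np.quantile(fit.coefficient("elephant_density"), [0.025, 0.975])
        assert lo <= 0.0 <= hi

    def test_seeded_reproducibility(self, synthetic_study):
        records, _ = synthetic_study
        cfg = fast_config(seed=5, warmup=100, sampling=100)
        f1 = fit_visitation_model(records, cfg)
        f2 = fit_visitation_model(records, cfg)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        np.testing.assert_array_equal(f1.sigma, f2.sigma)
        np.testing.assert_array_equal(f1.latent_density, f2.latent_density)

    def test_draw_count_contract(self, fitted):
        c, d, p = fitted.beta.shape
        assert (c, d) == (fitted.n_chains, fitted.n_draws_per_chain)
        assert len(fitted.names) == p == 10

    def test_latent_densities_nonnegative(self, fitted):
        assert (fitted.latent_density >= 0).all()

    def test_too_few_records_rejected(self, synthetic_study):
        records, _ = synthetic_study
        with pytest.raises(FitError, match="20"):
            fit_visitation_model(records[:10], fast_config())

    def test_attenuation_of_naive_plugin_fit(self):
        """Plugging noisy observed densities into OLS attenuates the slope
        relative to the errors-in-variables posterior mean (directionally,
        averaged over replicates)."""
        naive, eiv = [], []
        for rep in range(10):
            params = SyntheticParams(seed=700 + rep, obs_noise_scale=3.0)
            records, _ = generate_pa_table(params)
            fit = fit_visitation_model(records, fast_config(seed=rep, warmup=200,
                                                            sampling=200))
            eiv.append(fit.coefficient("elephant_density").mean())
            d = build_design([r for r in records if r.visits is not None])
            beta, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
            naive.append(beta[d.names.index("elephant_density")])
        assert np.mean(naive) <= np.mean(eiv)

    def test_imputed_sds_follow_the_mean_sd_line(self, fitted, synthetic_study):
        """Posterior-mean imputed sds regress on population means with a slope
        within +/-50% of the generating line's 0.122."""
        records, _ = synthetic_study
        means = {r.pa_id: r.elephant_pop_mean for r in records}
        pop = np.array([means[pa] for pa in fitted.imputed_pa_ids])
        sd_hat = fitted.imputed_sd.reshape(-1, len(fitted.imputed_pa_ids)).mean(axis=0)
        slope = np.polyfit(pop, sd_hat, 1)[0]
        assert 0.061 <= slope <= 0.183


class TestConvergence:
    def test_coefficients_converge_at_desk_scale(self, fitted):
        """Regression coefficients and sigma mix quickly; weakly identified
        per-record latents may need study-scale chains to clear the same bar."""
        report = check_convergence(fitted, PipelineConfig())
        coef = report.table[report.table["parameter"].str.startswith("beta_")
                            | (report.table["parameter"] == "sigma")]
        assert coef["rhat"].max() <= 1.05
        assert coef["ess"].min() > 100

    def test_iid_chains_rhat_near_one(self, rng):
        draws = rng.standard_normal((4, 2000))
        fit = PosteriorFit(
            names=("intercept",), beta=draws[:, :, None], sigma=np.abs(draws) + 1,
            latent_density=np.zeros((4, 2000, 0)), imputed_sd=np.zeros((4, 2000, 0)),
            latent_pa_ids=[], imputed_pa_ids=[], covariate_means=np.zeros(1), seed=0)
        report = check_convergence(fit, PipelineConfig())
        assert report.table["rhat"].max() <= 1.01
        assert report.passed

    def test_disjoint_chains_fail(self, rng):
        draws = rng.standard_normal((2, 500))
        draws[1] += 50.0
        fit = PosteriorFit(
            names=("intercept",), beta=draws[:, :, None], sigma=np.abs(draws) + 1,
            latent_density=np.zeros((2, 500, 0)), imputed_sd=np.zeros((2, 500, 0)),
            latent_pa_ids=[], imputed_pa_ids=[], covariate_means=np.zeros(1), seed=0)
        report = check_convergence(fit, PipelineConfig())
        assert report.table["rhat"].max() > 1.01
        assert not report.passed

    def test_single_chain_rejected(self, fitted):
        one_chain = PosteriorFit(
            names=fitted.names, beta=fitted.beta[:1], sigma=fitted.sigma[:1],
            latent_density=fitted.latent_density[:1], imputed_sd=fitted.imputed_sd[:1],
            latent_pa_ids=fitted.latent_pa_ids, imputed_pa_ids=fitted.imputed_pa_ids,
            covariate_means=fitted.covariate_means, seed=0)
        with pytest.raises(ValueError, match="chain"):
            check_convergence(one_chain, PipelineConfig())


class TestModelFitR2:
    def test_perfect_predictions(self):
        """A noiseless generator refit at matched conditions yields slope ~1,
        intercept ~0, R^2 ~1."""
        params = SyntheticParams(seed=17, residual_sd=0.0,
                                 sd_line_intercept=2.0, sd_line_slope=0.005,
                                 sd_line_jitter=0.5)
        records, _ = generate_pa_table(params)
        cfg = fast_config(seed=1, warmup=200, sampling=200)
        cfg.imputation = ImputationConfig(intercept=2.0, slope=0.005, residual_sd=0.5)
        fit = fit_visitation_model(records, cfg)
        slope, intercept, r2 = model_fit_r2(fit, records)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r2 > 0.98

    def test_r2_in_unit_interval(self, fitted, synthetic_study):
        records, _ = synthetic_study
        _, _, r2 = model_fit_r2(fitted, records)
        assert 0.0 <= r2 <= 1.0

    def test_too_few_records_rejected(self, fitted, synthetic_study):
        records, _ = synthetic_study
        with pytest.raises(ValueError):
            model_fit_r2(fitted, records[:2])


class TestWithinSite:
    def test_recovers_density_coefficient(self):
        panel = generate_within_site_panel(n_years=56, seed=6)
        fit = fit_within_site(panel, config=fast_config(seed=3))
        lo, hi = np.quantile(fit.coefficient("elephant_density"), [0.025, 0.975])
        assert lo <= 0.67 <= hi

    def test_zero_noise_coefficients_recovered(self):
        beta = {"intercept": 2.0, "log_area": 0.47, "log_gdp": 0.3,
                "elephant_density": 0.67}
        panel = generate_within_site_panel(n_years=40, true_coefficients=beta,
                                           residual_sd=0.0, seed=2)
        fit = fit_within_site(panel, config=fast_config(seed=1))
        for name, truth in beta.items():
            assert fit.coefficient(name).mean() == pytest.approx(truth, abs=0.05)

    def test_density_only_reduced_model(self):
        panel = generate_within_site_panel(n_years=15, seed=9)
        fit = fit_within_site(panel, predictors=("density",),
                              config=fast_config(seed=2))
        assert fit.names == ("intercept", "elephant_density")

    def test_collinear_design_rejected(self):
        panel = generate_within_site_panel(n_years=20, seed=1)
        panel["area_km2"] = 100.0
        panel["country_gdp"] = 100.0  # log columns now identical & constant
        with pytest.raises(FitError, match="collinear"):
            fit_within_site(panel, config=fast_config())

    def test_short_panel_rejected(self):
        panel = generate_within_site_panel(n_years=12, seed=1).head(5)
        with pytest.raises(FitError):
            fit_within_site(panel)
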