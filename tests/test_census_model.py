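"""Design preparation and hurdle-model fitting behaviour."""

import numpy as np
import pytest

from seabird_cascade import (
    CensusSimParams,
    HurdleSpec,
    fit_hurdle_lognormal,
    generate_census,
    posterior_predictive_check,
    prepare_design,
)
from seabird_cascade.census import HurdlePosterior, validate_census
from seabird_cascade.exceptions import DegenerateDesignError, ParameterError, SchemaError
from scipy.special import expit


def small_census(**kw):
    return generate_census(CensusSimParams(n_islands=kw.pop("n_islands", 20), **kw))


class TestPrepareDesign:
    def test_two_island_zscores_are_symmetric(self):
        census = small_census(n_islands=4, seed=0).iloc[:2].copy()
        census["area_ha"] = [np.e**1, np.e**3]
        census["rat_status"] = ["present", "absent"]
        census["native_cover"] = [0.2, 0.6]
        design = prepare_design(census, HurdleSpec())
        z = np.unique(np.round(design.long["z_log_area"], 12))
        # sample sd (ddof=1) of {1, 3} is sqrt(2): z = -/+ 1/sqrt(2)
        np.testing.assert_allclose(z, [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert abs(design.long["z_log_area"].mean()) < 1e-14

    def test_missing_species_column_is_schema_error(self, census):
        with pytest.raises(SchemaError):
            validate_census(census, species=["albatross"])

    def test_standardization_round_trips(self, fitted):
        design, _ = fitted
        std = design.standardization
        area = np.array([1.0, 55.3, 400.0])
        np.testing.assert_allclose(
            std.inverse_log_area(std.z_log_area(area)), area, rtol=1e-12
        )
        cover = np.array([0.03, 0.43, 1.0])
        np.testing.assert_allclose(
            std.inverse_native_cover(std.z_native_cover(cover)), cover, atol=1e-12
        )

    def test_zero_variance_covariate_raises(self):
        census = small_census(seed=1)
        census["area_ha"] = 10.0
        with pytest.raises(DegenerateDesignError):
            prepare_design(census, HurdleSpec())

    def test_constant_rat_status_is_dropped_with_warning(self):
        census = small_census(seed=2, frac_rat_present=0.0)
        with pytest.warns(UserWarning, match="rat_status does not vary"):
            design = prepare_design(census, HurdleSpec())
        assert "b_rat" not in design.feature_names
        assert design.hurdle_feature_idx == []

    def test_drop_islands_excludes_rows(self):
        census = small_census(seed=3)
        design = prepare_design(census, HurdleSpec(), drop_islands=["I000"])
        assert "I000" not in set(design.long["island_id"])

    def test_invalid_mcmc_schedule_raises(self):
        with pytest.raises(ParameterError):
            HurdleSpec(iterations=500, warmup=600)
        with pytest.raises(ParameterError):
            HurdleSpec(chains=1)


class TestHurdleFit:
    def test_fit_returns_finite_draws_and_rhat_for_all_params(self, fitted):
        _, post = fitted
        for name, arr in post.draws().items():
            assert np.all(np.isfinite(arr)), name
            assert name in post.rhat
        assert np.all(post.sigma > 0) and np.all(post.tau > 0)

    def test_zero_free_census_concentrates_hurdle_near_zero(self):
        # all counts positive, no rat variation: P(zero) posterior must sit
        # well below 5%
        census = small_census(
            n_islands=70, seed=4, frac_rat_present=0.0,
            zero_prob_logit_intercept=-np.inf,
        )
        with pytest.warns(UserWarning, match="rat_status"):
            design = prepare_design(census, HurdleSpec())
        post = fit_hurdle_lognormal(
            design, HurdleSpec(iterations=1000, warmup=400, seed=5)
        )
        p_zero = expit(post.hurdle_gamma[:, :, 0].ravel())
        assert np.quantile(p_zero, 0.975) < 0.05

    def test_strong_rat_effect_sign_recovered(self, fitted):
        _, post = fitted
        rat_idx = post.hurdle_feature_names.index("hurdle_b_rat")
        draws = post.hurdle_gamma[:, :, rat_idx].ravel()
        assert np.mean(draws > 0) > 0.975

    def test_scale_equivariance_of_standardized_slopes(self):
        census = small_census(n_islands=40, seed=6)
        spec = HurdleSpec(iterations=1000, warmup=400, seed=7)
        post_a = fit_hurdle_lognormal(prepare_design(census, spec), spec)
        census2 = census.copy()
        census2["area_ha"] *= 1000.0
        post_b = fit_hurdle_lognormal(prepare_design(census2, spec), spec)
        ja = post_a.feature_names.index("b_log_area")
        slopes_a = post_a.beta[:, :, ja].ravel()
        slopes_b = post_b.beta[:, :, ja].ravel()
        # z-scoring absorbs the rescaling; same seed -> same covariate draws
        np.testing.assert_allclose(slopes_a.mean(), slopes_b.mean(), atol=0.02)

    def test_posterior_netcdf_round_trip(self, fitted, tmp_path):
        _, post = fitted
        path = tmp_path / "post.nc"
        post.to_netcdf(path)
        back = HurdlePosterior.from_netcdf(path)
        np.testing.assert_allclose(back.beta, post.beta)
        np.testing.assert_allclose(back.hurdle_gamma, post.hurdle_gamma)
        assert back.species == post.species
        assert back.standardization == post.standardization
        assert back.rhat == pytest.approx(post.rhat)


class TestPosteriorPredictiveCheck:
    def test_self_consistency_on_well_specified_data(self, fitted):
        design, post = fitted
        ppc = posterior_predictive_check(post, design, random_state=0)
        for stat, p in ppc.tail_prob.items():
            assert 0.01 < p < 0.99, f"{stat}: tail prob {p}"

    def test_zero_fraction_matches_within_mc_error(self, fitted):
        design, post = fitted
        ppc = posterior_predictive_check(post, design, random_state=1)
        rep = ppc.replicated["zero_fraction"]
        assert abs(ppc.observed["zero_fraction"] - rep.mean()) < 3 * rep.std()

    def test_replicates_have_data_shape(self, fitted):
        design, post = fitted
        ppc = posterior_predictive_check(post, design)
        assert ppc.replicates_shape == (post.n_draws, len(design.y))
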