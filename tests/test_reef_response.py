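"""Reef-metric regressions, scenario projection, and upscaling."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from seabird_cascade import (
    ReefFitSettings,
    ReefSimParams,
    fit_reef_model,
    generate_reef_survey,
    predict_reef_metrics,
    upscale_fish_biomass,
)
from seabird_cascade.exceptions import DegenerateDesignError, ParameterError, SchemaError
from seabird_cascade.nutrient_flux import NitrogenBudget
from seabird_cascade.reef import ReefPosterior
from seabird_cascade.synthetic import REEF_METRICS

FAST = ReefFitSettings(iterations=1200, warmup=400, seed=2)


def survey(n_islands=40, seed=0, **kw):
    return generate_reef_survey(ReefSimParams(n_islands=n_islands, seed=seed, **kw))


def budget(islands, values):
    da = xr.DataArray(
        np.asarray(values, dtype=float)[None, :],
        dims=("draw", "island"),
        coords={"island": islands},
    )
    return NitrogenBudget(kg_per_year=da, area_ha=pd.Series(1.0, index=islands))


class TestFitReefModel:
    def test_recovers_known_slope(self):
        post = fit_reef_model(survey(40, seed=1), "bioerosion", FAST)  # true slope 0.35
        assert abs(float(post.slope.mean()) - 0.35) < 0.1
        lo, hi = post.slope_interval()
        assert lo < 0.35 < hi

    def test_null_slope_interval_contains_zero(self):
        params = ReefSimParams(
            n_islands=30, seed=4, log_slopes={m: 0.0 for m in REEF_METRICS}
        )
        post = fit_reef_model(generate_reef_survey(params), "grazing", FAST)
        lo, hi = post.slope_interval()
        assert lo < 0.0 < hi

    def test_posterior_predictive_metrics_strictly_positive(self):
        post = fit_reef_model(survey(12, seed=5), "coral_growth", FAST)
        islands = ["A", "B"]
        proj = predict_reef_metrics(
            {"coral_growth": post}, {"current": budget(islands, [10.0, 100.0])}
        )
        assert (proj.predictions["coral_growth"]["current"].values > 0).all()

    def test_metric_models_are_independent(self):
        s = survey(12, seed=6)
        a = fit_reef_model(s, "grazing", FAST)
        _ = fit_reef_model(s, "fish_biomass", FAST)
        b = fit_reef_model(s, "grazing", FAST)
        np.testing.assert_array_equal(a.slope, b.slope)

    def test_held_out_island_coverage_near_nominal(self):
        # posterior predictive of a new observation: mu + N(0, tau) + N(0, sigma)
        train, test = survey(40, seed=7), survey(40, seed=107)
        post = fit_reef_model(train, "fish_biomass", FAST)
        rng = np.random.default_rng(0)
        S = post.n_draws
        obs = test.groupby("island_id").first()
        mu = (
            post.intercept.reshape(S, 1)
            + post.slope.reshape(S, 1) * np.log(obs["nitrogen_kg_ha_yr"].values)[None, :]
            + rng.normal(0.0, post.tau.reshape(S, 1), (S, len(obs)))
            + rng.normal(0.0, post.sigma.reshape(S, 1), (S, len(obs)))
        )
        lo, hi = np.quantile(np.exp(mu), [0.10, 0.90], axis=0)
        cover = np.mean((obs["fish_biomass"].values >= lo) & (obs["fish_biomass"].values <= hi))
        assert 0.6 <= cover <= 0.95  # nominal 80%

    def test_constant_nitrogen_is_degenerate(self):
        s = survey(8, seed=8)
        s["nitrogen_kg_ha_yr"] = 12.0
        with pytest.raises(DegenerateDesignError):
            fit_reef_model(s, "grazing", FAST)

    def test_too_few_islands_rejected(self):
        with pytest.raises(ParameterError):
            fit_reef_model(survey(12, seed=9).query("island_id < 'R003'"), "grazing", FAST)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            fit_reef_model(survey(8, seed=10).drop(columns=["grazing"]), "grazing", FAST)


def point_mass_reef_posterior(slope=0.4, metric="fish_biomass"):
    shape = (2, 5)
    return ReefPosterior(
        metric=metric,
        intercept=np.full(shape, 2.0),
        slope=np.full(shape, slope),
        sigma=np.full(shape, 0.3),
        tau=np.full(shape, 0.2),
        island_labels=np.array(["A"]),
        rhat={},
        nitrogen_floor=0.01,
    )


class TestPredictAndUpscale:
    def test_identity_budget_gives_zero_percent_change(self):
        post = point_mass_reef_posterior()
        islands = ["A", "B", "C"]
        b = budget(islands, [5.0, 50.0, 500.0])
        proj = predict_reef_metrics(
            {"fish_biomass": post}, {"current": b, "scenario": b}
        )
        np.testing.assert_array_equal(
            proj.pct_change["fish_biomass"]["scenario"].values, 0.0
        )

    def test_percent_change_closed_form_and_unit_invariance(self):
        # pct = 100*(exp(slope * dlogN) - 1); intercept and variances cancel,
        # so the metric's raw units cannot matter
        post = point_mass_reef_posterior(slope=0.4)
        islands = ["A", "B"]
        proj = predict_reef_metrics(
            {"fish_biomass": post},
            {"current": budget(islands, [10.0, 10.0]), "up": budget(islands, [20.0, 40.0])},
        )
        expected = 100.0 * (np.exp(0.4 * np.log([2.0, 4.0])) - 1.0)
        np.testing.assert_allclose(
            proj.pct_change["fish_biomass"]["up"].values[0], expected, rtol=1e-12
        )
        shifted = point_mass_reef_posterior(slope=0.4)
        shifted.intercept += 7.0  # rescaling the metric by e^7
        proj2 = predict_reef_metrics(
            {"fish_biomass": shifted},
            {"current": budget(islands, [10.0, 10.0]), "up": budget(islands, [20.0, 40.0])},
        )
        np.testing.assert_allclose(
            proj2.pct_change["fish_biomass"]["up"].values,
            proj.pct_change["fish_biomass"]["up"].values,
            rtol=1e-12,
        )

    def test_increased_nitrogen_with_positive_slope_raises_all_metrics(self, fitted_reef=None):
        post = fit_reef_model(survey(20, seed=11), "grazing", FAST)
        islands = ["A", "B"]
        proj = predict_reef_metrics(
            {"grazing": post},
            {"current": budget(islands, [10.0, 20.0]), "up": budget(islands, [30.0, 60.0])},
        )
        med = np.median(proj.pct_change["grazing"]["up"].values, axis=0)
        assert (med > 0).all()

    def test_uniform_biomass_upscales_to_area_product(self):
        post = point_mass_reef_posterior()
        islands = ["A", "B"]
        b = budget(islands, [10.0, 10.0])
        proj = predict_reef_metrics({"fish_biomass": post}, {"current": b})
        # overwrite predictions with a uniform 100 kg/ha field
        proj.predictions["fish_biomass"]["current"] = xr.DataArray(
            np.full((4, 2), 100.0), dims=("draw", "island"), coords={"island": islands}
        )
        ups = upscale_fish_biomass(proj, reef_area_km2=4380.0)
        # 4380 km2 * 100 ha/km2 * 100 kg/ha / 1000 = 43,800 tons
        assert ups.mean_tons()["current"] == pytest.approx(43_800.0)

    def test_zero_change_scenario_gives_zero_difference(self):
        post = point_mass_reef_posterior()
        b = budget(["A"], [10.0])
        proj = predict_reef_metrics({"fish_biomass": post}, {"current": b, "same": b})
        ups = upscale_fish_biomass(proj)
        diff = ups.difference_vs_current("same")
        assert diff["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_difference_linear_in_per_ha_increment(self):
        post = point_mass_reef_posterior()
        islands = ["A"]
        proj = predict_reef_metrics({"fish_biomass": post}, {"current": budget(islands, [10.0])})
        base = proj.predictions["fish_biomass"]["current"]
        for k, scn in ((1.0, "s1"), (2.0, "s2")):
            proj.predictions["fish_biomass"][scn] = base + k * 10.0
        ups = upscale_fish_biomass(proj)
        d1 = ups.difference_vs_current("s1")["mean"]
        d2 = ups.difference_vs_current("s2")["mean"]
        assert d2 == pytest.approx(2.0 * d1, rel=1e-9)
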