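"""Guano-nitrogen budgets: arithmetic, linearity, scenario composition."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from seabird_cascade import (
    ExcretionConstants,
    Scenario,
    nitrogen_input,
    scenario_nitrogen,
)
from seabird_cascade.bioenergetics import SpeciesProfile
from seabird_cascade.exceptions import ConfigurationError, JoinError, ParameterError
from seabird_cascade.scenarios import AbundancePrediction


def profile(name, mass=100.0, season=100.0):
    return SpeciesProfile(
        species=name,
        adult_mass_g=mass,
        colony_latitude_deg=-6.0,
        breeding_phases=(("all", season),),
        season_length_days=season,
        max_foraging_radius_km=100.0,
        mean_foraging_radius_km=50.0,
        fmr_coefficients={"all": (0.0, 1.0, 0.0)},
    )


def fixed_rate_constants(g_per_day=10.0, n_frac=0.2):
    # exponent 0 -> defecation(mass) == coefficient, any mass
    return ExcretionConstants(
        defecation_coef_g_per_day=g_per_day,
        defecation_mass_exponent=0.0,
        guano_n_fraction=n_frac,
    )


def census_frame(pairs_a, pairs_b=None, areas=None):
    n = len(pairs_a)
    out = {
        "island_id": [f"I{i}" for i in range(n)],
        "area_ha": areas if areas is not None else np.full(n, 10.0),
        "rat_status": ["present"] * n,
        "native_cover": np.full(n, 0.5),
        "pairs_a": pairs_a,
    }
    if pairs_b is not None:
        out["pairs_b"] = pairs_b
    return pd.DataFrame(out)


class TestNitrogenInput:
    def test_reference_arithmetic(self):
        # 1000 pairs * 2 adults * 10 g/day * 0.2 N * 100 days / 1000 = 400 kg/yr
        census = census_frame([1000])
        budget = nitrogen_input(
            census, {"a": profile("a")}, fixed_rate_constants(),
            pd.Series([10.0], index=["I0"]),
        )
        assert float(budget.kg_per_year.values[0, 0]) == pytest.approx(400.0)

    def test_zero_abundance_gives_zero_budget(self):
        census = census_frame([0, 0, 0])
        budget = nitrogen_input(
            census, {"a": profile("a")}, fixed_rate_constants(),
            pd.Series(10.0, index=["I0", "I1", "I2"]),
        )
        assert np.all(budget.kg_per_year.values == 0.0)
        assert np.all(budget.total_tons_draws() == 0.0)

    def test_additive_across_species_and_islands(self):
        profiles = {"a": profile("a"), "b": profile("b", season=50.0)}
        const = fixed_rate_constants()
        areas = pd.Series(10.0, index=["I0", "I1"])
        both = nitrogen_input(census_frame([100, 200], [300, 400]), profiles, const, areas)
        only_a = nitrogen_input(census_frame([100, 200]), profiles, const, areas)
        only_b = nitrogen_input(
            census_frame([0, 0], [300, 400]), profiles, const, areas
        )
        np.testing.assert_allclose(
            both.kg_per_year.values,
            only_a.kg_per_year.values + only_b.kg_per_year.values,
            rtol=1e-12,
        )
        assert both.total_tons_draws()[0] == pytest.approx(
            float(both.kg_per_year.values.sum()) / 1000.0
        )

    def test_degree_one_homogeneity_in_abundance_and_season(self):
        const = fixed_rate_constants()
        areas = pd.Series(10.0, index=["I0"])
        base = nitrogen_input(census_frame([100]), {"a": profile("a")}, const, areas)
        x3 = nitrogen_input(census_frame([300]), {"a": profile("a")}, const, areas)
        long_season = nitrogen_input(
            census_frame([100]), {"a": profile("a", season=200.0)}, const, areas
        )
        assert float(x3.kg_per_year.sum()) == pytest.approx(3 * float(base.kg_per_year.sum()))
        assert float(long_season.kg_per_year.sum()) == pytest.approx(
            2 * float(base.kg_per_year.sum())
        )

    def test_per_ha_normalization_scales_inversely_with_area(self):
        const = fixed_rate_constants()
        b1 = nitrogen_input(
            census_frame([500], areas=[10.0]), {"a": profile("a")}, const,
            pd.Series([10.0], index=["I0"]),
        )
        b2 = nitrogen_input(
            census_frame([500], areas=[50.0]), {"a": profile("a")}, const,
            pd.Series([50.0], index=["I0"]),
        )
        np.testing.assert_allclose(
            b1.per_ha().values, 5.0 * b2.per_ha().values, rtol=1e-12
        )
        np.testing.assert_allclose(b1.total_tons_draws(), b2.total_tons_draws())

    def test_missing_profile_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            nitrogen_input(
                census_frame([10]), {}, fixed_rate_constants(),
                pd.Series([10.0], index=["I0"]),
            )

    def test_invalid_constants_rejected(self):
        with pytest.raises(ParameterError):
            ExcretionConstants(
                defecation_coef_g_per_day=-1.0,
                defecation_mass_exponent=0.5,
                guano_n_fraction=0.2,
            )
        with pytest.raises(ParameterError):
            ExcretionConstants(
                defecation_coef_g_per_day=1.0,
                defecation_mass_exponent=0.5,
                guano_n_fraction=1.5,
            )


def prediction_for(islands, species, values):
    """Point-mass AbundancePrediction with a singleton draw axis."""
    arr = xr.DataArray(
        np.asarray(values, dtype=float)[None, :, :],
        dims=("draw", "island", "species"),
        coords={"island": islands, "species": list(species)},
    )
    return AbundancePrediction(scenario=Scenario("s", 0.5), draws=arr, island_ids=islands)


class TestScenarioNitrogen:
    def test_identity_prediction_reproduces_current_budget(self):
        census = census_frame([100, 200], [300, 400])
        profiles = {"a": profile("a"), "b": profile("b")}
        const = fixed_rate_constants()
        areas = pd.Series(10.0, index=["I0", "I1"])
        current = nitrogen_input(census, profiles, const, areas)
        pred = prediction_for(["I0", "I1"], ["a", "b"], [[100, 300], [200, 400]])
        scen = scenario_nitrogen(census, pred, profiles, const)
        np.testing.assert_allclose(
            scen.kg_per_year.values, current.kg_per_year.values, rtol=1e-12
        )

    def test_doubling_focal_pairs_raises_only_focal_contribution(self):
        census = census_frame([100, 200], [300, 400])
        profiles = {"a": profile("a"), "b": profile("b")}
        const = fixed_rate_constants()
        pred1 = prediction_for(["I0", "I1"], ["a"], [[100], [200]])
        pred2 = prediction_for(["I0", "I1"], ["a"], [[200], [400]])
        s1 = scenario_nitrogen(census, pred1, profiles, const)
        s2 = scenario_nitrogen(census, pred2, profiles, const)
        # species b contributes identically; focal a doubles
        rate_a = 2 * 10.0 * 0.2 * 100.0 / 1000.0  # kg/yr per pair of species a
        np.testing.assert_allclose(
            s2.kg_per_year.values - s1.kg_per_year.values,
            np.array([[100 * rate_a, 200 * rate_a]]),
            rtol=1e-12,
        )

    def test_two_island_two_species_hand_computation(self):
        census = census_frame([10, 0], [5, 20])
        profiles = {"a": profile("a", season=100.0), "b": profile("b", season=50.0)}
        const = fixed_rate_constants(g_per_day=8.0, n_frac=0.25)
        pred = prediction_for(["I0", "I1"], ["a"], [[40], [60]])
        scen = scenario_nitrogen(census, pred, profiles, const)
        per_pair_a = 2 * 8.0 * 0.25 * 100.0 / 1000.0  # 0.4 kg
        per_pair_b = 2 * 8.0 * 0.25 * 50.0 / 1000.0  # 0.2 kg
        expected = np.array([[40 * per_pair_a + 5 * per_pair_b,
                              60 * per_pair_a + 20 * per_pair_b]])
        np.testing.assert_allclose(scen.kg_per_year.values, expected, rtol=1e-9)

    def test_island_mismatch_is_join_error(self):
        census = census_frame([10])
        pred = prediction_for(["I0", "IX"], ["a"], [[10], [10]])
        with pytest.raises(JoinError):
            scenario_nitrogen(census, pred, {"a": profile("a")}, fixed_rate_constants())
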