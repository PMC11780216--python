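"""Spatial biomass extraction, P/B production, and the sustainability rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seabird_cascade import (
    PreyAssumptions,
    PreyFieldSimParams,
    assess_supply,
    extract_biomass,
    generate_prey_field,
    production_from_biomass,
    sustainable_threshold,
)
from seabird_cascade.exceptions import EmptyExtractionError, ParameterError, UnitMismatchError
from seabird_cascade.prey_supply import haversine_km

CENTER = (-6.5, 71.0)


class TestExtractBiomass:
    def test_uniform_disc_matches_analytic_area(self, uniform_prey_field):
        # density 1 t/km2 -> biomass = disc area = pi * 500^2 tons
        got = extract_biomass(uniform_prey_field, CENTER, 500.0)
        assert got == pytest.approx(np.pi * 500.0**2, rel=0.02)

    def test_monotone_in_radius(self, prey_field):
        radii = [100.0, 300.0, 600.0, 1200.0]
        vals = [extract_biomass(prey_field, CENTER, r) for r in radii]
        assert np.all(np.diff(vals) > 0)

    def test_tiny_radius_selects_single_containing_cell(self, uniform_prey_field):
        # center exactly on a cell center: membership is by cell-center
        # distance, so a sub-cell radius captures exactly that one cell
        lat = float(uniform_prey_field["lat"].values[20])
        lon = float(uniform_prey_field["lon"].values[30])
        got = extract_biomass(uniform_prey_field, (lat, lon), 1.0)
        from seabird_cascade.prey_supply import cell_areas_km2

        area = float(cell_areas_km2(uniform_prey_field).sel(lat=lat))
        assert got == pytest.approx(area, rel=1e-9)

    def test_linear_in_density(self, prey_field):
        doubled = (prey_field * 2.0).assign_attrs(prey_field.attrs)
        a = extract_biomass(prey_field, CENTER, 400.0)
        b = extract_biomass(doubled, CENTER, 400.0)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_discretization_error_shrinks_with_resolution(self):
        errs = {}
        for res in (1.0, 0.25):
            field = generate_prey_field(
                PreyFieldSimParams(grid_resolution=res, n_months=1,
                                   lognormal_cv=0.0, mean_density=1.0, seed=0)
            )
            got = extract_biomass(field, CENTER, 500.0)
            errs[res] = abs(got - np.pi * 500.0**2) / (np.pi * 500.0**2)
        assert errs[0.25] < errs[1.0]

    def test_disc_outside_grid_raises(self, prey_field):
        with pytest.raises(EmptyExtractionError):
            extract_biomass(prey_field, (60.0, -150.0), 100.0)

    def test_wrong_units_rejected(self, prey_field):
        bad = prey_field.copy()
        bad.attrs["units"] = "kg m-2"
        with pytest.raises(UnitMismatchError):
            extract_biomass(bad, CENTER, 100.0)


class TestProductionAndThreshold:
    def test_pb_interval_reference_values(self):
        lo, hi = production_from_biomass(1_000_000.0)
        assert (lo, hi) == (1_400_000.0, 3_400_000.0)

    def test_zero_biomass_zero_production(self):
        assert production_from_biomass(0.0) == (0.0, 0.0)

    def test_threshold_multipliers_of_standing_biomass(self):
        # 25% of P/B 1.4 and 3.4 -> 0.35-0.85 x biomass per year
        lo, hi = sustainable_threshold(production_from_biomass(1.0))
        assert lo == pytest.approx(0.35)
        assert hi == pytest.approx(0.85)

    def test_quarter_of_production(self):
        assert sustainable_threshold((100.0, 100.0)) == (25.0, 25.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(biomass=st.floats(0.0, 1e9), scale=st.floats(0.001, 1e3))
    def test_interval_ordering_and_linearity(self, biomass, scale):
        lo, hi = production_from_biomass(biomass)
        assert lo <= hi
        lo2, hi2 = production_from_biomass(biomass * scale)
        assert lo2 == pytest.approx(lo * scale)
        assert hi2 == pytest.approx(hi * scale)

    def test_invalid_assumptions_rejected(self):
        with pytest.raises(ParameterError):
            PreyAssumptions(pb_at_tl_low=0.0)
        with pytest.raises(ParameterError):
            PreyAssumptions(sustainable_fraction=1.0)


class TestAssessSupply:
    def test_consumption_far_below_threshold(self, uniform_prey_field):
        res = assess_supply(100.0, uniform_prey_field, CENTER, 500.0)
        assert res.exceedance_prob_low == 0.0
        assert res.exceedance_prob_high == 0.0

    def test_tie_at_low_bound_is_not_exceedance(self, uniform_prey_field):
        probe = assess_supply(1.0, uniform_prey_field, CENTER, 500.0)
        at_bound = probe.threshold_tons_per_year[0]
        res = assess_supply(at_bound, uniform_prey_field, CENTER, 500.0)
        assert res.exceedance_prob_low == 0.0  # strictly-greater convention
        res2 = assess_supply(np.nextafter(at_bound, np.inf), uniform_prey_field, CENTER, 500.0)
        assert res2.exceedance_prob_low == 1.0

    def test_double_threshold_consumption_always_exceeds(self, uniform_prey_field):
        probe = assess_supply(1.0, uniform_prey_field, CENTER, 500.0)
        lo, hi = probe.threshold_tons_per_year
        res = assess_supply(np.full(50, 2.0 * hi), uniform_prey_field, CENTER, 500.0)
        assert res.exceedance_prob_low == 1.0
        assert res.exceedance_prob_high == 1.0
        # threshold identity holds exactly
        assert res.threshold_tons_per_year[0] == pytest.approx(
            0.25 * res.production_tons_per_year[0]
        )


def test_haversine_known_distance_and_symmetry():
    # one degree of latitude on the sphere: R * pi/180
    d = haversine_km(0.0, 0.0, 1.0, 0.0)
    assert d == pytest.approx(6371.0 * np.pi / 180.0, rel=1e-12)
    assert haversine_km(-5.0, 70.0, 3.0, 80.0) == pytest.approx(
        haversine_km(3.0, 80.0, -5.0, 70.0), rel=1e-12
    )
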