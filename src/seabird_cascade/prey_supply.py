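"""Epipelagic prey supply: extraction, production, and sustainability.

A gridded monthly forage-fish biomass density field (tons/km², an
:class:`xarray.DataArray` with dims ``time, lat, lon``) is reduced to the
mean annual standing stock inside a foraging disc (great-circle radius
around a colony centroid), converted to annual production with
trophic-level-dependent production-to-biomass (P/B) turnover ratios, and
compared against seabird consumption through a sustainable-extraction
criterion: consumption should not exceed 25% of production.

With the default P/B ratios (3.4 /yr at trophic level 3.0, 1.4 /yr at 3.7 —
turnover falls as trophic level rises) the threshold works out to
0.35–0.85 × standing biomass per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .exceptions import EmptyExtractionError, ParameterError, UnitMismatchError

__all__ = [
    "PreyAssumptions",
    "SupplyAssessment",
    "extract_biomass",
    "production_from_biomass",
    "sustainable_threshold",
    "assess_supply",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0
EXPECTED_UNITS = "t km-2"


@dataclass(frozen=True)
class PreyAssumptions:
    """Trophic-level bracket, P/B turnover ratios, and sustainable fraction.

    Note the inversion: the *low* trophic level carries the *high* turnover
    (``pb_at_tl_low`` = 3.4 /yr at TL 3.0) and vice versa (1.4 /yr at 3.7).
    """

    tl_low: float = 3.0
    tl_high: float = 3.7
    pb_at_tl_low: float = 3.4
    pb_at_tl_high: float = 1.4
    sustainable_fraction: float = 0.25

    def __post_init__(self):
        if self.pb_at_tl_low <= 0 or self.pb_at_tl_high <= 0:
            raise ParameterError("P/B ratios must be > 0")
        if not 0 < self.sustainable_fraction < 1:
            raise ParameterError("sustainable_fraction must lie in (0, 1)")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, float)) - np.radians(np.asarray(lon1, float))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _validate_field(field: xr.DataArray):
    for dim in ("time", "lat", "lon"):
        if dim not in field.dims:
            raise ParameterError(f"prey field lacks dimension {dim!r}")
    units = field.attrs.get("units", EXPECTED_UNITS)
    if units != EXPECTED_UNITS:
        raise UnitMismatchError(
            f"prey field units {units!r}; expected {EXPECTED_UNITS!r}"
        )
    if float(field.min()) < 0:
        raise ParameterError("prey density must be nonnegative")


def cell_areas_km2(field: xr.DataArray) -> xr.DataArray:
    """Latitude-corrected cell areas (km²) for a regular lat/lon grid."""
    lat = field["lat"].values
    lon = field["lon"].values
    dlat = np.median(np.diff(lat)) if lat.size > 1 else 1.0
    dlon = np.median(np.diff(lon)) if lon.size > 1 else 1.0
    area = (
        EARTH_RADIUS_KM**2
        * np.radians(dlat)
        * np.radians(dlon)
        * np.cos(np.radians(lat))
    )
    return xr.DataArray(area, dims=("lat",), coords={"lat": lat})


def extract_biomass(
    field: xr.DataArray, center: tuple[float, float], radius_km: float
) -> float:
    """Mean annual standing stock (tons) inside a foraging disc.

    Cells belong to the disc if their centers lie within ``radius_km``
    great-circle distance of ``center = (lat, lon)``; cell areas are
    latitude-corrected.  The monthly total is averaged over the field's
    time axis.  A disc containing no cell centers raises
    :class:`~seabird_cascade.exceptions.EmptyExtractionError`.
    """
    _validate_field(field)
    if radius_km <= 0:
        raise ParameterError("radius_km must be > 0")
    clat, clon = center
    lat2d, lon2d = xr.broadcast(field["lat"], field["lon"])
    dist = haversine_km(clat, clon, lat2d.values, lon2d.values)
    mask = xr.DataArray(
        dist <= radius_km, dims=("lat", "lon"),
        coords={"lat": field["lat"], "lon": field["lon"]},
    )
    if not bool(mask.any()):
        raise EmptyExtractionError(
            f"no grid cells within {radius_km} km of ({clat}, {clon})"
        )
    per_month = (field.where(mask, 0.0) * cell_areas_km2(field)).sum(dim=("lat", "lon"))
    return float(per_month.mean(dim="time"))


def production_from_biomass(
    biomass_tons: float, assumptions: PreyAssumptions = PreyAssumptions()
) -> tuple[float, float]:
    """Annual production interval (tons/yr): biomass × P/B at each TL bound.

    Low bound uses the high-TL (slow-turnover) ratio; high bound the low-TL
    (fast-turnover) ratio, so ``low <= high`` always.
    """
    if biomass_tons < 0:
        raise ParameterError("biomass must be >= 0")
    return (
        biomass_tons * assumptions.pb_at_tl_high,
        biomass_tons * assumptions.pb_at_tl_low,
    )


def sustainable_threshold(
    production: tuple[float, float], assumptions: PreyAssumptions = PreyAssumptions()
) -> tuple[float, float]:
    """Sustainable extraction interval: 25% of production per bound."""
    lo, hi = production
    if lo < 0 or hi < lo:
        raise ParameterError("production must be an ordered nonnegative interval")
    return (assumptions.sustainable_fraction * lo, assumptions.sustainable_fraction * hi)


@dataclass
class SupplyAssessment:
    """Standing stock, production and threshold intervals, and exceedance.

    ``exceedance_prob_low/high`` are the posterior probabilities that
    consumption strictly exceeds each threshold bound (ties do not count as
    exceedance).
    """

    standing_biomass_tons: float
    production_tons_per_year: tuple[float, float]
    threshold_tons_per_year: tuple[float, float]
    consumption_draws: np.ndarray
    exceedance_prob_low: float
    exceedance_prob_high: float

    def to_dict(self) -> dict:
        cons = self.consumption_draws
        return {
            "standing_biomass_tons": self.standing_biomass_tons,
            "production_tons_per_year": list(self.production_tons_per_year),
            "threshold_tons_per_year": list(self.threshold_tons_per_year),
            "consumption_mean_tons_per_year": float(np.mean(cons)),
            "consumption_q2.5": float(np.quantile(cons, 0.025)),
            "consumption_q97.5": float(np.quantile(cons, 0.975)),
            "exceedance_prob_low": self.exceedance_prob_low,
            "exceedance_prob_high": self.exceedance_prob_high,
        }


def assess_supply(
    consumption_tons_per_year,
    field: xr.DataArray,
    center: tuple[float, float],
    radius_km: float,
    assumptions: PreyAssumptions = PreyAssumptions(),
) -> SupplyAssessment:
    """Compare consumption draws against the sustainable-extraction interval.

    ``consumption_tons_per_year`` is a scalar or an array of posterior
    draws.  Exceedance uses strict inequality: consumption exactly at a
    bound is *not* an exceedance.
    """
    cons = np.atleast_1d(np.asarray(consumption_tons_per_year, dtype=float))
    if np.any(cons < 0):
        raise ParameterError("consumption must be >= 0")
    biomass = extract_biomass(field, center, radius_km)
    production = production_from_biomass(biomass, assumptions)
    threshold = sustainable_threshold(production, assumptions)
    return SupplyAssessment(
        standing_biomass_tons=biomass,
        production_tons_per_year=production,
        threshold_tons_per_year=threshold,
        consumption_draws=cons,
        exceedance_prob_low=float(np.mean(cons > threshold[0])),
        exceedance_prob_high=float(np.mean(cons > threshold[1])),
    )
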