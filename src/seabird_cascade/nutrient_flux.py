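"""Seabird-derived nitrogen fluxes onto islands.

Annual nitrogen input per island is the sum over species of::

    pairs × adults_per_pair × defecation(mass) [g dry guano/day]
          × guano_N_fraction × season_days / 1000   [kg N/yr]

with an allometric defecation rate ``defecation(m) = a · m^b`` (g/day per
bird for body mass m in grams).  The defecation and guano-N constants are
configuration data (see ``data/species_profiles_synthetic.yaml``); the code
supplies only the functional form and bookkeeping.  Budgets are degree-1
homogeneous in abundance and season length, and accept posterior abundance
draws, which flow through to per-hectare rates and archipelago totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .bioenergetics import SpeciesProfile
from .exceptions import ConfigurationError, JoinError, ParameterError
from .scenarios import AbundancePrediction

__all__ = ["ExcretionConstants", "NitrogenBudget", "nitrogen_input", "scenario_nitrogen"]

KG_PER_TON = 1000.0


@dataclass(frozen=True)
class ExcretionConstants:
    """Allometric defecation rate and guano nitrogen content."""

    defecation_coef_g_per_day: float
    defecation_mass_exponent: float
    guano_n_fraction: float
    #: fraction of the season's defecation deposited at the colony
    colony_residence_fraction: float = 1.0
    citation: str = ""

    def __post_init__(self):
        if self.defecation_coef_g_per_day <= 0:
            raise ParameterError("defecation coefficient must be > 0")
        if not 0 < self.guano_n_fraction < 1:
            raise ParameterError("guano_n_fraction must lie in (0, 1)")
        if not 0 < self.colony_residence_fraction <= 1:
            raise ParameterError("colony_residence_fraction must lie in (0, 1]")

    def defecation_g_per_day(self, mass_g: float) -> float:
        if mass_g <= 0:
            raise ParameterError("mass must be > 0")
        return self.defecation_coef_g_per_day * mass_g**self.defecation_mass_exponent


@dataclass
class NitrogenBudget:
    """Per-island nitrogen input, kg N/yr, with a draw dimension.

    ``kg_per_year`` has dims ``(draw, island)``; point budgets carry a
    singleton draw axis.  ``area_ha`` aligns with the island coordinate and
    supplies per-hectare normalization.
    """

    kg_per_year: xr.DataArray
    area_ha: pd.Series

    def __post_init__(self):
        islands = [str(i) for i in self.kg_per_year.coords["island"].values]
        missing = set(islands) - set(self.area_ha.index.astype(str))
        if missing:
            raise JoinError(f"areas missing for islands: {sorted(missing)}")
        self.area_ha = self.area_ha.astype(float).reindex(islands)

    @property
    def islands(self) -> list[str]:
        return [str(i) for i in self.kg_per_year.coords["island"].values]

    def per_ha(self) -> xr.DataArray:
        """kg N ha⁻¹ yr⁻¹ per island (draw, island)."""
        areas = xr.DataArray(
            self.area_ha.values, dims=("island",), coords={"island": self.islands}
        )
        return self.kg_per_year / areas

    def total_tons_draws(self) -> np.ndarray:
        """Archipelago total, tons N/yr, per draw."""
        return self.kg_per_year.sum(dim="island").values / KG_PER_TON

    def mean_per_island_kg_yr(self) -> pd.Series:
        return pd.Series(
            self.kg_per_year.mean(dim="draw").values, index=self.islands
        )

    def summary(self) -> pd.DataFrame:
        per_ha = self.per_ha()
        return pd.DataFrame(
            {
                "island_id": self.islands,
                "kg_per_year": self.kg_per_year.mean(dim="draw").values,
                "kg_per_ha_per_year": per_ha.mean(dim="draw").values,
                "area_ha": self.area_ha.values,
            }
        )


def _species_kg_per_pair_year(
    profile: SpeciesProfile, constants: ExcretionConstants
) -> float:
    """kg N per breeding pair per year for one species."""
    g_per_day = constants.defecation_g_per_day(profile.adult_mass_g)
    return (
        profile.adults_per_pair
        * g_per_day
        * constants.guano_n_fraction
        * profile.season_length_days
        * constants.colony_residence_fraction
        / 1000.0
    )


def nitrogen_input(
    abundances: pd.DataFrame | xr.DataArray,
    profiles: Mapping[str, SpeciesProfile],
    constants: ExcretionConstants,
    area_ha: pd.Series,
) -> NitrogenBudget:
    """Annual nitrogen budget from per-island, per-species abundances.

    ``abundances`` is either a census-style wide table (``island_id`` +
    ``pairs_<species>`` columns; point estimate, singleton draw axis) or an
    :class:`xarray.DataArray` of posterior draws with dims
    ``(draw, island, species)``.  Every species present must have a profile.
    """
    if isinstance(abundances, pd.DataFrame):
        if "island_id" not in abundances.columns:
            raise JoinError("abundance table needs an island_id column")
        species = [c[len("pairs_"):] for c in abundances.columns if c.startswith("pairs_")]
        arr = xr.DataArray(
            abundances[[f"pairs_{s}" for s in species]].to_numpy(float)[None, :, :],
            dims=("draw", "island", "species"),
            coords={
                "island": abundances["island_id"].astype(str).to_numpy(),
                "species": species,
            },
        )
    else:
        arr = abundances
        species = [str(s) for s in arr.coords["species"].values]

    missing = [s for s in species if s not in profiles]
    if missing:
        raise ConfigurationError(f"no species profile for: {missing}")

    rates = xr.DataArray(
        [_species_kg_per_pair_year(profiles[s], constants) for s in species],
        dims=("species",),
        coords={"species": species},
    )
    kg = (arr * rates).sum(dim="species")
    return NitrogenBudget(kg_per_year=kg, area_ha=area_ha)


def scenario_nitrogen(
    census: pd.DataFrame,
    prediction: AbundancePrediction,
    profiles: Mapping[str, SpeciesProfile],
    constants: ExcretionConstants,
) -> NitrogenBudget:
    """Nitrogen budget under a restoration scenario.

    The budget keeps the census (current) contribution for every species
    *not* covered by the prediction and for islands outside the prediction
    set, and replaces the focal species' contribution on predicted islands
    with the posterior abundance draws.  By construction the result is never
    below the non-focal baseline.
    """
    if "island_id" not in census.columns:
        raise JoinError("census needs an island_id column")
    census = census.set_index(census["island_id"].astype(str), drop=False)
    pred_islands = [str(i) for i in prediction.draws.coords["island"].values]
    missing = set(pred_islands) - set(census.index)
    if missing:
        raise JoinError(f"prediction islands absent from census: {sorted(missing)}")

    focal = [str(s) for s in prediction.draws.coords["species"].values]
    all_species = [c[len("pairs_"):] for c in census.columns if c.startswith("pairs_")]
    area = pd.Series(census["area_ha"].to_numpy(float), index=census.index)

    miss_prof = [s for s in set(all_species) | set(focal) if s not in profiles]
    if miss_prof:
        raise ConfigurationError(f"no species profile for: {sorted(miss_prof)}")

    # baseline: everything current, minus focal species on predicted islands
    base_kg = np.zeros(len(census))
    for s in all_species:
        rate = _species_kg_per_pair_year(profiles[s], constants)
        pairs = census[f"pairs_{s}"].to_numpy(float)
        if s in focal:
            pairs = pairs.copy()
            pairs[census.index.isin(pred_islands)] = 0.0
        base_kg += pairs * rate

    S = prediction.draws.sizes["draw"]
    kg = np.tile(base_kg, (S, 1))
    isl_pos = {isl: j for j, isl in enumerate(census.index)}
    pred_vals = prediction.draws.values  # (draw, island, species)
    for k, s in enumerate(focal):
        rate = _species_kg_per_pair_year(profiles[s], constants)
        for i, isl in enumerate(pred_islands):
            kg[:, isl_pos[isl]] += pred_vals[:, i, k] * rate

    da = xr.DataArray(
        kg, dims=("draw", "island"), coords={"island": list(census.index)}
    )
    return NitrogenBudget(kg_per_year=da, area_ha=area)
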