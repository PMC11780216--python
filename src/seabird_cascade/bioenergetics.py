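"""Seabird bioenergetics: from breeding pairs to annual prey consumption.

The chain is: allometric field metabolic rate (FMR, kJ/day) per breeding
phase → daily prey intake per individual (g/day) given prey energy density
and assimilation efficiency → annual colony consumption (tons/yr) as the
product of intake, phase durations, breeding pairs and adults per pair.
Every step is linear in abundance, so posterior draws of abundance pass
straight through.

FMR follows the allometric form ``FMR = exp(a + b·ln(mass_g) + c·|lat|)``
with phase-specific coefficients supplied as configuration data (see
``data/species_profiles_synthetic.yaml``); only breeding adults within the
breeding season are counted, since these species disperse away from the
colony outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "SpeciesProfile",
    "EnergeticsConstants",
    "field_metabolic_rate",
    "daily_intake",
    "annual_consumption",
    "load_species_profiles",
    "load_constants",
]

GRAMS_PER_TON = 1e6


@dataclass(frozen=True)
class SpeciesProfile:
    """Morphology, phenology, foraging ranges and FMR coefficients of one species.

    ``fmr_coefficients`` maps each breeding-phase name to ``(intercept,
    mass_exponent, latitude_term)`` of the log-linear FMR model.  Phase
    durations must partition (at most) the breeding season.
    """

    species: str
    adult_mass_g: float
    colony_latitude_deg: float
    breeding_phases: tuple[tuple[str, float], ...]
    season_length_days: float
    max_foraging_radius_km: float
    mean_foraging_radius_km: float
    fmr_coefficients: Mapping[str, tuple[float, float, float]]
    adults_per_pair: int = 2

    def __post_init__(self):
        if self.adult_mass_g <= 0:
            raise ParameterError("adult_mass_g must be > 0")
        if self.max_foraging_radius_km <= 0 or self.mean_foraging_radius_km <= 0:
            raise ParameterError("foraging radii must be > 0")
        if any(d <= 0 for _, d in self.breeding_phases):
            raise ParameterError("phase durations must be > 0")
        if sum(d for _, d in self.breeding_phases) > self.season_length_days + 1e-9:
            raise ParameterError("phase durations exceed the breeding season")

    @property
    def phase_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.breeding_phases)


@dataclass(frozen=True)
class EnergeticsConstants:
    """Prey energy density (kJ/g wet mass) and assimilation efficiency."""

    prey_energy_density_kj_per_g: float = 5.5
    assimilation_efficiency: float = 0.75

    def __post_init__(self):
        if self.prey_energy_density_kj_per_g <= 0:
            raise ParameterError("prey energy density must be > 0")
        if not 0 < self.assimilation_efficiency <= 1:
            raise ParameterError("assimilation efficiency must lie in (0, 1]")


def field_metabolic_rate(profile: SpeciesProfile, phase: str) -> float:
    """Phase-specific FMR in kJ/day: ``exp(a + b·ln(mass) + c·|latitude|)``."""
    if phase not in profile.fmr_coefficients:
        raise ConfigurationError(
            f"no FMR coefficients for phase {phase!r} of {profile.species}"
        )
    a, b, c = profile.fmr_coefficients[phase]
    fmr = float(np.exp(a + b * np.log(profile.adult_mass_g) + c * abs(profile.colony_latitude_deg)))
    if not np.isfinite(fmr) or fmr <= 0:
        raise ConfigurationError("FMR must be positive and finite")
    return fmr


def daily_intake(fmr_kj_per_day, constants: EnergeticsConstants):
    """Daily prey intake per individual, g/day: ``FMR / (density × efficiency)``."""
    fmr = np.asarray(fmr_kj_per_day, dtype=float)
    if np.any(fmr <= 0):
        raise ParameterError("FMR must be > 0")
    return fmr / (constants.prey_energy_density_kj_per_g * constants.assimilation_efficiency)


def annual_consumption(abundance_pairs, profile: SpeciesProfile, constants: EnergeticsConstants):
    """Annual prey consumption, tons/yr, for an abundance of breeding pairs.

    ``tons/yr = Σ_phases intake_phase(g/day) × duration(days) × pairs ×
    adults_per_pair / 1e6``.  ``abundance_pairs`` may be a scalar or an
    array of posterior draws; the output has the same shape.
    """
    pairs = np.asarray(abundance_pairs, dtype=float)
    if np.any(pairs < 0):
        raise ParameterError("abundance must be >= 0")
    grams_per_bird = sum(
        daily_intake(field_metabolic_rate(profile, name), constants) * days
        for name, days in profile.breeding_phases
    )
    out = pairs * profile.adults_per_pair * grams_per_bird / GRAMS_PER_TON
    return float(out) if np.isscalar(abundance_pairs) else out


# -- configuration loading ------------------------------------------------


def _profile_from_dict(name: str, d: dict) -> SpeciesProfile:
    try:
        return SpeciesProfile(
            species=name,
            adult_mass_g=float(d["adult_mass_g"]),
            colony_latitude_deg=float(d["colony_latitude_deg"]),
            breeding_phases=tuple((p["name"], float(p["days"])) for p in d["breeding_phases"]),
            season_length_days=float(d["season_length_days"]),
            max_foraging_radius_km=float(d["max_foraging_radius_km"]),
            mean_foraging_radius_km=float(d["mean_foraging_radius_km"]),
            fmr_coefficients={
                k: tuple(float(x) for x in v) for k, v in d["fmr_coefficients"].items()
            },
            adults_per_pair=int(d.get("adults_per_pair", 2)),
        )
    except KeyError as e:
        raise ConfigurationError(f"species profile {name!r} lacks field {e}") from e


def _default_config_text() -> str:
    return (
        resources.files("seabird_cascade")
        .joinpath("data/species_profiles_synthetic.yaml")
        .read_text()
    )


def load_species_profiles(path=None) -> dict[str, SpeciesProfile]:
    """Load species profiles from YAML (package default if ``path`` is None).

    The shipped default file carries synthetic stand-in constants calibrated
    to realistic magnitudes; swap in transcribed published values via
    ``path`` for real analyses.
    """
    text = _default_config_text() if path is None else open(path).read()
    cfg = yaml.safe_load(text)
    return {name: _profile_from_dict(name, d) for name, d in cfg["species"].items()}


def load_constants(path=None) -> dict:
    """Load energetics and excretion constants from the same YAML layout."""
    from .nutrient_flux import ExcretionConstants

    text = _default_config_text() if path is None else open(path).read()
    cfg = yaml.safe_load(text)
    e = cfg.get("energetics", {})
    x = cfg.get("excretion", {})
    return {
        "energetics": EnergeticsConstants(
            prey_energy_density_kj_per_g=float(e.get("prey_energy_density_kj_per_g", 5.5)),
            assimilation_efficiency=float(e.get("assimilation_efficiency", 0.75)),
        ),
        "excretion": ExcretionConstants(
            defecation_coef_g_per_day=float(x["defecation_coef_g_per_day"]),
            defecation_mass_exponent=float(x["defecation_mass_exponent"]),
            guano_n_fraction=float(x["guano_n_fraction"]),
            citation=str(x.get("citation", "")),
        ),
    }
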