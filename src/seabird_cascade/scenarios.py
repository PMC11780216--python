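"""Restoration-scenario predictions of breeding-seabird abundance.

Scenarios set rat status to absent and native vegetation cover to a target
proportion (the canonical set is 25%, 50% and 75% cover — roughly the lower
quartile, mean and upper quartile of native cover across the archipelago's
islands).  Predictions use only the lognormal (positive) component of the
fitted hurdle model: the question is how many pairs an island could host
once rats are gone, so the zero process is bypassed.

Per posterior draw, the expected pairs on an island are the lognormal mean
``exp(mu + sigma²/2 [+ tau²/2])``; including the residual variance and
integrating the island random intercept (new-island prediction) are the
defaults, with flags to use the median ``exp(mu)`` or to condition on a zero
island effect instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .census import HurdlePosterior
from .diagnostics import hpd_interval
from .exceptions import ParameterError, SchemaError, UndefinedRatioError

__all__ = ["Scenario", "CANONICAL_SCENARIOS", "AbundancePrediction", "predict_abundance", "fold_change", "FoldChange"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """A rat-eradication + vegetation-restoration scenario."""

    name: str
    native_cover: float
    rat_status: str = "absent"

    def __post_init__(self):
        if not 0.0 <= self.native_cover <= 1.0:
            raise ParameterError("native_cover must lie in [0, 1]")
        if self.rat_status != "absent":
            raise ParameterError("restoration scenarios assume rats are eradicated")


CANONICAL_SCENARIOS = (
    Scenario("eradication_25pct_cover", 0.25),
    Scenario("eradication_50pct_cover", 0.50),
    Scenario("eradication_75pct_cover", 0.75),
)


@dataclass
class AbundancePrediction:
    """Posterior draws of predicted breeding pairs under one scenario.

    ``draws`` has dims (draw, island, species); totals sum over islands
    (and species, for the overall total) within each draw, so totals carry
    full posterior uncertainty.
    """

    scenario: Scenario
    draws: xr.DataArray
    island_ids: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.draws.coords["species"].values]

    def totals_by_species(self) -> xr.DataArray:
        """(draw, species) totals over islands."""
        return self.draws.sum(dim="island")

    def total_draws(self) -> np.ndarray:
        """Overall total pairs per draw."""
        return self.draws.sum(dim=("island", "species")).values

    def summary(self, hdi_prob: float = 0.95) -> pd.DataFrame:
        """Tidy per-island, per-species posterior mean and quantile interval."""
        a = (1 - hdi_prob) / 2
        arr = self.draws
        mean = arr.mean(dim="draw")
        lo = arr.quantile(a, dim="draw")
        hi = arr.quantile(1 - a, dim="draw")
        rows = []
        for i, isl in enumerate(arr.coords["island"].values):
            for j, sp in enumerate(arr.coords["species"].values):
                rows.append(
                    {
                        "scenario": self.scenario.name,
                        "island_id": str(isl),
                        "species": str(sp),
                        "mean": float(mean[i, j]),
                        "lower": float(lo[i, j]),
                        "upper": float(hi[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def predict_abundance(
    posterior: HurdlePosterior,
    islands: pd.DataFrame,
    scenario: Scenario,
    *,
    mean_type: str = "mean",
    island_effect: str = "integrate",
) -> AbundancePrediction:
    """Predict per-island, per-species breeding pairs under a scenario.

    ``islands`` needs columns ``island_id`` and ``area_ha``; the scenario
    fixes rat status (absent) and native cover for every island.  Covariates
    are standardized with the transform stored at fit time.  A scenario
    covariate outside the training range logs a warning but does not error.

    ``mean_type``: "mean" uses the lognormal mean ``exp(mu + sigma²/2)``;
    "median" uses ``exp(mu)``.  ``island_effect``: "integrate" adds
    ``tau²/2`` (marginal new-island mean, only with ``mean_type="mean"``);
    "zero" conditions on a zero island intercept.
    """
    if "island_id" not in islands.columns or "area_ha" not in islands.columns:
        raise SchemaError("islands table needs island_id and area_ha columns")
    if islands["area_ha"].isna().any():
        raise SchemaError("island area missing")
    if mean_type not in ("mean", "median"):
        raise ParameterError("mean_type must be 'mean' or 'median'")
    if island_effect not in ("integrate", "zero"):
        raise ParameterError("island_effect must be 'integrate' or 'zero'")

    std = posterior.standardization
    z_la = std.z_log_area(islands["area_ha"].to_numpy(float))
    z_nc = np.full(len(islands), float(std.z_native_cover(scenario.native_cover)))
    if np.any(np.abs(z_la) > 3) or abs(z_nc[0]) > 3:
        logger.warning(
            "scenario covariates more than 3 training sds from the mean; "
            "predictions extrapolate (max |z_log_area|=%.2f, |z_cover|=%.2f)",
            float(np.abs(z_la).max()),
            abs(float(z_nc[0])),
        )

    S = posterior.n_draws
    beta = posterior.beta.reshape(S, -1)
    name_idx = {n: j for j, n in enumerate(posterior.feature_names)}
    n_isl, n_sp = len(islands), len(posterior.species)

    mu = np.zeros((S, n_isl, n_sp))
    for k, sp in enumerate(posterior.species):
        key = f"intercept[{sp}]"
        mu[:, :, k] += beta[:, [name_idx[key if key in name_idx else "intercept"]]]
    if "b_log_area" in name_idx:
        mu += (beta[:, [name_idx["b_log_area"]]] * z_la[None, :])[:, :, None]
    if "b_native_cover" in name_idx:
        mu += (beta[:, [name_idx["b_native_cover"]]] * z_nc[None, :])[:, :, None]
    # rat absent: the rat column contributes 0

    if mean_type == "mean":
        extra = posterior.sigma.reshape(S) ** 2
        if island_effect == "integrate" and posterior.u.size:
            extra = extra + posterior.tau.reshape(S) ** 2
        pairs = np.exp(mu + 0.5 * extra[:, None, None])
    else:
        pairs = np.exp(mu)

    da = xr.DataArray(
        pairs,
        dims=("draw", "island", "species"),
        coords={
            "island": islands["island_id"].astype(str).to_numpy(),
            "species": list(posterior.species),
        },
        name="predicted_pairs",
    )
    return AbundancePrediction(
        scenario=scenario, draws=da, island_ids=list(islands["island_id"].astype(str))
    )


@dataclass(frozen=True)
class FoldChange:
    """Posterior of the ratio of predicted to current total pairs."""

    ratio_draws: np.ndarray
    current_total: float

    @property
    def mean(self) -> float:
        return float(self.ratio_draws.mean())

    def interval(self, prob: float = 0.95, kind: str = "quantile") -> tuple[float, float]:
        if kind == "hpd":
            return hpd_interval(self.ratio_draws, prob)
        a = (1 - prob) / 2
        return (
            float(np.quantile(self.ratio_draws, a)),
            float(np.quantile(self.ratio_draws, 1 - a)),
        )


def fold_change(current_total: float, predicted: AbundancePrediction | np.ndarray) -> FoldChange:
    """Fold change of predicted total pairs over the current total.

    ``current_total`` is the observed total breeding pairs across the same
    island set (a plain count, no uncertainty); the ratio is formed per
    posterior draw.  A zero current total raises
    :class:`~seabird_cascade.exceptions.UndefinedRatioError` — report the
    absolute increase instead in that case.
    """
    if current_total < 0:
        raise ParameterError("current_total must be >= 0")
    if current_total == 0:
        raise UndefinedRatioError(
            "current total is zero; fold change undefined (use absolute increase)"
        )
    totals = (
        predicted.total_draws()
        if isinstance(predicted, AbundancePrediction)
        else np.asarray(predicted, dtype=float)
    )
    return FoldChange(ratio_draws=totals / current_total, current_total=float(current_total))
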