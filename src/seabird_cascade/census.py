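"""Hurdle-lognormal modelling of island breeding-seabird censuses.

The census table has one row per island (area in ha, rat status, proportion
of native vegetation cover, and breeding-pair counts per species).  Counts
are heavily zero-inflated, with zeros concentrated on rat-present islands,
and the positive counts are lognormal-tailed; the model is therefore a
hurdle: a Bernoulli-logit part for whether a count is zero (driven by rat
status) and a lognormal regression for positive counts with species-specific
intercepts, shared slopes on z-scored log area and native cover, and an
island random intercept to absorb spatial non-independence.

The module exposes the analysis surface — :func:`prepare_design`,
:func:`fit_hurdle_lognormal`, :func:`posterior_predictive_check`,
:func:`loo_pareto_k` — over :class:`~seabird_cascade.estimators.HurdleLognormalRegression`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import diagnostics
from .diagnostics import LooDiagnostics, hpd_interval, psis_loo
from .estimators import HurdleLognormalRegression
from .exceptions import DegenerateDesignError, ParameterError, SchemaError

__all__ = [
    "HurdleSpec",
    "Standardization",
    "HurdleDesign",
    "HurdlePosterior",
    "PPCSummary",
    "validate_census",
    "prepare_design",
    "fit_hurdle_lognormal",
    "posterior_predictive_check",
    "loo_pareto_k",
]

REQUIRED_COLUMNS = ("island_id", "area_ha", "rat_status", "native_cover")


@dataclass(frozen=True)
class HurdleSpec:
    """Model specification and MCMC schedule for the census hurdle model.

    Priors default to weakly informative choices on the standardized scale:
    Normal(0, 2.5) on coefficients, Normal(0, 1.5) on the hurdle intercept
    (logit scale), half-Student-t(3, 2.5) on the residual and island sds.
    Override any entry via ``priors``.
    """

    hurdle_predictors: tuple[str, ...] = ("rat",)
    positive_predictors: tuple[str, ...] = ("rat", "log_area", "native_cover")
    species_intercepts: bool = True
    island_random_intercept: bool = True
    priors: dict | None = None
    chains: int = 4
    iterations: int = 3000
    warmup: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ParameterError("chains must be >= 2")
        if self.iterations <= self.warmup:
            raise ParameterError("iterations must exceed warmup")
        unknown = set(self.positive_predictors) - {"rat", "log_area", "native_cover"}
        if unknown:
            raise ParameterError(f"unknown positive-part predictors: {unknown}")
        if set(self.hurdle_predictors) - {"rat"}:
            raise ParameterError("hurdle part supports the 'rat' predictor only")

    def prior(self, key: str, default: float) -> float:
        return float((self.priors or {}).get(key, default))


@dataclass(frozen=True)
class Standardization:
    """Stored z-scoring transform (sample mean/sd, ddof=1) for predictions."""

    log_area_mean: float
    log_area_sd: float
    native_cover_mean: float
    native_cover_sd: float

    def z_log_area(self, area_ha):
        return (np.log(np.asarray(area_ha, float)) - self.log_area_mean) / self.log_area_sd

    def z_native_cover(self, cover):
        return (np.asarray(cover, float) - self.native_cover_mean) / self.native_cover_sd

    def inverse_log_area(self, z):
        return np.exp(np.asarray(z, float) * self.log_area_sd + self.log_area_mean)

    def inverse_native_cover(self, z):
        return np.asarray(z, float) * self.native_cover_sd + self.native_cover_mean


@dataclass
class HurdleDesign:
    """Long-format design produced by :func:`prepare_design`."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: list[str]
    hurdle_feature_idx: list[int]
    species: tuple[str, ...]
    standardization: Standardization
    long: pd.DataFrame
    islands: pd.DataFrame


def validate_census(census: pd.DataFrame, species: Sequence[str] | None = None):
    """Check the census schema; return the species list (from pairs_* columns)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in census.columns]
    if missing:
        raise SchemaError(f"census table lacks required columns: {missing}")
    pair_cols = [c for c in census.columns if c.startswith("pairs_")]
    found = tuple(c[len("pairs_") :] for c in pair_cols)
    if species is not None:
        absent = [s for s in species if s not in found]
        if absent:
            raise SchemaError(f"census lacks species columns: {absent}")
        found = tuple(species)
    if not found:
        raise SchemaError("census table has no pairs_<species> columns")
    if (census["area_ha"] <= 0).any():
        raise SchemaError("area_ha must be > 0")
    if ((census["native_cover"] < 0) | (census["native_cover"] > 1)).any():
        raise SchemaError("native_cover must lie in [0, 1]")
    bad = set(census["rat_status"].unique()) - {"present", "absent"}
    if bad:
        raise SchemaError(f"rat_status must be 'present'/'absent', got {bad}")
    for sp in found:
        col = census[f"pairs_{sp}"]
        if (col < 0).any() or not np.allclose(col, np.round(col)):
            raise SchemaError(f"pairs_{sp} must be nonnegative integers")
    return found


def prepare_design(
    census: pd.DataFrame,
    spec: HurdleSpec,
    species: Sequence[str] | None = None,
    drop_islands: Sequence[str] = (),
) -> HurdleDesign:
    """Build standardized long-format design matrices from a census table.

    Log island area and native cover are z-scored across islands (sample sd,
    ddof=1) and the transform is stored so that scenario predictions apply
    the identical scaling.  Counts are stacked long over species.  Islands in
    ``drop_islands`` (e.g. a confounded inhabited island) are removed first.
    A binary rat covariate with no variation is dropped with a warning;
    a zero-variance continuous covariate raises
    :class:`~seabird_cascade.exceptions.DegenerateDesignError`.
    """
    species = validate_census(census, species)
    df = census[~census["island_id"].isin(set(drop_islands))].reset_index(drop=True)
    if df["island_id"].duplicated().any():
        raise SchemaError("island_id values must be unique")

    rat = (df["rat_status"] == "present").astype(float).to_numpy()
    n_rat, n_free = int(rat.sum()), int((1 - rat).sum())
    if min(n_rat, n_free) < 2:
        warnings.warn(
            f"fewer than 2 islands in a rat class (present={n_rat}, absent={n_free}); "
            "rat effects may be weakly identified",
            stacklevel=2,
        )

    log_area = np.log(df["area_ha"].to_numpy(float))
    cover = df["native_cover"].to_numpy(float)
    sds = {"log_area": np.std(log_area, ddof=1), "native_cover": np.std(cover, ddof=1)}
    means = {"log_area": np.mean(log_area), "native_cover": np.mean(cover)}
    for name in ("log_area", "native_cover"):
        degenerate = sds[name] <= 1e-10 * max(1.0, abs(means[name]))
        if name in spec.positive_predictors and degenerate:
            raise DegenerateDesignError(f"covariate {name} has zero variance")
    std = Standardization(
        log_area_mean=float(np.mean(log_area)),
        log_area_sd=float(sds["log_area"]) if sds["log_area"] > 0 else 1.0,
        native_cover_mean=float(np.mean(cover)),
        native_cover_sd=float(sds["native_cover"]) if sds["native_cover"] > 0 else 1.0,
    )

    rat_varies = 0.0 < rat.mean() < 1.0
    hurdle_preds = spec.hurdle_predictors
    pos_preds = spec.positive_predictors
    if not rat_varies and ("rat" in hurdle_preds or "rat" in pos_preds):
        warnings.warn("rat_status does not vary; dropping it from the model", stacklevel=2)
        hurdle_preds = tuple(p for p in hurdle_preds if p != "rat")
        pos_preds = tuple(p for p in pos_preds if p != "rat")

    # long format over island x species
    n_isl = len(df)
    long = pd.DataFrame(
        {
            "island_id": np.tile(df["island_id"].to_numpy(), len(species)),
            "species": np.repeat(list(species), n_isl),
            "rat": np.tile(rat, len(species)),
            "z_log_area": np.tile(std.z_log_area(df["area_ha"]), len(species)),
            "z_native_cover": np.tile(std.z_native_cover(cover), len(species)),
            "pairs": np.concatenate(
                [df[f"pairs_{sp}"].to_numpy(float) for sp in species]
            ),
        }
    )

    cols, names = [], []
    if spec.species_intercepts:
        for sp in species:
            cols.append((long["species"] == sp).to_numpy(float))
            names.append(f"intercept[{sp}]")
    else:
        cols.append(np.ones(len(long)))
        names.append("intercept")
    covariate_map = {
        "rat": ("b_rat", long["rat"].to_numpy()),
        "log_area": ("b_log_area", long["z_log_area"].to_numpy()),
        "native_cover": ("b_native_cover", long["z_native_cover"].to_numpy()),
    }
    hurdle_idx = []
    for pred in ("rat", "log_area", "native_cover"):
        if pred in pos_preds:
            name, col = covariate_map[pred]
            if pred in hurdle_preds:
                hurdle_idx.append(len(cols))
            cols.append(col)
            names.append(name)

    X = np.column_stack(cols)
    return HurdleDesign(
        X=X,
        y=long["pairs"].to_numpy(float),
        groups=long["island_id"].to_numpy(),
        feature_names=names,
        hurdle_feature_idx=hurdle_idx,
        species=tuple(species),
        standardization=std,
        long=long,
        islands=df,
    )


@dataclass
class HurdlePosterior:
    """Posterior draws and metadata of a fitted census hurdle model.

    Arrays are (chain, draw, ...); parameter naming follows the design's
    ``feature_names`` for the positive part and ``hurdle_*`` for the zero
    part.  Holds everything scenario prediction needs (draws plus the stored
    standardization), independent of the fitted estimator object.
    """

    beta: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    u: np.ndarray
    hurdle_gamma: np.ndarray
    feature_names: list[str]
    hurdle_feature_names: list[str]
    island_labels: np.ndarray
    species: tuple[str, ...]
    standardization: Standardization
    rhat: dict[str, float]
    log_lik: np.ndarray | None = None
    design: HurdleDesign | None = field(default=None, repr=False)
    model: HurdleLognormalRegression | None = field(default=None, repr=False)

    def __post_init__(self):
        for arr in (self.beta, self.sigma, self.tau, self.hurdle_gamma):
            if not np.all(np.isfinite(arr)):
                raise ValueError("posterior draws must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("residual sd must be positive in every draw")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def draws(self) -> dict[str, np.ndarray]:
        """Named (chain, draw) arrays of all scalar parameters."""
        out = {}
        for j, name in enumerate(self.feature_names):
            out[name] = self.beta[:, :, j]
        out["sigma"] = self.sigma
        if self.island_labels is not None and self.u.size:
            out["tau"] = self.tau
        for j, name in enumerate(self.hurdle_feature_names):
            out[name] = self.hurdle_gamma[:, :, j]
        return out

    def summary(self, hdi_prob: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd, central 95% quantile interval and HPD interval."""
        rows = []
        a = (1 - hdi_prob) / 2
        for name, arr in self.draws().items():
            flat = arr.reshape(-1)
            lo, hi = hpd_interval(flat, hdi_prob)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    f"q{100 * a:g}": np.quantile(flat, a),
                    f"q{100 * (1 - a):g}": np.quantile(flat, 1 - a),
                    "hpd_lo": lo,
                    "hpd_hi": hi,
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- persistence ------------------------------------------------------

    def to_netcdf(self, path):
        """Write draws and prediction metadata as a NetCDF3 file."""
        std = self.standardization
        ds = xr.Dataset(
            {
                "beta": (("chain", "draw", "feature"), self.beta),
                "sigma": (("chain", "draw"), self.sigma),
                "tau": (("chain", "draw"), self.tau),
                "u": (("chain", "draw", "island"), self.u),
                "hurdle_gamma": (("chain", "draw", "hurdle_feature"), self.hurdle_gamma),
            },
            coords={
                "feature": list(self.feature_names),
                "hurdle_feature": list(self.hurdle_feature_names),
                "island": [str(s) for s in self.island_labels],
            },
            attrs={
                # NetCDF3 attributes hold scalars/strings only -> JSON-encode
                "species": json.dumps(list(self.species)),
                "log_area_mean": std.log_area_mean,
                "log_area_sd": std.log_area_sd,
                "native_cover_mean": std.native_cover_mean,
                "native_cover_sd": std.native_cover_sd,
                "rhat": json.dumps({k: float(v) for k, v in self.rhat.items()}),
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "HurdlePosterior":
        ds = xr.open_dataset(path, engine="scipy")
        std = Standardization(
            log_area_mean=float(ds.attrs["log_area_mean"]),
            log_area_sd=float(ds.attrs["log_area_sd"]),
            native_cover_mean=float(ds.attrs["native_cover_mean"]),
            native_cover_sd=float(ds.attrs["native_cover_sd"]),
        )
        rhat = {k: float(v) for k, v in json.loads(ds.attrs["rhat"]).items()}
        return cls(
            beta=ds["beta"].values,
            sigma=ds["sigma"].values,
            tau=ds["tau"].values,
            u=ds["u"].values,
            hurdle_gamma=ds["hurdle_gamma"].values,
            feature_names=[str(f) for f in ds["feature"].values],
            hurdle_feature_names=[str(f) for f in ds["hurdle_feature"].values],
            island_labels=np.asarray(ds["island"].values),
            species=tuple(json.loads(ds.attrs["species"])),
            standardization=std,
            rhat=rhat,
        )


def fit_hurdle_lognormal(design: HurdleDesign, spec: HurdleSpec) -> HurdlePosterior:
    """Fit the hurdle-lognormal census model by MCMC.

    Runs ``spec.chains`` independent chains; warns (does not error) if any
    split-R̂ exceeds 1.01.  The returned posterior carries pointwise
    log-likelihoods for PSIS-LOO and the standardization record for
    scenario predictions.
    """
    est = HurdleLognormalRegression(
        hurdle_features=tuple(design.hurdle_feature_idx),
        fit_intercept=False,
        prior_sd_beta=spec.prior("beta", 2.5),
        hurdle_prior_sd_intercept=spec.prior("hurdle_intercept", 1.5),
        hurdle_prior_sd_beta=spec.prior("hurdle_beta", 2.5),
        sd_prior_df=spec.prior("sd_df", 3.0),
        sd_prior_scale=spec.prior("sd_scale", 2.5),
        chains=spec.chains,
        iterations=spec.iterations,
        warmup=spec.warmup,
        random_state=spec.seed,
    )
    groups = design.groups if spec.island_random_intercept else None
    est.fit(design.X, design.y, groups=groups)

    chains = spec.chains
    keep = spec.iterations - spec.warmup
    ll = est.log_likelihood_draws(design.X, design.y, groups)
    hurdle_names = ["hurdle_intercept"] + [
        "hurdle_" + _hurdle_name(design.feature_names[i]) for i in design.hurdle_feature_idx
    ]
    rhat = {}
    pos = est.positive_
    for j, name in enumerate(design.feature_names):
        rhat[name] = diagnostics.split_rhat(pos.coef_draws_[:, :, j])
    rhat["sigma"] = diagnostics.split_rhat(pos.sigma_draws_)
    if groups is not None:
        rhat["tau"] = diagnostics.split_rhat(pos.tau_draws_)
    for j, name in enumerate(hurdle_names):
        rhat[name] = diagnostics.split_rhat(est.hurdle_coef_draws_[:, :, j])

    n_isl = pos.group_labels_.size if pos.group_labels_ is not None else 0
    return HurdlePosterior(
        beta=pos.coef_draws_,
        sigma=pos.sigma_draws_,
        tau=pos.tau_draws_ if n_isl else np.zeros_like(pos.sigma_draws_),
        u=pos.u_draws_ if n_isl else np.zeros((chains, keep, 0)),
        hurdle_gamma=est.hurdle_coef_draws_,
        feature_names=list(design.feature_names),
        hurdle_feature_names=hurdle_names,
        island_labels=(
            pos.group_labels_ if n_isl else np.asarray([], dtype=object)
        ),
        species=design.species,
        standardization=design.standardization,
        rhat=rhat,
        log_lik=ll.reshape(chains, keep, -1),
        design=design,
        model=est,
    )


def _hurdle_name(feature_name: str) -> str:
    return feature_name  # b_rat -> hurdle_b_rat via prefix at call site


@dataclass(frozen=True)
class PPCSummary:
    """Observed vs. replicated summaries from a posterior predictive check.

    ``tail_prob`` entries are P(replicated <= observed); values near 0 or 1
    flag a statistic the model fails to reproduce.
    """

    observed: dict[str, float]
    replicated: dict[str, np.ndarray]
    tail_prob: dict[str, float]
    replicates_shape: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "statistic": k,
                "observed": self.observed[k],
                "replicated_mean": float(np.mean(self.replicated[k])),
                "replicated_sd": float(np.std(self.replicated[k])),
                "tail_prob": self.tail_prob[k],
            }
            for k in self.observed
        ]
        return pd.DataFrame(rows)


def posterior_predictive_check(
    posterior: HurdlePosterior, design: HurdleDesign | None = None, random_state: int = 0
) -> PPCSummary:
    """Compare observed census statistics with posterior-predictive replicates.

    Statistics: fraction of zero counts, maximum count, and mean log of the
    positive counts.  One replicated dataset is drawn per posterior draw.
    """
    if design is None:
        design = posterior.design
    if design is None:
        raise ValueError("a design (or a posterior fitted in-session) is required")
    if posterior.model is None:
        raise ValueError("posterior predictive replication requires the fitted model")
    reps = posterior.model.sample_posterior_predictive(
        design.X, groups=design.groups, random_state=random_state
    )

    def stats(arr2d):
        pos_mask = arr2d > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_log_pos = np.array(
                [
                    np.log(row[m]).mean() if m.any() else np.nan
                    for row, m in zip(arr2d, pos_mask)
                ]
            )
        return {
            "zero_fraction": (arr2d == 0).mean(axis=1),
            "max_count": arr2d.max(axis=1),
            "mean_log_positive": mean_log_pos,
        }

    obs = {k: float(v[0]) for k, v in stats(design.y[None, :]).items()}
    rep = stats(reps)
    tail = {
        k: float(np.mean(rep[k][np.isfinite(rep[k])] <= obs[k])) for k in obs
    }
    return PPCSummary(
        observed=obs, replicated=rep, tail_prob=tail, replicates_shape=reps.shape
    )


def loo_pareto_k(posterior: HurdlePosterior, min_draws: int = 1000) -> LooDiagnostics:
    """PSIS-LOO diagnostics from the posterior's stored pointwise log-likelihood."""
    if posterior.log_lik is None:
        raise ValueError("posterior has no stored log-likelihood draws")
    return psis_loo(posterior.log_lik, min_draws=min_draws)
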