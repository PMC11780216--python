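"""End-to-end pipeline: census fit → scenarios → energetics → supply →
nitrogen → reef projection, with seeded determinism and persisted outputs.

A single :class:`RunConfig` (YAML-loadable) names the inputs (real files or
synthetic-generator parameters), the scenario set, the MCMC schedule and a
root seed.  All randomness fans out from that seed through fixed per-stage
subseeds, so a run is a pure function of (config, seed): repeating it yields
an identical summary JSON.  Each stage's outputs are persisted under the
output directory; any stage error aborts with the stage name while keeping
the partial outputs already written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .bioenergetics import annual_consumption, load_constants, load_species_profiles
from .census import HurdleSpec, fit_hurdle_lognormal, loo_pareto_k, prepare_design
from .exceptions import SeabirdCascadeError
from .nutrient_flux import nitrogen_input, scenario_nitrogen
from .prey_supply import PreyAssumptions, assess_supply
from .reef import (
    DEFAULT_REEF_AREA_KM2,
    ReefFitSettings,
    fit_reef_model,
    predict_reef_metrics,
    upscale_fish_biomass,
)
from .scenarios import Scenario, fold_change, predict_abundance
from .synthetic import (
    REEF_METRICS,
    CensusSimParams,
    PreyFieldSimParams,
    ReefSimParams,
    generate_census,
    generate_prey_field,
    generate_reef_survey,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]

ALL_STAGES = ("census", "scenarios", "energetics", "supply", "nitrogen", "reef")
#: fixed per-stage subseed indices — disabling a stage never shifts another's seed
_STAGE_SEED_IDX = {name: i for i, name in enumerate(("simulate",) + ALL_STAGES)}


class PipelineError(SeabirdCascadeError, RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (see ``RunConfig.from_yaml`` for file layout)."""

    census_path: str | None = None
    prey_path: str | None = None
    reef_path: str | None = None
    census_sim: CensusSimParams | None = field(default_factory=CensusSimParams)
    prey_sim: PreyFieldSimParams | None = field(default_factory=PreyFieldSimParams)
    reef_sim: ReefSimParams | None = field(default_factory=ReefSimParams)
    profiles_path: str | None = None
    scenario_covers: tuple[float, ...] = (0.25, 0.50, 0.75)
    chains: int = 4
    iterations: int = 3000
    warmup: int = 1000
    seed: int = 0
    outdir: str = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    centroid: tuple[float, float] = (-5.83, 72.0)
    all_species_radius_km: float = 1200.0
    reef_area_km2: float = DEFAULT_REEF_AREA_KM2
    drop_islands: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise SeabirdCascadeError(f"unknown stages: {sorted(unknown)}")
        for p in (self.census_path, self.prey_path, self.reef_path, self.profiles_path):
            if p is not None and not Path(p).exists():
                raise SeabirdCascadeError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(open(path)) or {}
        kw: dict = {}
        for key in (
            "census_path", "prey_path", "reef_path", "profiles_path", "seed",
            "outdir", "chains", "iterations", "warmup", "all_species_radius_km",
            "reef_area_km2",
        ):
            if key in cfg:
                kw[key] = cfg[key]
        if "scenario_covers" in cfg:
            kw["scenario_covers"] = tuple(float(c) for c in cfg["scenario_covers"])
        if "stages" in cfg:
            kw["stages"] = tuple(cfg["stages"])
        if "centroid" in cfg:
            kw["centroid"] = tuple(float(x) for x in cfg["centroid"])
        if "drop_islands" in cfg:
            kw["drop_islands"] = tuple(cfg["drop_islands"])
        for key, cls_ in (
            ("census_sim", CensusSimParams),
            ("prey_sim", PreyFieldSimParams),
            ("reef_sim", ReefSimParams),
        ):
            if key in cfg:
                kw[key] = None if cfg[key] is None else cls_(**cfg[key])
        return cls(**kw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(entropy=[int(self.seed), _STAGE_SEED_IDX[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def config_hash(self) -> str:
        # outdir is bookkeeping, not part of the scientific configuration
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _interval(draws, a=0.025):
    return [float(np.quantile(draws, a)), float(np.quantile(draws, 1 - a))]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dict.

    The summary (also written to ``<outdir>/summary.json``) holds totals,
    fold changes, consumption vs. sustainability thresholds, nitrogen
    budgets and reef percent changes, plus provenance (config hash, seed,
    package version).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        }
    }

    profiles = load_species_profiles(config.profiles_path)
    constants = load_constants(config.profiles_path)

    # ---- ingest (real files or seeded synthesis) ------------------------
    stage = "ingest"
    try:
        sim_seed = config.stage_seed("simulate")
        if config.census_path:
            census = pd.read_csv(config.census_path)
        else:
            census = generate_census(replace(config.census_sim, seed=sim_seed))
            census.to_csv(outdir / "census_synthetic.csv", index=False)
        if config.prey_path:
            prey = xr.open_dataset(config.prey_path, engine="scipy")["biomass_density"]
        else:
            prey = generate_prey_field(replace(config.prey_sim, seed=sim_seed + 1))
            prey.to_dataset().to_netcdf(outdir / "prey_field_synthetic.nc", engine="scipy")
        if config.reef_path:
            reef_survey = pd.read_csv(config.reef_path)
        else:
            reef_survey = generate_reef_survey(replace(config.reef_sim, seed=sim_seed + 2))
            reef_survey.to_csv(outdir / "reef_survey_synthetic.csv", index=False)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, e) from e

    species = [c[len("pairs_"):] for c in census.columns if c.startswith("pairs_")]
    current_by_species = {s: int(census[f"pairs_{s}"].sum()) for s in species}
    summary["current"] = {
        "pairs_by_species": current_by_species,
        "total_pairs": int(sum(current_by_species.values())),
    }

    posterior = None
    if "census" in config.stages:
        stage = "census"
        try:
            spec = HurdleSpec(
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=config.stage_seed("census"),
            )
            design = prepare_design(census, spec, drop_islands=config.drop_islands)
            posterior = fit_hurdle_lognormal(design, spec)
            posterior.to_netcdf(outdir / "census_posterior.nc")
            posterior.summary().to_csv(outdir / "census_posterior_summary.csv")
            loo = loo_pareto_k(posterior)
            summary["census_fit"] = {
                "n_islands": int(len(design.islands)),
                "species": list(design.species),
                "max_rhat": float(max(posterior.rhat.values())),
                "loo_elpd": loo.elpd,
                "frac_pareto_k_below_0p7": loo.frac_k_below_0p7,
                "frac_pareto_k_below_0p5": loo.frac_k_below_0p5,
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    predictions: dict[str, object] = {}
    if "scenarios" in config.stages and posterior is not None:
        stage = "scenarios"
        try:
            rat_islands = census[census["rat_status"] == "present"]
            target = rat_islands if len(rat_islands) else census
            pred_rows = []
            summary["scenarios"] = {}
            current_focal = int(
                sum(target[f"pairs_{s}"].sum() for s in posterior.species)
            )
            for cover in config.scenario_covers:
                scn = Scenario(f"eradication_{int(round(100 * cover))}pct_cover", cover)
                pred = predict_abundance(posterior, target, scn)
                predictions[scn.name] = pred
                pred_rows.append(pred.summary())
                totals = pred.total_draws()
                entry = {
                    "total_pairs_mean": float(totals.mean()),
                    "total_pairs_interval": _interval(totals),
                    "by_species_mean": {
                        s: float(pred.totals_by_species().sel(species=s).mean())
                        for s in pred.species
                    },
                }
                if current_focal > 0:
                    fc = fold_change(current_focal, pred)
                    entry["fold_change_mean"] = fc.mean
                    entry["fold_change_interval"] = list(fc.interval())
                summary["scenarios"][scn.name] = entry
            pd.concat(pred_rows).to_csv(outdir / "scenario_predictions.csv", index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    consumption_draws: dict[str, dict[str, np.ndarray]] = {}
    if "energetics" in config.stages:
        stage = "energetics"
        try:
            cur = {
                s: annual_consumption(
                    current_by_species[s], profiles[s], constants["energetics"]
                )
                for s in species
            }
            consumption_draws["current"] = {s: np.asarray([v]) for s, v in cur.items()}
            summary["consumption_tons_per_year"] = {
                "current": {
                    **{s: float(v) for s, v in cur.items()},
                    "total": float(sum(cur.values())),
                }
            }
            for name, pred in predictions.items():
                per_sp = {}
                nonfocal = sum(
                    cur[s] for s in species if s not in pred.species
                )
                for s in pred.species:
                    draws = pred.totals_by_species().sel(species=s).values
                    per_sp[s] = annual_consumption(
                        draws, profiles[s], constants["energetics"]
                    )
                consumption_draws[name] = per_sp
                total = sum(per_sp.values()) + nonfocal
                summary["consumption_tons_per_year"][name] = {
                    **{s: float(v.mean()) for s, v in per_sp.items()},
                    "total": float(np.mean(total)),
                    "total_interval": _interval(total),
                }
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    if "supply" in config.stages and consumption_draws:
        stage = "supply"
        try:
            assumptions = PreyAssumptions()
            summary["supply"] = {}
            for name, per_sp in consumption_draws.items():
                total = sum(np.asarray(v, dtype=float) for v in per_sp.values())
                assessment = assess_supply(
                    total, prey, config.centroid, config.all_species_radius_km, assumptions
                )
                summary["supply"][name] = assessment.to_dict()
            per_species_cur = {}
            for s in species:
                assessment = assess_supply(
                    consumption_draws["current"][s],
                    prey,
                    config.centroid,
                    profiles[s].max_foraging_radius_km,
                    assumptions,
                )
                per_species_cur[s] = assessment.to_dict()
            summary["supply"]["per_species_current"] = per_species_cur
            with open(outdir / "supply_assessment.json", "w") as fh:
                json.dump(summary["supply"], fh, indent=2)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    budgets = {}
    if "nitrogen" in config.stages:
        stage = "nitrogen"
        try:
            area = pd.Series(
                census["area_ha"].to_numpy(float),
                index=census["island_id"].astype(str),
            )
            budgets["current"] = nitrogen_input(
                census, profiles, constants["excretion"], area
            )
            for name, pred in predictions.items():
                budgets[name] = scenario_nitrogen(
                    census, pred, profiles, constants["excretion"]
                )
            summary["nitrogen_tons_per_year"] = {
                name: float(np.mean(b.total_tons_draws())) for name, b in budgets.items()
            }
            rows = []
            for name, b in budgets.items():
                df = b.summary()
                df.insert(0, "scenario", name)
                rows.append(df)
            pd.concat(rows).to_csv(outdir / "nitrogen_budgets.csv", index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    if "reef" in config.stages and budgets:
        stage = "reef"
        try:
            settings = ReefFitSettings(
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=config.stage_seed("reef"),
            )
            metrics = [m for m in REEF_METRICS if m in reef_survey.columns]
            posteriors = {
                m: fit_reef_model(reef_survey, m, settings) for m in metrics
            }
            projection = predict_reef_metrics(posteriors, budgets)
            projection.pct_change_summary().to_csv(
                outdir / "reef_pct_change.csv", index=False
            )
            summary["reef"] = {
                "slope_means": {
                    m: float(p.slope.mean()) for m, p in posteriors.items()
                },
                "pct_change": {
                    m: {
                        scn: float(arr.mean(dim="island").values.mean())
                        for scn, arr in per_scn.items()
                        if scn != "current"
                    }
                    for m, per_scn in projection.pct_change.items()
                },
            }
            if "fish_biomass" in posteriors:
                ups = upscale_fish_biomass(projection, config.reef_area_km2)
                summary["reef"]["fish_biomass_tons"] = ups.mean_tons()
                summary["reef"]["fish_biomass_tons_increase"] = {
                    scn: ups.difference_vs_current(scn)
                    for scn in ups.tons_draws
                    if scn != "current"
                }
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def render_report(summary: dict, outdir) -> list[str]:
    """Render bar-chart figures and tables from a pipeline summary.

    Produces an abundance panel (current vs. scenario totals, log scale), a
    consumption panel with the sustainable-extraction threshold band, and a
    reef percent-change panel.  Missing summary sections are skipped with a
    warning; returns the list of files written.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    scn_names = list(summary.get("scenarios", {}))
    if "current" in summary:
        fig, ax = plt.subplots(figsize=(7, 4))
        labels = ["current"] + scn_names
        totals = [max(summary["current"]["total_pairs"], 0.5)] + [
            summary["scenarios"][s]["total_pairs_mean"] for s in scn_names
        ]
        ax.bar(labels, totals, color=["#e08214"] + ["#c2a5cf", "#9970ab", "#762a83"][: len(scn_names)])
        ax.set_yscale("log")
        ax.set_ylabel("breeding pairs (total)")
        ax.set_title("Predicted breeding pairs under restoration scenarios")
        if scn_names:
            for i, s in enumerate(scn_names, start=1):
                lo, hi = summary["scenarios"][s]["total_pairs_interval"]
                # a heavy-tailed posterior mean can sit outside the quantile
                # interval; clamp the whiskers at zero length
                ax.errorbar(
                    i, totals[i],
                    yerr=[[max(totals[i] - lo, 0.0)], [max(hi - totals[i], 0.0)]],
                    fmt="none", ecolor="k",
                )
        fig.autofmt_xdate(rotation=20)
        path = outdir / "abundance.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))
    else:
        warnings.warn("summary lacks 'current'; skipping abundance figure", stacklevel=2)

    cons = summary.get("consumption_tons_per_year")
    if cons:
        fig, ax = plt.subplots(figsize=(7, 4))
        labels = list(cons)
        vals = [max(cons[k]["total"], 1e-3) for k in labels]
        ax.bar(labels, vals, color="#e08214")
        ax.set_yscale("log")
        ax.set_ylabel("prey consumption (tons/yr)")
        supply = summary.get("supply", {})
        first = next((supply[k] for k in labels if k in supply), None)
        if first:
            lo, hi = first["threshold_tons_per_year"]
            ax.axhline(lo, ls="--", color="#7f3b08", label="threshold (low)")
            ax.axhline(hi, ls="--", color="#fdb863", label="threshold (high)")
            ax.legend()
        ax.set_title("Seabird prey consumption vs. sustainable extraction")
        fig.autofmt_xdate(rotation=20)
        path = outdir / "consumption.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))

    reef = summary.get("reef")
    if reef:
        fig, ax = plt.subplots(figsize=(7, 4))
        metrics = list(reef["pct_change"])
        width = 0.8 / max(len(scn_names), 1)
        x = np.arange(len(metrics))
        for j, s in enumerate(scn_names):
            vals = [reef["pct_change"][m].get(s, np.nan) for m in metrics]
            ax.bar(x + j * width, vals, width, label=s)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(metrics, rotation=15)
        ax.set_ylabel("% change vs. current")
        ax.set_title("Reef responses to restored nitrogen input")
        ax.legend(fontsize=7)
        path = outdir / "reef_changes.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))

    return written
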