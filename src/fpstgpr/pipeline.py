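"""End-to-end orchestration: simulate -> extract -> crosswalk -> model ->
rake -> aggregate -> report -> metareg, from a single YAML config.

Stages communicate through files in the working directory, every artifact
is content-hashed into a manifest, and a rerun with the same config and
seed reproduces identical hashes. Partnered models are fitted before
unpartnered ones (the partnered posterior mean is a covariate of the
unpartnered model), and CPR before the need-share model (the CPR posterior
mean is a covariate of the need model); the stage runner enforces that
ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation as agg
from .constants import AGE_GROUPS, MARITAL_STATUSES, QUANTITY_CPR, QUANTITY_NEED_SHARE
from .consistency import make_consistent
from .crosswalk import apply_crosswalk_frame, estimate_component_bias
from .hierarchy import LocationHierarchy, global_age_weights
from .indicators import extract_estimates
from .metareg import expected_curves
from .methods import ALL_METHODS
from .stgpr import STGPR, StGprConfig, logit, summarize_draws
from .synthetic import (
    GeneratorParams,
    TrueSurface,
    generate_covariates,
    generate_true_surface,
    make_survey_designs,
    simulate_all_surveys,
)
from .hierarchy import generate_population

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "crosswalk", "model", "rake", "aggregate", "report", "metareg")


@dataclass
class RunConfig:
    """Everything a run needs; YAML-serializable."""

    workdir: str = "run"
    seed: int = 0
    # synthetic world (desk scale by default)
    n_super_regions: int = 2
    n_regions_per_super: int = 2
    n_locations_per_region: int = 3
    year_start: int = 1970
    year_end: int = 2019
    cadence: int = 10
    n_per_cell: int = 400
    missing_rate: float = 0.25
    partnered_only_rate: float = 0.0
    # modelling
    n_draws: int = 250
    model_methods: bool = True
    stgpr: dict = field(default_factory=dict)
    crosswalk_scale: str = "natural"
    gamma: float = 0.1
    fp2020_baseline_year: int = 2012
    fp2020_end_year: int = 2019
    fp2020_goal: float = agg.FP2020_GOAL
    fp2020_goal_table: str | None = None
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _model_seed(seed: int, name: str) -> int:
    digest = int(hashlib.sha256(name.encode()).hexdigest()[:8], 16)
    return int(np.random.SeedSequence([seed, digest]).generate_state(1)[0] % (2**31))


_FLOAT_FMT = "%.10g"


class Pipeline:
    """Stage runner bound to a config and working directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.dir = Path(config.workdir)
        self.dir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.dir / name

    # -------------------------------------------------------------- #
    def stage_simulate(self) -> None:
        cfg = self.cfg
        hierarchy = LocationHierarchy.balanced(
            cfg.n_super_regions, cfg.n_regions_per_super, cfg.n_locations_per_region
        )
        covariates = generate_covariates(hierarchy, cfg.years, seed=cfg.seed)
        params = GeneratorParams()
        surface = generate_true_surface(hierarchy, covariates, params, seed=cfg.seed + 10)
        population = generate_population(hierarchy, cfg.years, seed=cfg.seed + 20)
        designs = make_survey_designs(
            hierarchy,
            cfg.years,
            cadence=cfg.cadence,
            n_per_cell=cfg.n_per_cell,
            missing_rate=cfg.missing_rate,
            partnered_only_rate=cfg.partnered_only_rate,
            seed=cfg.seed + 30,
        )
        microdata = simulate_all_surveys(surface, designs, seed=cfg.seed + 1)

        hierarchy.to_csv(self.path("hierarchy.csv"))
        covariates.to_csv(self.path("covariates.csv"), index=False, float_format=_FLOAT_FMT)
        surface.to_csv(self.path("surface.csv"))
        population.to_csv(self.path("population.csv"), index=False, float_format=_FLOAT_FMT)
        ddf = pd.DataFrame(
            [
                {
                    "survey_id": d.survey_id,
                    "location_id": d.location_id,
                    "year": d.year,
                    "n_women": d.n_women,
                    "missing_components": ";".join(sorted(d.missing_components)),
                    "partnered_only": d.partnered_only,
                }
                for d in designs
            ]
        )
        ddf.to_csv(self.path("designs.csv"), index=False)
        microdata.to_csv(self.path("microdata.csv"), index=False, float_format=_FLOAT_FMT)
        gen_cfg = {"seed": cfg.seed, "params": params.to_dict()}
        with open(self.path("generator_config.yaml"), "w") as fh:
            yaml.safe_dump(gen_cfg, fh, sort_keys=True)

    # -------------------------------------------------------------- #
    def _load_designs(self) -> pd.DataFrame:
        return pd.read_csv(self.path("designs.csv"), keep_default_na=False)

    def _missing_map(self) -> dict:
        designs = self._load_designs()
        return {
            r["survey_id"]: frozenset(str(r["missing_components"]).split(";")) - {""}
            for _, r in designs.iterrows()
        }

    def stage_extract(self) -> None:
        self._require("microdata.csv", "extract", "simulate")
        microdata = pd.read_csv(self.path("microdata.csv"))
        est = extract_estimates(microdata, missing_by_survey=self._missing_map())
        est.to_csv(self.path("estimates.csv"), index=False, float_format=_FLOAT_FMT)

    def stage_crosswalk(self) -> None:
        self._require("estimates.csv", "crosswalk", "extract")
        microdata = pd.read_csv(self.path("microdata.csv"))
        missing_map = self._missing_map()
        complete_ids = [s for s, m in missing_map.items() if not m]
        complete = microdata[microdata["survey_id"].isin(complete_ids)]
        biases = estimate_component_bias(complete, scale=self.cfg.crosswalk_scale)
        biases.to_csv(self.path("biases.csv"), index=False, float_format=_FLOAT_FMT)
        estimates = pd.read_csv(self.path("estimates.csv"), keep_default_na=False)
        estimates["mean"] = estimates["mean"].astype(float)
        estimates["se"] = estimates["se"].astype(float)
        adjusted, dropped = apply_crosswalk_frame(estimates, biases)
        adjusted.to_csv(self.path("estimates.csv"), index=False, float_format=_FLOAT_FMT)
        dropped.to_csv(self.path("crosswalk_dropped.csv"), index=False)

    # -------------------------------------------------------------- #
    def _stgpr_config(self, extra_names=()) -> StGprConfig:
        kw = dict(self.cfg.stgpr)
        kw.setdefault("n_draws", self.cfg.n_draws)
        kw["extra_covariates"] = tuple(extra_names)
        return StGprConfig(**kw)

    def _model_quantities(self) -> list[str]:
        qs = [QUANTITY_CPR, QUANTITY_NEED_SHARE]
        if self.cfg.model_methods:
            qs += list(ALL_METHODS)
        return qs

    def _draws_path(self, marital: str, quantity: str) -> Path:
        return self.path(f"draws_{marital}_{quantity}.npy")

    def _fit_one(self, estimates, covariates, hierarchy, marital, quantity, extras, extra_names):
        sub = estimates[
            (estimates["marital"] == marital) & (estimates["quantity"] == quantity)
        ]
        cfg = self._stgpr_config(extra_names)
        model = STGPR(sub, covariates, hierarchy, cfg, extra_covariates=extras)
        res = model.fit(seed=_model_seed(self.cfg.seed, f"{marital}|{quantity}"))
        np.save(self._draws_path(marital, quantity), res.draws.astype(np.float32))
        return model, res

    def stage_model(self, maritals=MARITAL_STATUSES) -> dict:
        self._require("estimates.csv", "model", "crosswalk")
        cfg = self.cfg
        estimates = pd.read_csv(self.path("estimates.csv"), keep_default_na=False)
        estimates["mean"] = estimates["mean"].astype(float)
        estimates["se"] = estimates["se"].astype(float)
        covariates = pd.read_csv(self.path("covariates.csv"))
        hierarchy = LocationHierarchy.from_csv(self.path("hierarchy.csv"))
        if "unpartnered" in maritals and "partnered" not in maritals:
            if not self._draws_path("partnered", QUANTITY_CPR).exists():
                raise RuntimeError(
                    "cannot fit unpartnered models before partnered ones: the partnered "
                    "posterior mean is a covariate of every unpartnered model"
                )
        run_log = {"rmse": {}, "suite": {}}
        cells = None
        post_mean: dict[tuple, pd.DataFrame] = {}
        for marital in [m for m in ("partnered", "unpartnered") if m in maritals]:
            for quantity in self._model_quantities():
                extras = None
                extra_names = []
                frames = []
                if marital == "unpartnered":
                    pm = post_mean[("partnered", quantity)].rename(
                        columns={"hat": "partnered_hat"}
                    )
                    frames.append(pm)
                    extra_names.append("partnered_hat")
                if quantity == QUANTITY_NEED_SHARE:
                    pm = post_mean[(marital, QUANTITY_CPR)].rename(columns={"hat": "cpr_hat"})
                    frames.append(pm)
                    extra_names.append("cpr_hat")
                if frames:
                    extras = frames[0]
                    for f in frames[1:]:
                        extras = extras.merge(f, on=["location_id", "year", "age_group"])
                model, res = self._fit_one(
                    estimates, covariates, hierarchy, marital, quantity, extras, extra_names
                )
                cells = model.cells
                hat = model.cells.copy()
                hat["hat"] = logit(np.clip(res.posterior_mean, 1e-3, 1 - 1e-3))
                post_mean[(marital, quantity)] = hat
                run_log["rmse"][f"{marital}|{quantity}"] = res.stage1.rmse_by_suite
                run_log["suite"][f"{marital}|{quantity}"] = res.stage1.suite
        if cells is not None:
            cells.to_csv(self.path("cells.csv"), index=False)
        with open(self.path("model_log.yaml"), "w") as fh:
            yaml.safe_dump(run_log, fh, sort_keys=True)
        return run_log

    # -------------------------------------------------------------- #
    def _load_draws(self, marital: str, quantity: str) -> np.ndarray:
        p = self._draws_path(marital, quantity)
        if not p.exists():
            raise RuntimeError(f"missing draws for {marital}/{quantity}; run the model stage")
        return np.load(p).astype(float)

    def stage_rake(self) -> None:
        self._require("cells.csv", "rake", "model")
        cells = pd.read_csv(self.path("cells.csv"))
        summaries = []
        for marital in MARITAL_STATUSES:
            cpr = self._load_draws(marital, QUANTITY_CPR)
            need = self._load_draws(marital, QUANTITY_NEED_SHARE)
            methods = np.stack([self._load_draws(marital, m) for m in ALL_METHODS])
            cons = make_consistent(cpr, methods, need)
            np.savez(
                self.path(f"consistent_{marital}.npz"),
                cpr=cons.cpr.astype(np.float32),
                methods=cons.methods.astype(np.float32),
                mcpr=cons.mcpr.astype(np.float32),
                unmet=cons.unmet.astype(np.float32),
                demand_satisfied=cons.demand_satisfied.astype(np.float32),
            )
            for name, arr in (
                ("cpr", cons.cpr),
                ("mcpr", cons.mcpr),
                ("unmet", cons.unmet),
                ("demand_satisfied", cons.demand_satisfied),
            ):
                s = summarize_draws(arr)
                block = cells.copy()
                block["marital"] = marital
                block["quantity"] = name
                block[["mean", "lower", "upper"]] = s.to_numpy()
                summaries.append(block)
        pd.concat(summaries, ignore_index=True).to_csv(
            self.path("summaries.csv"), index=False, float_format=_FLOAT_FMT
        )

    # -------------------------------------------------------------- #
    def _all_women(self, cells: pd.DataFrame) -> dict:
        """Marital-aggregated draws for cpr, methods, need -> derived set."""
        surface = TrueSurface.from_csv(self.path("surface.csv"))
        pp = surface.partnered.set_index(["location_id", "year", "age_group"])[
            "partnered_proportion"
        ]
        key = pd.MultiIndex.from_frame(cells[["location_id", "year", "age_group"]])
        pi = pp.reindex(key).to_numpy()
        p = np.load(self.path("consistent_partnered.npz"))
        u = np.load(self.path("consistent_unpartnered.npz"))
        cpr = agg.aggregate_marital(p["cpr"], u["cpr"], pi)
        methods = np.stack(
            [agg.aggregate_marital(p["methods"][i], u["methods"][i], pi) for i in range(len(ALL_METHODS))]
        )
        # unmet aggregates directly; need share is then implied
        unmet = agg.aggregate_marital(p["unmet"], u["unmet"], pi)
        cons = make_consistent(
            cpr, methods, np.divide(unmet, np.maximum(1 - cpr, 1e-12))
        )
        return {
            "cpr": cons.cpr,
            "methods": cons.methods,
            "mcpr": cons.mcpr,
            "unmet": cons.unmet,
            "demand_satisfied": cons.demand_satisfied,
        }

    def stage_aggregate(self) -> None:
        self._require("consistent_partnered.npz", "aggregate", "rake")
        cells = pd.read_csv(self.path("cells.csv"))
        population = pd.read_csv(self.path("population.csv"))
        allw = self._all_women(cells)
        pop = population.set_index(["location_id", "year", "age_group"])["population"]
        key = pd.MultiIndex.from_frame(cells[["location_id", "year", "age_group"]])
        popv = pop.reindex(key).to_numpy()
        if np.isnan(popv).any():
            raise RuntimeError("population missing for some cells")
        np.savez(
            self.path("allwomen.npz"),
            **{k: v.astype(np.float32) for k, v in allw.items()},
        )
        # age-aggregated (15-49) draws per location-year, plus standardized
        weights = global_age_weights(population, year=min(2019, self.cfg.year_end))
        locs = cells["location_id"].unique()
        years = np.sort(cells["year"].unique())
        n_age = len(AGE_GROUPS)
        n_draws = allw["cpr"].shape[1]
        shape = (len(locs), len(years), n_age)
        out_rows = []
        agg_draws = {}
        for name in ("cpr", "mcpr", "unmet", "demand_satisfied"):
            cube = allw[name].reshape(*shape, n_draws)
            pop_cube = popv.reshape(shape)
            # aggregate over the age axis
            flat = np.moveaxis(cube, 2, 0)
            wflat = np.moveaxis(pop_cube, 2, 0)[..., None]
            agg1549 = agg.weighted_mean_draws(flat, np.broadcast_to(wflat, flat.shape), axis=0)
            std = agg.age_standardize(flat, weights.to_numpy())
            agg_draws[name] = agg1549
            for li, loc in enumerate(locs):
                for yi, yr in enumerate(years):
                    s = summarize_draws(agg1549[li, yi][None, :]).iloc[0]
                    st = summarize_draws(std[li, yi][None, :]).iloc[0]
                    out_rows.append(
                        {
                            "location_id": loc,
                            "year": int(yr),
                            "quantity": name,
                            "mean": s["mean"],
                            "lower": s["lower"],
                            "upper": s["upper"],
                            "mean_age_std": st["mean"],
                        }
                    )
        pd.DataFrame(out_rows).to_csv(
            self.path("agg_summaries.csv"), index=False, float_format=_FLOAT_FMT
        )
        np.savez(
            self.path("agg_draws.npz"),
            **{k: v.astype(np.float32) for k, v in agg_draws.items()},
            locations=locs,
            years=years,
        )

    def stage_report(self) -> None:
        self._require("agg_draws.npz", "report", "aggregate")
        cfg = self.cfg
        data = np.load(self.path("agg_draws.npz"), allow_pickle=True)
        locs = list(data["locations"])
        years = list(data["years"])
        i0, i1 = 0, len(years) - 1
        rows = []
        for name in ("cpr", "mcpr", "unmet", "demand_satisfied"):
            cube = data[name]
            for li, loc in enumerate(locs):
                rows.append(
                    {
                        "location_id": loc,
                        "quantity": name,
                        "draws_2019": cube[li, i1],
                        "draws_1970": cube[li, i0],
                    }
                )
        agg.render_indicator_report(rows).to_csv(self.path("report.csv"), index=False)

        # method mix 2019: share of total use per method, population-weighted
        cells = pd.read_csv(self.path("cells.csv"))
        allw = np.load(self.path("allwomen.npz"))
        population = pd.read_csv(self.path("population.csv"))
        pop = population.set_index(["location_id", "year", "age_group"])["population"]
        key = pd.MultiIndex.from_frame(cells[["location_id", "year", "age_group"]])
        popv = pop.reindex(key).to_numpy()
        last_year = cells["year"].max()
        mask = (cells["year"] == last_year).to_numpy()
        mix_rows = []
        for li, loc in enumerate(locs):
            lmask = mask & (cells["location_id"] == loc).to_numpy()
            cpr = agg.weighted_mean_draws(allw["cpr"][lmask], popv[lmask], axis=0)
            for mi, m in enumerate(ALL_METHODS):
                mm = agg.weighted_mean_draws(allw["methods"][mi][lmask], popv[lmask], axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    share = np.where(cpr > 0, mm / np.maximum(cpr, 1e-12), 0.0)
                mix_rows.append(
                    {
                        "location_id": loc,
                        "method": m,
                        "share_of_use": agg.format_percent(float(share.mean())),
                    }
                )
        pd.DataFrame(mix_rows).to_csv(self.path("methodmix.csv"), index=False)

        # FP2020-style accounting over all modelled locations
        years_arr = [int(y) for y in years]
        if cfg.fp2020_baseline_year in years_arr and cfg.fp2020_end_year in years_arr:
            mcpr = data["mcpr"]  # (loc, year, draw)
            pop_ly = (
                population.groupby(["location_id", "year"])["population"].sum().unstack("year")
            )
            pop_arr = pop_ly.reindex(index=locs, columns=years_arr).to_numpy()
            schedule = None
            if cfg.fp2020_goal_table:
                schedule = pd.read_csv(cfg.fp2020_goal_table)
            account = agg.fp2020_account(
                mcpr,
                pop_arr,
                years_arr,
                locs,
                goal=cfg.fp2020_goal,
                goal_schedule=schedule,
                baseline_year=cfg.fp2020_baseline_year,
                end_year=cfg.fp2020_end_year,
            )
            s_add = summarize_draws(account.additional_users[None, :]).iloc[0]
            s_short = summarize_draws(account.shortfall[None, :]).iloc[0]
            out = account.rate_check.copy()
            out["additional_users_mean"] = s_add["mean"]
            out["additional_users_lower"] = s_add["lower"]
            out["additional_users_upper"] = s_add["upper"]
            out["shortfall_mean"] = s_short["mean"]
            out.to_csv(self.path("fp2020.csv"), index=False, float_format=_FLOAT_FMT)

    def stage_metareg(self) -> None:
        self._require("allwomen.npz", "metareg", "aggregate")
        cells = pd.read_csv(self.path("cells.csv"))
        allw = np.load(self.path("allwomen.npz"))
        covariates = pd.read_csv(self.path("covariates.csv"))
        last_year = cells["year"].max()
        mask = (cells["year"] == last_year).to_numpy()
        sdi = (
            covariates.set_index(["location_id", "year"])["sdi"]
            .reindex(pd.MultiIndex.from_frame(cells[["location_id", "year"]]))
            .to_numpy()
        )
        frames = []
        for name in ("mcpr", "demand_satisfied"):
            draws = allw[name][mask]
            s = summarize_draws(draws)
            pts = cells[mask].reset_index(drop=True).copy()
            pts["sdi"] = sdi[mask]
            pts["value"] = s["mean"].to_numpy()
            pts["se"] = np.maximum(
                (s["upper"].to_numpy() - s["lower"].to_numpy()) / (2 * 1.96), 1e-3
            )
            grid = np.linspace(0, 100, 101)
            curves = expected_curves(pts, grid, gamma=self.cfg.gamma)
            curves["indicator"] = name
            frames.append(curves)
        pd.concat(frames, ignore_index=True).to_csv(
            self.path("curves.csv"), index=False, float_format=_FLOAT_FMT
        )

    # -------------------------------------------------------------- #
    def _require(self, filename: str, stage: str, producer: str) -> None:
        if not self.path(filename).exists():
            raise RuntimeError(
                f"stage '{stage}' requires {filename}, produced by stage '{producer}'"
            )

    def run(self) -> dict:
        """Execute every enabled stage in canonical order; write manifest."""
        enabled = [s for s in STAGES if s in self.cfg.stages]
        for stage in enabled:
            logger.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        manifest = {
            "seed": self.cfg.seed,
            "stages": enabled,
            "files": {
                p.name: _sha256(p)
                for p in sorted(self.dir.iterdir())
                if p.is_file() and p.name != "manifest.json"
            },
        }
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run(config: RunConfig) -> dict:
    return Pipeline(config).run()
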