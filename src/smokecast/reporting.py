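"""Presentation products and end-to-end orchestration.

Two presentation products summarize the Bayesian predictions the way a
burn-scheduling duty officer would consume them: per-condition predictive
summaries (median, central intervals, percent of the predictive
distribution above the 15 and 25 ug m^-3 reporting thresholds) and
exceedance tile grids over a Cartesian product of predictor conditions.
``run_pipeline`` wires the whole chain together on synthetic inputs:
simulate -> fire areas -> model table -> split -> all-subsets selection ->
Bayesian refit -> reports, for both the mean and maximum responses, and
writes a manifest with seeds and content hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import SmoothTerm
from .bayes import BayesGammaGAM, BayesGAMResults, McmcSettings, PriorConfig
from .gam import ModelFormula
from .predictors import AggregationPolicy, assemble_table, speed_dir_to_uv
from .selection import CANDIDATE_UNITS, select_best, split_data
from .synthetic import EFFECT_PRESETS, SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioGrid",
    "RunConfig",
    "tile_grid",
    "predictive_summary",
    "run_pipeline",
    "default_scenario",
    "formula_to_dict",
    "formula_from_dict",
    "save_fit",
    "load_fit",
]

#: Scenario keys that denote a wind regime given as (speed m/s, direction deg).
WIND_UNITS = {"coastal_wind": ("u_coast_aft", "v_coast_aft"), "inland_wind": ("u_inland", "v_inland")}


@dataclass
class ScenarioGrid:
    """A tile-plot scenario: inner axes, panel axes, fixed values, and the
    exceedance threshold.

    Axis values for the wind units are (speed, direction-from) pairs and are
    converted to U/V components; every predictor of the fitted formula must
    be covered by exactly one of varied / panels / fixed.
    """

    varied: dict = field(default_factory=dict)
    panels: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    threshold: float = 25.0

    def __post_init__(self):
        if len(self.varied) > 2 or len(self.panels) > 2:
            raise ValueError("at most two varied and two panel axes")
        for k, v in {**self.varied, **self.panels}.items():
            if len(v) == 0:
                raise ValueError(f"axis {k!r} has no values")


def default_scenario(threshold: float = 25.0) -> ScenarioGrid:
    """Tile scenario mirroring the reference presentation: lag PM2.5 and
    ventilation index inside each panel, fire-area-west levels by coastal
    wind regime (sea breeze vs westerly) across panels, temperature 14 C,
    other fire areas zero, inland wind ~15 km/h westerly."""
    return ScenarioGrid(
        varied={
            "lag_pm": [5.0, 10.0, 15.0, 20.0],
            "ventilation_index": [250.0, 500.0, 1000.0, 2000.0],
        },
        panels={
            "fire_west": [100.0, 1500.0, 3000.0],
            "coastal_wind": [(2.78, 90.0), (2.78, 270.0)],
        },
        fixed={
            "temperature": 14.0,
            "fire_south": 0.0,
            "fire_north": 0.0,
            "inland_wind": (4.17, 270.0),
            "cloud": 0.5,
            "mslp_west": 1016.0,
            "mslp_tasman": 1013.0,
        },
        threshold=threshold,
    )


def _apply_value(row: dict, key: str, value) -> None:
    if key in WIND_UNITS:
        u, v = speed_dir_to_uv(*value)
        uvar, vvar = WIND_UNITS[key]
        row[uvar] = u
        row[vvar] = v
    else:
        row[key] = float(value)


def _scenario_rows(fit: BayesGAMResults, scenario: ScenarioGrid) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand the scenario into (axis-label frame, predictor frame)."""
    axes = list(scenario.panels.items()) + list(scenario.varied.items())
    names = [a[0] for a in axes]
    combos = list(itertools.product(*(a[1] for a in axes))) or [()]
    labels, rows = [], []
    for combo in combos:
        row: dict = {}
        for k, v in scenario.fixed.items():
            _apply_value(row, k, v)
        for k, v in zip(names, combo):
            _apply_value(row, k, v)
        labels.append({k: str(v) for k, v in zip(names, combo)})
        rows.append(row)
    pred = pd.DataFrame(rows)
    needed = {v for t in fit.model.formula.terms for v in t.variables}
    missing = needed - set(pred.columns)
    if missing:
        raise ValueError(f"scenario does not set predictor(s): {sorted(missing)}")
    return pd.DataFrame(labels), pred


def tile_grid(fit: BayesGAMResults, scenario: ScenarioGrid) -> pd.DataFrame:
    """Exceedance percentages over the scenario's Cartesian product.

    One row per cell: the panel/varied axis values, the percent of the
    posterior-predictive distribution above the scenario threshold, and an
    extrapolation flag for cells outside the training predictor ranges
    (flagged, never suppressed).
    """
    labels, pred = _scenario_rows(fit, scenario)
    ppd = fit.posterior_predict(pred)
    out = labels.copy()
    out["exceedance_pct"] = 100.0 * ppd.exceedance_prob(scenario.threshold)
    out["threshold"] = scenario.threshold
    out["extrapolated"] = fit.model.gam.design.extrapolates(pred)
    return out


def predictive_summary(
    fit: BayesGAMResults,
    newdata: pd.DataFrame,
    thresholds=(15.0, 25.0),
    include_draws: bool = False,
):
    """Per-row predictive median, central 0.5/0.8/0.95 intervals and percent
    of the predictive distribution above each threshold."""
    ppd = fit.posterior_predict(newdata)
    out = pd.DataFrame({"median": np.median(ppd.draws, axis=0)})
    for lev in (0.5, 0.8, 0.95):
        out[f"lo_{lev}"] = np.quantile(ppd.draws, 0.5 - lev / 2, axis=0)
        out[f"hi_{lev}"] = np.quantile(ppd.draws, 0.5 + lev / 2, axis=0)
    for thr in thresholds:
        out[f"pct_above_{thr:g}"] = 100.0 * ppd.exceedance_prob(thr)
    if include_draws:
        return out, ppd
    return out


# -- formula / fit (de)serialization ----------------------------------


def formula_to_dict(formula: ModelFormula) -> dict:
    return {
        "response": formula.response,
        "terms": [
            {"variables": list(t.variables), "basis": t.basis, "basis_dim": t.basis_dim}
            for t in formula.terms
        ],
    }


def formula_from_dict(d: dict) -> ModelFormula:
    return ModelFormula(
        d["response"],
        tuple(SmoothTerm(tuple(t["variables"]), t["basis"], t["basis_dim"]) for t in d["terms"]),
    )


def save_fit(fit: BayesGAMResults, train_table: pd.DataFrame, prefix: Path) -> Path:
    """Persist a Bayesian fit as text artifacts: the training table, the
    retained draws (one column per parameter) and a JSON bundle tying them
    together. Returns the bundle path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table_path = prefix.with_suffix(".train.csv")
    draws_path = prefix.with_suffix(".draws.csv")
    train_table.to_csv(table_path, index=False)
    flat = fit.draws.reshape(-1, fit.draws.shape[-1])
    dd = pd.DataFrame(flat, columns=fit.param_names)
    dd.insert(0, "chain", np.repeat(np.arange(fit.draws.shape[0]), fit.draws.shape[1]))
    dd.to_csv(draws_path, index=False, float_format="%.12g")
    bundle = {
        "formula": formula_to_dict(fit.model.formula),
        "settings": asdict(fit.settings),
        "priors": fit.model.priors.to_dict(),
        "train_table": table_path.name,
        "draws": draws_path.name,
        "convergence_passed": fit.convergence.passed,
    }
    bundle_path = prefix.with_suffix(".fit.json")
    bundle_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle_path


def load_fit(bundle_path) -> BayesGAMResults:
    """Rebuild a :class:`BayesGAMResults` from a saved bundle without
    re-sampling."""
    from .bayes import ConvergenceReport, ess as _ess, rhat as _rhat

    bundle_path = Path(bundle_path)
    bundle = json.loads(bundle_path.read_text())
    train = pd.read_csv(bundle_path.parent / bundle["train_table"])
    draws_df = pd.read_csv(bundle_path.parent / bundle["draws"])
    settings = McmcSettings(**bundle["settings"])
    model = BayesGammaGAM(train, formula_from_dict(bundle["formula"]), PriorConfig(**bundle["priors"]))
    gam_res = model.gam.fit(method="reml")
    chains = draws_df["chain"].to_numpy()
    mat = draws_df.drop(columns="chain").to_numpy()
    n_chains = int(chains.max()) + 1
    draws = mat.reshape(n_chains, -1, mat.shape[1])
    r, e = _rhat(draws), _ess(draws)
    finite = r[~np.isnan(r)]
    report = ConvergenceReport(
        rhat=pd.Series(r, index=model.param_names),
        ess=pd.Series(e, index=model.param_names),
        passed=bool(len(finite) and np.max(finite) < 1.01),
    )
    return BayesGAMResults(
        model=model, gam_results=gam_res, draws=draws, settings=settings, convergence=report
    )


# -- pipeline ----------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run settings (synthetic inputs).

    ``basis_dims`` are the 1-D/2-D spline sizes used in selection; the
    pipeline default is deliberately compact so a full 2048-model search
    per response stays desk-fast.
    """

    out_dir: str = "smokecast_run"
    n_days: int = 400
    seed: int = 1
    scenario_preset: str = "default"
    responses: tuple = ("mean_pm", "max_pm")
    train_fraction: float = 0.8
    split_method: str = "random"
    basis_dims: tuple = (6, 12)
    selection_strategy: str = "transfer"
    units: tuple = tuple(CANDIDATE_UNITS)
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(chains=4, iterations=1500, warmup=750, thin=3, seed=0))
    thresholds: tuple = (15.0, 25.0)
    policy: AggregationPolicy = field(default_factory=AggregationPolicy)

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be strictly between 0 and 1 (a test set is required)")
        if self.scenario_preset not in EFFECT_PRESETS:
            raise ValueError(f"unknown scenario preset {self.scenario_preset!r}")
        for r in self.responses:
            if r not in ("mean_pm", "max_pm"):
                raise ValueError(f"unknown response {r!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain on synthetic inputs and write all artifacts.

    Returns a dict of artifact paths, including ``manifest`` (JSON with
    seeds, versions and content hashes; reruns with the same config produce
    identical hashes).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("[%7.2fs] stage: %s", time.time() - t0, name)

    try:
        stage("simulate")
        sim_cfg = SimulationConfig(
            n_days=config.n_days, seed=config.seed,
            effects=dict(EFFECT_PRESETS[config.scenario_preset]),
        )
        ds = generate_dataset(sim_cfg)
        artifacts.update(ds.write_csvs(out / "inputs"))

        stage("fire-areas")
        fire_path = out / "fire_days.csv"
        ds.fire_days.to_csv(fire_path, index=False, float_format="%.10g")
        artifacts["fire_days"] = fire_path

        stage("assemble")
        table = assemble_table(ds.pm_hourly, ds.weather, ds.fire_days, config.policy)
        if len(table) < 30:
            raise RuntimeError(f"assembled table has too few rows ({len(table)}) to model")
        table_path = out / "model_table.csv"
        table.to_csv(table_path, index=False, float_format="%.10g")
        artifacts["model_table"] = table_path

        for response in config.responses:
            tag = "mean" if response == "mean_pm" else "max"
            stage(f"select[{tag}]")
            train, test = split_data(table, config.train_fraction, config.seed, config.split_method)
            sel = select_best(
                train, test, response, units=list(config.units),
                basis_dims=config.basis_dims, strategy=config.selection_strategy,
            )
            aic_path = out / f"aic_table_{tag}.csv"
            sel.table.to_csv(aic_path, index=False, float_format="%.10g")
            artifacts[f"aic_table_{tag}"] = aic_path
            sel_path = out / f"selection_{tag}.json"
            sel_path.write_text(json.dumps(
                {"best_formula": formula_to_dict(sel.best_formula), "metrics": sel.metrics},
                indent=2, sort_keys=True))
            artifacts[f"selection_{tag}"] = sel_path

            stage(f"bayes[{tag}]")
            mcmc = McmcSettings(
                chains=config.mcmc.chains, iterations=config.mcmc.iterations,
                warmup=config.mcmc.warmup, thin=config.mcmc.thin, seed=config.seed,
            )
            fit = BayesGammaGAM(train, sel.best_formula).fit(mcmc)
            artifacts[f"fit_{tag}"] = save_fit(fit, train, out / f"bayes_{tag}")
            conv_path = out / f"convergence_{tag}.json"
            conv_path.write_text(json.dumps(
                {"passed": fit.convergence.passed,
                 "max_rhat": float(np.nanmax(fit.convergence.rhat.to_numpy())),
                 "min_ess": float(np.nanmin(fit.convergence.ess.to_numpy())),
                 "accept_rates": [float(a) for a in fit.accept_rates]},
                indent=2, sort_keys=True))
            artifacts[f"convergence_{tag}"] = conv_path

            stage(f"reports[{tag}]")
            summ = predictive_summary(fit, test, config.thresholds)
            summ.insert(0, "fire_day", test["fire_day"].astype(str).to_numpy())
            summ.insert(1, "observed", test[response].to_numpy())
            summ_path = out / f"predictive_summary_{tag}.csv"
            summ.to_csv(summ_path, index=False, float_format="%.10g")
            artifacts[f"predictive_summary_{tag}"] = summ_path

            tiles = tile_grid(fit, default_scenario(max(config.thresholds)))
            tile_path = out / f"tiles_{tag}.csv"
            tiles.to_csv(tile_path, index=False, float_format="%.10g")
            artifacts[f"tiles_{tag}"] = tile_path
    except Exception as err:  # label the failing stage, keep partial artifacts
        raise RuntimeError(f"pipeline failed ({err})") from err

    manifest = {
        "package": "smokecast",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "artifacts": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in artifacts.items()},
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = man_path
    logger.info("[%7.2fs] done", time.time() - t0)
    return artifacts
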