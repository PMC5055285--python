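"""End-to-end experiments: generate or load data, run models, score, report.

``run_experiment`` orchestrates the full analysis for a configured set of
sites: synthesize (or read) forcing and logger records, hourly-average them,
build the emersion mask from tide + wave run-up, run each configured
body-temperature model, pair daily maxima per logger, and emit per-(site,
model, logger) skill reports, an inter-logger baseline and cross-site
Average/SD summary tables, all as CSV with NaN rendered "NA".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import daily_max_pairs, emersion_mask, hourly_average, wave_runup
from .models import (
    HeatBudgetParams,
    fit_site_regression,
    predict_elvin_gonor,
    predict_site_regression,
    steady_state_temperature,
)
from .series import (
    BodyTemperatureSeries,
    read_body_csv,
    read_environment_csv,
    write_body_csv,
    write_environment_csv,
)
from .synthetic import GeneratorConfig, SiteConfig, generate_environment, generate_truth_loggers
from .verification import CategoryScheme, interlogger_baseline, skill_report

ALL_MODELS = ("air_proxy", "elvin_gonor", "site_regression", "heat_budget")

SCALAR_METRICS = ("bias", "mae", "rmse", "heidke", "peirce", "gerrity")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    sites: tuple[SiteConfig, ...]
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: tuple[str, ...] = ALL_MODELS
    scheme: CategoryScheme = field(default_factory=CategoryScheme)
    heat_budget_params: HeatBudgetParams = field(default_factory=HeatBudgetParams)
    runup_coefficient: float = 1.0
    in_sample_regression: bool = False
    #: Optional site_id -> {"environment": path, "loggers": [paths]} mapping;
    #: when present those CSVs are read instead of generating synthetic data.
    input_paths: dict | None = None

    def __post_init__(self):
        if len(self.sites) < 1:
            raise ValueError("need at least one site")
        if len(self.models) < 1:
            raise ValueError("need at least one model")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, generator=replace(self.generator, seed=int(seed)))

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        sites = tuple(SiteConfig(**s) for s in raw["sites"])
        gen_raw = dict(raw.get("generator", {}))
        if "tidal_constituents" in gen_raw:
            gen_raw["tidal_constituents"] = tuple(tuple(c) for c in gen_raw["tidal_constituents"])
        if "heat_budget_params" in gen_raw:
            gen_raw["heat_budget_params"] = HeatBudgetParams(**gen_raw["heat_budget_params"])
        kwargs = dict(
            sites=sites,
            generator=GeneratorConfig(**gen_raw),
            models=tuple(raw.get("models", ALL_MODELS)),
            runup_coefficient=float(raw.get("runup_coefficient", 1.0)),
            in_sample_regression=bool(raw.get("in_sample_regression", False)),
            input_paths=raw.get("input_paths"),
        )
        if "scheme" in raw:
            kwargs["scheme"] = CategoryScheme(
                labels=tuple(raw["scheme"]["labels"]), bounds=tuple(raw["scheme"]["bounds"])
            )
        if "heat_budget_params" in raw:
            kwargs["heat_budget_params"] = HeatBudgetParams(**raw["heat_budget_params"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class ExperimentResult:
    """All outputs of one experiment run."""

    reports: pd.DataFrame  # one row per (site, model, microsite)
    baseline: pd.DataFrame  # inter-logger rows per site
    summary: pd.DataFrame  # metric x model with per-site columns, Average, SD
    tables: dict  # (site, model, microsite) -> ContingencyTable
    provenance: dict
    failures: list
    log: list


def summarize_across_sites(per_site_values) -> tuple[float, float]:
    """Unweighted mean and sample (n-1) standard deviation of per-site values."""
    vals = np.asarray(list(per_site_values), dtype=float)
    if len(vals) < 1:
        raise ValueError("mean requires at least one value")
    mean = float(vals.mean())
    if len(vals) < 2:
        raise ValueError("sample SD requires at least two values")
    sd = float(vals.std(ddof=1))
    return mean, sd


def _site_inputs(cfg: ExperimentConfig, site: SiteConfig, log: list):
    """Generate or load the forcing record and observed loggers for one site."""
    if cfg.input_paths and site.site_id in cfg.input_paths:
        paths = cfg.input_paths[site.site_id]
        env = read_environment_csv(paths["environment"])
        loggers = [read_body_csv(p) for p in paths["loggers"]]
        log.append(f"{site.site_id}: loaded {len(env)} records, {len(loggers)} loggers from CSV")
    else:
        env = generate_environment(site, cfg.generator)
        loggers = generate_truth_loggers(env, site, cfg.generator)
        log.append(f"{site.site_id}: generated {len(env)} records, {len(loggers)} loggers")
    return env, loggers


def _hourly_site(cfg: ExperimentConfig, site: SiteConfig, env: pd.DataFrame, loggers):
    henv = pd.DataFrame({c: hourly_average(env[c]) for c in env.columns}).dropna()
    runup = wave_runup(henv["sig_wave_height"], site.shore_slope, cfg.runup_coefficient)
    mask = emersion_mask(henv["tide_height"], runup, site.logger_elevation)
    hloggers = {
        b.microsite_id: hourly_average(b.temps).reindex(henv.index) for b in loggers
    }
    return henv, mask, hloggers


def _forecasts(cfg: ExperimentConfig, site: SiteConfig, henv, mask, hloggers, log: list):
    """Hourly forecast series per model, plus the per-model evaluation window start."""
    out: dict[str, pd.Series] = {}
    eval_start: dict[str, pd.Timestamp | None] = {}
    for model in cfg.models:
        if model == "air_proxy":
            out[model] = henv["air_temp"].copy()
            eval_start[model] = None
        elif model == "elvin_gonor":
            out[model] = predict_elvin_gonor(henv["air_temp"], henv["solar"])
            eval_start[model] = None
        elif model == "heat_budget":
            out[model] = pd.Series(
                steady_state_temperature(
                    henv["air_temp"].to_numpy(),
                    henv["solar"].to_numpy(),
                    henv["wind"].to_numpy(),
                    cfg.heat_budget_params,
                ),
                index=henv.index,
            )
            eval_start[model] = None
        elif model == "site_regression":
            split = henv.index[len(henv) // 2]
            train_mask = mask & (henv.index < split) if not cfg.in_sample_regression else mask
            observed = pd.concat(hloggers.values(), axis=0)
            air = pd.concat([henv["air_temp"]] * len(hloggers), axis=0)
            sol = pd.concat([henv["solar"]] * len(hloggers), axis=0)
            msk = pd.concat([train_mask] * len(hloggers), axis=0)
            coeffs = fit_site_regression(
                air.reset_index(drop=True),
                sol.reset_index(drop=True),
                observed.reset_index(drop=True),
                msk.reset_index(drop=True),
            )
            log.append(
                f"{site.site_id}: site_regression fit n={coeffs.n} "
                f"(intercept={coeffs.intercept:.3f}, air={coeffs.air_coeff:.3f}, "
                f"solar={coeffs.solar_coeff:.5f})"
            )
            out[model] = predict_site_regression(coeffs, henv["air_temp"], henv["solar"])
            eval_start[model] = None if cfg.in_sample_regression else split
    return out, eval_start


def run_experiment(cfg: ExperimentConfig, output_dir=None) -> ExperimentResult:
    """Run the full experiment; deterministic for a fixed config and seed.

    Any per-(site, model) failure is recorded and the run continues; the
    result is written to ``output_dir`` (skill reports, summary, baseline,
    contingency tables, run log, provenance) when one is given.
    """
    log: list = []
    failures: list = []
    rows = []
    baseline_frames = []
    tables: dict = {}

    for site in cfg.sites:
        try:
            env, loggers = _site_inputs(cfg, site, log)
            henv, mask, hloggers = _hourly_site(cfg, site, env, loggers)
            log.append(
                f"{site.site_id}: {len(henv)} hours, {int(mask.sum())} emersed hours"
            )
            forecasts, eval_start = _forecasts(cfg, site, henv, mask, hloggers, log)
        except Exception as exc:  # noqa: BLE001 - per-site isolation
            failures.append({"site": site.site_id, "model": "*", "error": str(exc)})
            continue
        for model in cfg.models:
            if model not in forecasts:
                failures.append({"site": site.site_id, "model": model, "error": "no forecast"})
                continue
            fseries = forecasts[model]
            for mid, lseries in hloggers.items():
                try:
                    f, o, m = fseries, lseries, mask
                    start = eval_start.get(model)
                    if start is not None:
                        keep = fseries.index >= start
                        f, o, m = fseries[keep], lseries[keep], mask[keep]
                    pairs = daily_max_pairs(f, o, m, site.utc_offset)
                    report = skill_report(pairs, cfg.scheme)
                except Exception as exc:  # noqa: BLE001
                    failures.append({"site": site.site_id, "model": model, "error": str(exc)})
                    continue
                row = {"site": site.site_id, "model": model, "microsite": mid}
                row.update(report.to_row(cfg.scheme))
                rows.append(row)
                tables[(site.site_id, model, mid)] = report.table
                log.append(
                    f"{site.site_id}/{model}/{mid}: {report.n_days} paired days"
                )
        if len(hloggers) >= 2:
            base = interlogger_baseline(hloggers, mask, cfg.scheme, site.utc_offset)
            base.insert(0, "site", site.site_id)
            baseline_frames.append(base)

    reports = pd.DataFrame(rows)
    baseline = (
        pd.concat(baseline_frames, ignore_index=True) if baseline_frames else pd.DataFrame()
    )
    summary = _cross_site_summary(cfg, reports, baseline)
    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": int(cfg.generator.seed),
        "version": __version__,
    }
    result = ExperimentResult(
        reports=reports,
        baseline=baseline,
        summary=summary,
        tables=tables,
        provenance=provenance,
        failures=failures,
        log=log,
    )
    if output_dir is not None:
        write_result(result, cfg, output_dir)
    if len(reports) == 0 and failures:
        raise RuntimeError(f"all (site, model) runs failed: {failures}")
    return result


def _cross_site_summary(cfg: ExperimentConfig, reports: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Table-style summary: per-site logger-mean values, cross-site Average and SD."""
    if len(reports) == 0:
        return pd.DataFrame()
    site_ids = [s.site_id for s in cfg.sites]
    rows = []
    groups = [(model, reports[reports["model"] == model]) for model in cfg.models]
    if len(baseline):
        groups.append(("among_loggers", baseline.assign(model="among_loggers")))
    for metric in SCALAR_METRICS:
        for model, sub in groups:
            if len(sub) == 0 or metric not in sub.columns:
                continue
            per_site = sub.groupby("site")[metric].mean()
            row = {"metric": metric, "model": model}
            for sid in site_ids:
                row[sid] = per_site.get(sid, float("nan"))
            vals = [v for v in (per_site.get(s) for s in site_ids) if v is not None and np.isfinite(v)]
            if len(vals) >= 1:
                row["average"] = float(np.mean(vals))
            if len(vals) >= 2:
                row["sd"] = float(np.std(vals, ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)


def write_result(result: ExperimentResult, cfg: ExperimentConfig, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.reports.to_csv(out / "skill_reports.csv", index=False, na_rep="NA")
    result.summary.to_csv(out / "summary.csv", index=False, na_rep="NA")
    result.baseline.to_csv(out / "interlogger_baseline.csv", index=False, na_rep="NA")
    tdir = out / "contingency_tables"
    tdir.mkdir(exist_ok=True)
    for (site, model, mid), table in result.tables.items():
        table.to_dataframe(cfg.scheme).to_csv(tdir / f"{site}_{model}_{mid}.csv")
    (out / "run_log.txt").write_text("\n".join(result.log) + "\n")
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2) + "\n")
    if result.failures:
        (out / "failures.json").write_text(json.dumps(result.failures, indent=2) + "\n")


def write_synthetic_inputs(cfg: ExperimentConfig, output_dir) -> list:
    """Generate and persist the synthetic CSVs for every configured site."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for site in cfg.sites:
        env = generate_environment(site, cfg.generator)
        env_path = out / f"{site.site_id}_environment.csv"
        write_environment_csv(env, env_path)
        written.append(env_path)
        for body in generate_truth_loggers(env, site, cfg.generator):
            p = out / f"{site.site_id}_{body.microsite_id}.csv"
            write_body_csv(body, p)
            written.append(p)
    return written
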