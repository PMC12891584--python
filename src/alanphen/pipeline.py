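"""End-to-end experiment orchestration.

A single YAML config drives the full workflow: simulate synthetic sites ->
MAD-filter the observed senescence dates -> calibrate each configured model
(base and ALAN variants) -> evaluate and compare -> preseason sensitivity
statistics -> century-scale projection.  Stages communicate only through the
CSV tables they write, so deleting downstream outputs and rerunning
reproduces them bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alan as alan_mod
from .calibration import compare_models, evaluate_predictions, pso_calibrate, run_projection
from .models import ModelParams, SenescenceModelSpec, param_names
from .stats import optimal_preseason, ridge_sensitivities
from .synthetic import (
    SyntheticConfig,
    generate_daily_temperature,
    generate_sites,
    inject_outliers,
    read_site_bundle,
    simulate_observed_dfs,
    write_site_bundle,
)

__all__ = ["ExperimentConfig", "run_experiment", "STAGES", "stage_seed"]

STAGES = ("simulate", "filter", "fit", "evaluate", "sensitivity", "project")

DEFAULT_CONFIG = {
    "synthetic": {},
    "truth": {
        "family": "CDD",
        "alan_enabled": True,
        "params": {"t_th": 22.0, "cdd_th": 120.0, "k": -3.0},
    },
    "models": [
        {"family": "CDD", "alan_enabled": False},
        {"family": "CDD", "alan_enabled": True},
    ],
    "pso": {"particles": 20, "iterations": 40},
    "sensitivity": {"penalty": 1.0, "alpha": 0.05, "max_months": 6},
    "projection": {"end_year": 2100, "gdp_growth": 0.05},
    "outlier": {"fraction": 0.0, "magnitude": 40.0},
    "output_dir": "experiment_out",
    "master_seed": 0,
}


@dataclasses.dataclass
class ExperimentConfig:
    """Validated experiment settings; round-trips losslessly through YAML."""

    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        merged = _deep_merge(DEFAULT_CONFIG, d or {})
        # validate eagerly so failures happen before any stage runs
        SyntheticConfig(**merged["synthetic"])
        cls._truth_spec_params(merged)
        for m in merged["models"]:
            SenescenceModelSpec(m["family"], m.get("alan_enabled", False))
        return cls(raw=merged)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)

    @staticmethod
    def _truth_spec_params(raw: dict):
        t = raw["truth"]
        spec = SenescenceModelSpec(t["family"], t.get("alan_enabled", False))
        return spec, t["params"]

    @property
    def synthetic(self) -> SyntheticConfig:
        return SyntheticConfig(**self.raw["synthetic"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    @property
    def master_seed(self) -> int:
        return int(self.raw["master_seed"])

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def model_specs(self) -> list[SenescenceModelSpec]:
        return [
            SenescenceModelSpec(m["family"], m.get("alan_enabled", False))
            for m in self.raw["models"]
        ]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding stages never perturbs earlier streams."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: ExperimentConfig) -> list[str]:
    syn = cfg.synthetic
    spec, pvalues = cfg._truth_spec_params(cfg.raw)
    params = ModelParams(spec, pvalues)
    seed = stage_seed(cfg.master_seed, "simulate")
    sites = []
    for site in generate_sites(syn):
        site = simulate_observed_dfs(site, spec, params, syn.dfs_noise_sd,
                                     seed=stage_seed(seed, f"dfs:{site.site_id}"))
        frac = cfg.raw["outlier"]["fraction"]
        if frac > 0:
            corrupted, _ = inject_outliers(
                site.dfs_observed, frac, cfg.raw["outlier"]["magnitude"],
                seed=stage_seed(seed, f"outlier:{site.site_id}"),
            )
            site.dfs_observed = corrupted
        sites.append(site)
    data_dir = cfg.output_dir / "data"
    write_site_bundle(sites, data_dir)
    return [str(data_dir / t) for t in
            ("daily_temperature.csv", "annual_series.csv", "monthly_climate.csv")]


def stage_filter(cfg: ExperimentConfig) -> list[str]:
    data_dir = cfg.output_dir / "data"
    annual = pd.read_csv(data_dir / "annual_series.csv")
    flagged = np.zeros(len(annual), dtype=bool)
    for _, grp in annual.groupby("site_id"):
        vals = grp["dfs_observed_doy"].to_numpy()
        ok = np.isfinite(vals)
        if ok.sum() >= 3:
            _, mask = alan_mod.mad_filter(vals[ok])
            idx = grp.index[ok][mask]
            flagged[annual.index.get_indexer(idx)] = True
    annual.loc[flagged, "dfs_observed_doy"] = np.nan
    annual["mad_flagged"] = flagged
    out = data_dir / "annual_series_filtered.csv"
    annual.to_csv(out, index=False, float_format="%.10g")
    return [str(out)]


def _load_sites(cfg: ExperimentConfig):
    data_dir = cfg.output_dir / "data"
    sites = read_site_bundle(data_dir)
    filtered = data_dir / "annual_series_filtered.csv"
    if filtered.exists():
        ann = pd.read_csv(filtered)
        for site in sites:
            grp = ann[ann["site_id"] == site.site_id].sort_values("year")
            site.dfs_observed = grp["dfs_observed_doy"].to_numpy(dtype=float)
    return sites


def stage_fit(cfg: ExperimentConfig) -> list[str]:
    sites = _load_sites(cfg)
    fit_dir = cfg.output_dir / "fits"
    fit_dir.mkdir(parents=True, exist_ok=True)
    seed0 = stage_seed(cfg.master_seed, "fit")
    written = []
    for spec in cfg.model_specs():
        param_rows, pred_rows = [], []
        for site in sites:
            result = pso_calibrate(
                spec, site, pso_config=cfg.raw["pso"],
                seed=stage_seed(seed0, f"{spec.name}:{site.site_id}"),
            )
            for nm in param_names(spec):
                param_rows.append({"site_id": site.site_id, "param": nm,
                                   "value": result.best_params[nm]})
            param_rows.append({"site_id": site.site_id, "param": "_objective",
                               "value": result.objective})
            for yr, pred in zip(result.years, result.predicted):
                pred_rows.append({"site_id": site.site_id, "year": int(yr),
                                  "predicted_doy": pred})
        pf = fit_dir / f"params_{spec.name}.csv"
        qf = fit_dir / f"predictions_{spec.name}.csv"
        pd.DataFrame(param_rows).to_csv(pf, index=False, float_format="%.10g")
        pd.DataFrame(pred_rows).to_csv(qf, index=False, float_format="%.10g")
        written += [str(pf), str(qf)]
    return written


def stage_evaluate(cfg: ExperimentConfig) -> list[str]:
    data_dir = cfg.output_dir / "data"
    fit_dir = cfg.output_dir / "fits"
    eval_dir = cfg.output_dir / "eval"
    eval_dir.mkdir(parents=True, exist_ok=True)
    ann_path = data_dir / "annual_series_filtered.csv"
    if not ann_path.exists():
        ann_path = data_dir / "annual_series.csv"
    annual = pd.read_csv(ann_path)

    metric_rows = []
    metrics_by_model = {}
    for spec in cfg.model_specs():
        preds = pd.read_csv(fit_dir / f"predictions_{spec.name}.csv")
        per_site = []
        for site_id, grp in preds.groupby("site_id"):
            obs = annual[annual["site_id"] == site_id].set_index("year")["dfs_observed_doy"]
            merged = grp.set_index("year").join(obs)
            m = evaluate_predictions(
                merged["predicted_doy"], merged["dfs_observed_doy"], spec.param_count
            )
            per_site.append(m)
            metric_rows.append({
                "model": spec.name, "site_id": site_id, "r": m.r, "p_value": m.p_value,
                "rmse": m.rmse, "aic": m.aic, "n": m.n, "k_params": m.k_params,
            })
        metrics_by_model[spec.name] = per_site
    mf = eval_dir / "metrics.csv"
    cf = eval_dir / "comparison.csv"
    pd.DataFrame(metric_rows).to_csv(mf, index=False, float_format="%.10g")
    compare_models(metrics_by_model, alpha=cfg.raw["sensitivity"]["alpha"]).to_csv(
        cf, float_format="%.10g"
    )
    return [str(mf), str(cf)]


def _monthly_tables(site):
    """Driver tables (n_years, 12): ALAN (night-length disaggregated), monthly
    mean temperature, precipitation, shortwave."""
    from ._calendar import DAYS_PER_YEAR, month_index

    months = month_index(np.arange(1, DAYS_PER_YEAR + 1))
    temp_monthly = np.vstack([
        np.array([site.daily_temp[int(y)][months == m].mean() for m in range(1, 13)])
        for y in site.years
    ])
    weights = alan_mod.disaggregate_alan_monthly(1.0, site.latitude)
    alan_monthly = np.outer(site.alan.alan_year, weights)
    return {
        "alan": alan_monthly,
        "temperature": temp_monthly,
        "precipitation": site.monthly_precip,
        "shortwave": site.monthly_shortwave,
    }


def stage_sensitivity(cfg: ExperimentConfig) -> list[str]:
    sites = _load_sites(cfg)
    sens_dir = cfg.output_dir / "sensitivity"
    sens_dir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.raw["sensitivity"]
    rows = []
    for site in sites:
        if site.dfs_observed is None or np.isfinite(site.dfs_observed).sum() < 8:
            continue
        tables = _monthly_tables(site)
        window_anoms = {}
        estimates = {}
        for driver, table in tables.items():
            others = {k: v for k, v in tables.items() if k != driver}
            try:
                est = optimal_preseason(
                    site.dfs_observed, site.years, table, driver_name=driver,
                    other_drivers=others, max_months=scfg["max_months"],
                )
            except ValueError:
                continue
            estimates[driver] = est
        if not estimates:
            continue
        # ridge sensitivities on each driver's optimal window
        from .stats import _window_mean, detrend_normalize
        from ._calendar import month_of_doy

        ok = np.isfinite(site.dfs_observed)
        anchor = month_of_doy(int(round(float(site.dfs_observed[ok].mean()))))
        dfs_anom = detrend_normalize(site.dfs_observed[ok])
        cols = []
        for driver, est in estimates.items():
            cols.append(detrend_normalize(_window_mean(
                tables[driver], site.years[ok], site.years, anchor, est.preseason_length
            )))
        betas = ridge_sensitivities(dfs_anom, np.column_stack(cols), penalty=scfg["penalty"])
        for (driver, est), beta in zip(estimates.items(), betas):
            rows.append({
                "site_id": site.site_id, "driver": driver,
                "preseason_length": est.preseason_length, "partial_r": est.partial_r,
                "p_value": est.p_value, "ridge_coeff": float(beta),
            })
    est_df = pd.DataFrame(rows)
    ef = sens_dir / "estimates.csv"
    est_df.to_csv(ef, index=False, float_format="%.10g")

    alpha = scfg["alpha"]
    summary_rows = []
    for driver, grp in est_df.groupby("driver"):
        sig = grp["p_value"] < alpha
        summary_rows.append({
            "driver": driver,
            "n_sites": len(grp),
            "share_positive_sig": float(((grp["partial_r"] > 0) & sig).mean()),
            "share_negative_sig": float(((grp["partial_r"] < 0) & sig).mean()),
            "share_nonsignificant": float((~sig).mean()),
        })
    sf = sens_dir / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(sf, index=False, float_format="%.10g")
    return [str(ef), str(sf)]


def stage_project(cfg: ExperimentConfig) -> list[str]:
    sites = _load_sites(cfg)
    fit_dir = cfg.output_dir / "fits"
    proj_dir = cfg.output_dir / "projection"
    proj_dir.mkdir(parents=True, exist_ok=True)
    pcfg = cfg.raw["projection"]
    syn = cfg.synthetic
    end_year = int(pcfg["end_year"])
    future_years = np.arange(syn.year_start, end_year + 1)
    seed0 = stage_seed(cfg.master_seed, "project")

    traj_rows, trend_rows = [], []
    for spec in cfg.model_specs():
        pdf = pd.read_csv(fit_dir / f"params_{spec.name}.csv")
        for site in sites:
            sp = pdf[(pdf["site_id"] == site.site_id) & (pdf["param"] != "_objective")]
            params = ModelParams(spec, dict(zip(sp["param"], sp["value"])))

            daily = generate_daily_temperature(
                site.latitude, future_years, syn,
                seed=[stage_seed(seed0, f"temp:{site.site_id}"), 0],
            )
            scenario = {"daily_temp": daily, "latitude": site.latitude}
            if spec.alan_enabled:
                t = np.arange(future_years.size, dtype=float)
                gdp_path = float(site.gdp[0]) * np.exp(pcfg["gdp_growth"] * t)
                # single-site fit: ALAN_mean is constant here, so fold the
                # a*ALAN_mean term into the intercept (a = 0)
                b, c = np.polyfit(np.log(site.gdp), site.alan.alan_year, 1)
                coefs = {"a": 0.0, "b": float(b), "c": float(c)}
                future_alan = alan_mod.project_future_alan(coefs, site.alan.alan_mean, gdp_path)
                scenario["alan"] = alan_mod.AnnualAlanSeries(future_years, future_alan)
            out = run_projection(spec, params, scenario)
            for yr, d in zip(out["years"], out["dfs"]):
                traj_rows.append({"model": spec.name, "site_id": site.site_id,
                                  "year": int(yr), "dfs_doy": d})
            trend_rows.append({"model": spec.name, "site_id": site.site_id,
                               "slope_days_per_year": out["slope"], "mk_p": out["p"]})
    tf = proj_dir / "trajectories.csv"
    rf = proj_dir / "trends.csv"
    pd.DataFrame(traj_rows).to_csv(tf, index=False, float_format="%.10g")
    pd.DataFrame(trend_rows).to_csv(rf, index=False, float_format="%.10g")
    return [str(tf), str(rf)]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "sensitivity": stage_sensitivity,
    "project": stage_project,
}


def run_experiment(config: ExperimentConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; returns the output manifest.

    Any stage failure halts the run; the manifest written so far is saved
    with the failing stage recorded.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "master_seed": config.master_seed,
                "stages": {}}
    manifest_path = config.output_dir / "manifest.json"
    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}")
            manifest["stages"][stage] = _STAGE_FUNCS[stage](config)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
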