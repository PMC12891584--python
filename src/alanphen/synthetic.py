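"""Seeded synthetic site datasets with known ground truth.

Emulates the statistical structure the downstream analysis assumes — a
seasonal temperature cycle with AR(1) noise and a warming trend, monotonically
growing noisy nighttime radiance, seasonal monthly climate, and senescence
dates generated by a known process model plus observation noise — so every
stage is testable without external data.

Seeding is counter-based: one master seed plus (site index, stream id) feeds
``numpy.random.default_rng`` so each site's streams are independent of how
many sites exist or the order they are generated in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._calendar import DAYS_PER_YEAR
from .alan import AnnualAlanSeries
from .models import (
    ModelParams,
    SenescenceModelSpec,
    lud_anomaly,
    predict_dfs_series,
    spring_summer_mean_temp,
)

__all__ = [
    "SyntheticConfig",
    "SiteDataset",
    "generate_daily_temperature",
    "generate_site_dataset",
    "generate_sites",
    "simulate_observed_dfs",
    "inject_outliers",
    "write_site_bundle",
    "read_site_bundle",
]

# stream ids for the counter-based per-site substreams
_STREAM_TEMP, _STREAM_ALAN, _STREAM_CLIMATE, _STREAM_LUD, _STREAM_GDP, _STREAM_LAT = range(6)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic-site generator; validated on construction."""

    n_sites: int = 5
    year_start: int = 2001
    year_end: int = 2022
    latitude_range: tuple = (25.0, 65.0)
    temp_mean_annual: float = 10.0
    temp_seasonal_amplitude: float = 12.0
    temp_ar1_coeff: float = 0.6
    temp_noise_sd: float = 2.0
    warming_trend: float = 0.03
    alan_start: float = 2.0
    alan_growth: float = 0.3
    alan_noise_sd: float = 0.15
    dfs_noise_sd: float = 4.0
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        lo, hi = self.latitude_range
        if not (-90 <= lo <= hi <= 90):
            raise ValueError("latitude_range must be ordered and within [-90, 90]")
        if not 0 <= self.temp_ar1_coeff < 1:
            raise ValueError("temp_ar1_coeff must lie in [0, 1)")
        for name in ("temp_seasonal_amplitude", "temp_noise_sd", "alan_start",
                     "alan_growth", "alan_noise_sd", "dfs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.outlier_fraction <= 0.3:
            raise ValueError("outlier_fraction must lie in [0, 0.3]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass
class SiteDataset:
    """One site's multi-year forcing and phenology series."""

    site_id: int
    latitude: float
    years: np.ndarray
    daily_temp: dict  # year -> (365,) ndarray, degC
    alan: AnnualAlanSeries
    monthly_precip: np.ndarray  # (n_years, 12), mm
    monthly_shortwave: np.ndarray  # (n_years, 12), W m-2
    lud: np.ndarray  # (n_years,), DOY
    gdp: np.ndarray  # (n_years,)
    dfs_observed: np.ndarray | None = None  # (n_years,), DOY with NaN = missing
    truth: dict = field(default_factory=dict)  # provenance of simulated DFS

    @property
    def n_years(self) -> int:
        return self.years.size

    def lud_anomalies(self) -> dict:
        anoms = lud_anomaly(self.lud)
        return dict(zip(self.years.tolist(), anoms))

    def tss_by_year(self, months) -> dict:
        return {
            int(y): spring_summer_mean_temp(self.daily_temp[int(y)], months)
            for y in self.years
        }


def _site_rng(seed: int, site_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, site_index, stream])


def generate_daily_temperature(latitude, years, config: SyntheticConfig, seed=None):
    """Daily mean temperature per year: sinusoid + warming trend + AR(1) noise.

    The seasonal cycle peaks near DOY 200; the annual-mean temperature is
    lowered by 0.6 degC per degree of latitude above 45 (a crude lapse so
    sites differ); the warming trend adds ``warming_trend * year_index``
    uniformly within each year.  AR(1) noise is continuous across year
    boundaries with stationary standard deviation ``temp_noise_sd``.

    Returns dict year -> 365-value ndarray.
    """
    years = [int(y) for y in years]
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    doy = np.arange(1, DAYS_PER_YEAR + 1)
    site_mean = config.temp_mean_annual - 0.6 * (latitude - 45.0)
    cycle = site_mean + config.temp_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 200.0) / DAYS_PER_YEAR
    )

    n_days = len(years) * DAYS_PER_YEAR
    noise = np.zeros(n_days)
    if config.temp_noise_sd > 0:
        rho = config.temp_ar1_coeff
        innov_sd = config.temp_noise_sd * np.sqrt(1.0 - rho**2)
        eps = rng.normal(0.0, innov_sd, size=n_days)
        noise[0] = rng.normal(0.0, config.temp_noise_sd)
        for t in range(1, n_days):
            noise[t] = rho * noise[t - 1] + eps[t]

    out = {}
    for i, year in enumerate(years):
        chunk = noise[i * DAYS_PER_YEAR : (i + 1) * DAYS_PER_YEAR]
        out[year] = cycle + config.warming_trend * i + chunk
    return out


def generate_site_dataset(config: SyntheticConfig, site_index: int) -> SiteDataset:
    """Build one complete site (DFS left unset; see :func:`simulate_observed_dfs`)."""
    if not 0 <= site_index < config.n_sites:
        raise ValueError(f"site_index {site_index} out of range for n_sites={config.n_sites}")
    years = config.years
    n = years.size
    t = np.arange(n, dtype=float)

    lo, hi = config.latitude_range
    latitude = float(_site_rng(config.seed, site_index, _STREAM_LAT).uniform(lo, hi))

    daily_temp = generate_daily_temperature(
        latitude, years, config, seed=[config.seed, site_index, _STREAM_TEMP]
    )

    rng_alan = _site_rng(config.seed, site_index, _STREAM_ALAN)
    alan_vals = config.alan_start + config.alan_growth * t
    if config.alan_noise_sd > 0:
        alan_vals = alan_vals + rng_alan.normal(0.0, config.alan_noise_sd, size=n)
    alan_vals = np.maximum(alan_vals, 0.0)

    rng_clim = _site_rng(config.seed, site_index, _STREAM_CLIMATE)
    month = np.arange(1, 13, dtype=float)
    precip_cycle = 60.0 * (1.0 + 0.5 * np.sin(2.0 * np.pi * (month - 3.0) / 12.0))
    sw_cycle = 180.0 + 90.0 * np.cos(2.0 * np.pi * (month - 6.5) / 12.0)
    precip = np.maximum(precip_cycle + rng_clim.normal(0.0, 10.0, size=(n, 12)), 0.0)
    shortwave = np.maximum(sw_cycle + rng_clim.normal(0.0, 15.0, size=(n, 12)), 0.0)

    rng_lud = _site_rng(config.seed, site_index, _STREAM_LUD)
    lud = np.round(rng_lud.normal(110.0, 5.0, size=n))

    rng_gdp = _site_rng(config.seed, site_index, _STREAM_GDP)
    gdp = 1000.0 * np.exp(0.05 * t) * np.exp(rng_gdp.normal(0.0, 0.05, size=n))

    return SiteDataset(
        site_id=site_index,
        latitude=latitude,
        years=years,
        daily_temp=daily_temp,
        alan=AnnualAlanSeries(years, alan_vals),
        monthly_precip=precip,
        monthly_shortwave=shortwave,
        lud=lud,
        gdp=gdp,
    )


def generate_sites(config: SyntheticConfig) -> list[SiteDataset]:
    return [generate_site_dataset(config, i) for i in range(config.n_sites)]


def simulate_observed_dfs(
    site: SiteDataset,
    model: SenescenceModelSpec,
    true_params: ModelParams,
    noise_sd: float,
    seed: int,
) -> SiteDataset:
    """Fill the observed-DFS field: model prediction + rounded Gaussian noise.

    Years where the model never crosses its threshold stay missing (NaN).
    Observation noise is assumed iid Gaussian and rounded to whole days to
    mimic in-situ records; no distributional information is available for
    the real records, so this is an explicit modelling assumption.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    traces = predict_dfs_series(
        model,
        true_params,
        site.daily_temp,
        site.latitude,
        alan=site.alan,
        lud_anomalies=site.lud_anomalies(),
        tss_by_year=site.tss_by_year(model.tss_months),
    )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=site.n_years) if noise_sd > 0 else np.zeros(site.n_years)
    observed = np.full(site.n_years, np.nan)
    for i, year in enumerate(site.years.tolist()):
        tr = traces[year]
        if tr.crossing_day is not None:
            observed[i] = float(tr.crossing_day) + (np.round(noise[i]) if noise_sd > 0 else 0.0)
    out = dataclasses.replace(site, dfs_observed=observed)
    out.truth = {"model": model.name, "params": dict(true_params.values), "noise_sd": noise_sd}
    return out


def inject_outliers(dfs_series, fraction: float, magnitude: float, seed: int):
    """Corrupt round(fraction * n) entries by +/- magnitude days.

    Returns (corrupted series, boolean mask of true outlier positions); only
    non-missing entries are eligible for corruption.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    x = np.asarray(dfs_series, dtype=float).copy()
    mask = np.zeros(x.size, dtype=bool)
    n_out = int(round(fraction * x.size))
    if n_out == 0:
        return x, mask
    rng = np.random.default_rng(seed)
    eligible = np.nonzero(np.isfinite(x))[0]
    if n_out > eligible.size:
        raise ValueError("not enough non-missing values to corrupt")
    idx = rng.choice(eligible, size=n_out, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_out)
    x[idx] += signs * magnitude
    mask[idx] = True
    return x, mask


# ---------------------------------------------------------------------------
# plain-CSV serialization of a site bundle (see docs/data_dictionary.md)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_site_bundle(sites: list[SiteDataset], outdir) -> dict:
    """Write daily_temperature.csv, annual_series.csv, monthly_climate.csv + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    daily_rows = []
    for s in sites:
        for year in s.years.tolist():
            temps = s.daily_temp[int(year)]
            daily_rows.append(
                pd.DataFrame({
                    "site_id": s.site_id,
                    "year": int(year),
                    "doy": np.arange(1, DAYS_PER_YEAR + 1),
                    "temperature_c": temps,
                })
            )
    pd.concat(daily_rows, ignore_index=True).to_csv(
        outdir / "daily_temperature.csv", index=False, float_format=_FLOAT_FMT
    )

    annual_rows = []
    for s in sites:
        annual_rows.append(
            pd.DataFrame({
                "site_id": s.site_id,
                "latitude": s.latitude,
                "year": s.years,
                "alan_nw": s.alan.alan_year,
                "lud_doy": s.lud,
                "gdp": s.gdp,
                "dfs_observed_doy": (
                    s.dfs_observed if s.dfs_observed is not None else np.full(s.n_years, np.nan)
                ),
            })
        )
    pd.concat(annual_rows, ignore_index=True).to_csv(
        outdir / "annual_series.csv", index=False, float_format=_FLOAT_FMT
    )

    monthly_rows = []
    for s in sites:
        for i, year in enumerate(s.years.tolist()):
            monthly_rows.append(
                pd.DataFrame({
                    "site_id": s.site_id,
                    "year": int(year),
                    "month": np.arange(1, 13),
                    "precip_mm": s.monthly_precip[i],
                    "shortwave_wm2": s.monthly_shortwave[i],
                })
            )
    pd.concat(monthly_rows, ignore_index=True).to_csv(
        outdir / "monthly_climate.csv", index=False, float_format=_FLOAT_FMT
    )

    manifest = {
        "n_sites": len(sites),
        "year_start": int(min(int(s.years.min()) for s in sites)),
        "year_end": int(max(int(s.years.max()) for s in sites)),
        "tables": ["daily_temperature.csv", "annual_series.csv", "monthly_climate.csv"],
    }
    with open(outdir / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    return manifest


def read_site_bundle(indir) -> list[SiteDataset]:
    """Reconstruct SiteDataset objects from a written bundle."""
    indir = Path(indir)
    daily = pd.read_csv(indir / "daily_temperature.csv")
    annual = pd.read_csv(indir / "annual_series.csv")
    monthly = pd.read_csv(indir / "monthly_climate.csv")

    sites = []
    for site_id, ann in annual.groupby("site_id"):
        ann = ann.sort_values("year")
        years = ann["year"].to_numpy()
        d_site = daily[daily["site_id"] == site_id]
        daily_temp = {
            int(y): g.sort_values("doy")["temperature_c"].to_numpy()
            for y, g in d_site.groupby("year")
        }
        m_site = monthly[monthly["site_id"] == site_id]
        precip = np.vstack([
            m_site[m_site["year"] == y].sort_values("month")["precip_mm"].to_numpy()
            for y in years
        ])
        sw = np.vstack([
            m_site[m_site["year"] == y].sort_values("month")["shortwave_wm2"].to_numpy()
            for y in years
        ])
        dfs = ann["dfs_observed_doy"].to_numpy()
        sites.append(
            SiteDataset(
                site_id=int(site_id),
                latitude=float(ann["latitude"].iloc[0]),
                years=years,
                daily_temp=daily_temp,
                alan=AnnualAlanSeries(years, ann["alan_nw"].to_numpy()),
                monthly_precip=precip,
                monthly_shortwave=sw,
                lud=ann["lud_doy"].to_numpy(dtype=float),
                gdp=ann["gdp"].to_numpy(dtype=float),
                dfs_observed=None if np.all(np.isnan(dfs)) else dfs,
            )
        )
    return sites
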