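"""Artificial-light-at-night (ALAN) transforms.

Night-length astronomy, monthly disaggregation of annual radiance, the
exponential ALAN forcing coefficient used by the light-enhanced senescence
models, the MAD outlier filter for in-situ senescence records, resource-use
efficiency ratios, and the ALAN-GDP regression used to extend radiance into
future scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._calendar import DAYS_PER_YEAR, doys_of_month

__all__ = [
    "AnnualAlanSeries",
    "NightLengthTable",
    "night_length",
    "day_length",
    "monthly_night_hours",
    "disaggregate_alan_monthly",
    "alan_forcing_coefficient",
    "mad_filter",
    "efficiency_ratios",
    "fit_alan_gdp_regression",
    "project_future_alan",
]


@dataclass(frozen=True)
class AnnualAlanSeries:
    """One site's annual nighttime-radiance record (nW cm-2 sr-1)."""

    years: np.ndarray
    alan_year: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        vals = np.asarray(self.alan_year, dtype=float)
        if years.shape != vals.shape or years.ndim != 1:
            raise ValueError("years and alan_year must be 1-d and equal length")
        if vals.size == 0:
            raise ValueError("empty ALAN series")
        if np.any(vals < 0):
            raise ValueError("ALAN radiance must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "alan_year", vals)

    @property
    def alan_max(self) -> float:
        return float(self.alan_year.max())

    @property
    def alan_mean(self) -> float:
        return float(self.alan_year.mean())

    def value_for(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in ALAN series")
        return float(self.alan_year[idx[0]])


@dataclass(frozen=True)
class NightLengthTable:
    """Mean nightly hours per calendar month at one latitude."""

    latitude: float
    nh_month: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.nh_month is None:
            object.__setattr__(self, "nh_month", monthly_night_hours(self.latitude))
        nh = np.asarray(self.nh_month, dtype=float)
        if nh.shape != (12,):
            raise ValueError("nh_month must have 12 entries")
        if np.any(nh < 0) or np.any(nh > 24):
            raise ValueError("night hours must lie in [0, 24]")
        object.__setattr__(self, "nh_month", nh)


def _declination_rad(doy: np.ndarray | float) -> np.ndarray | float:
    """Solar declination (radians), standard 23.44 deg sine approximation."""
    return np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + np.asarray(doy, dtype=float)) / 365.0)


def day_length(latitude: float, doy) -> np.ndarray | float:
    """Hours of daylight from the declination / hour-angle formula.

    cos(hour angle) is clamped to [-1, 1] so polar day yields 24 h and
    polar night 0 h instead of a domain error.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must be in [-90, 90], got {latitude}")
    doy_arr = np.asarray(doy, dtype=float)
    if np.any(doy_arr < 1) or np.any(doy_arr > DAYS_PER_YEAR):
        raise ValueError("doy must be in [1, 365]")
    phi = np.deg2rad(latitude)
    delta = _declination_rad(doy_arr)
    cos_h0 = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_h0)
    return hours if np.ndim(doy) else float(hours)


def night_length(latitude: float, doy) -> np.ndarray | float:
    """Hours of darkness: 24 minus :func:`day_length`."""
    dl = day_length(latitude, doy)
    return 24.0 - dl


def monthly_night_hours(latitude: float) -> np.ndarray:
    """Mean nightly hours for each of the 12 calendar months."""
    return np.array(
        [float(np.mean(night_length(latitude, doys_of_month(m)))) for m in range(1, 13)]
    )


def disaggregate_alan_monthly(alan_year: float, latitude: float) -> np.ndarray:
    """Split an annual ALAN value into 12 months weighted by night length.

    ALAN_month = NH_month * 12 / sum(NH_month) * ALAN_year, so the mean of
    the 12 monthly values equals the annual value exactly.
    """
    if alan_year < 0:
        raise ValueError("annual ALAN must be non-negative")
    nh = monthly_night_hours(latitude)
    total = nh.sum()
    if total <= 0:
        raise ValueError("total night hours is zero; cannot disaggregate")
    return nh * 12.0 / total * alan_year


def alan_forcing_coefficient(alan_i, alan_max: float, k: float):
    """Annual light-forcing multiplier exp(k * (ALAN_i - ALAN_max) / ALAN_max).

    Equals 1 when ``alan_i == alan_max`` or ``k == 0``; strictly positive;
    monotone in ``alan_i`` with the sign of ``k``.
    """
    if alan_max <= 0:
        raise ValueError(f"alan_max must be positive, got {alan_max}")
    alan_i = np.asarray(alan_i, dtype=float)
    if np.any(alan_i < 0):
        raise ValueError("alan_i must be non-negative")
    out = np.exp(k * (alan_i - alan_max) / alan_max)
    return out if out.ndim else float(out)


def mad_filter(dfs_series, multiplier: float = 2.5):
    """Median-absolute-deviation outlier screen for senescence-date records.

    Flags index i when ``|x_i - median| > multiplier * MAD`` where
    MAD = median(|x_i - median(x)|).  With MAD = 0 (all values at the
    median) the strict inequality flags nothing.

    Returns
    -------
    kept : ndarray of the retained values
    mask : boolean ndarray, True where flagged as outlier
    """
    x = np.asarray(dfs_series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-d series of length >= 3 for a stable median/MAD")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    mask = dev > multiplier * mad
    return x[~mask], mask


def efficiency_ratios(gpp: float, et: float, sw: float, fpar: float):
    """Water- and light-use efficiency: GPP/ET and GPP/(SW*0.45*FPAR)."""
    if et <= 0:
        raise ValueError("evapotranspiration must be positive")
    if sw <= 0:
        raise ValueError("shortwave radiation must be positive")
    if not 0 < fpar <= 1:
        raise ValueError("FPAR must lie in (0, 1]")
    wue = gpp / et
    lue = gpp / (sw * 0.45 * fpar)
    return wue, lue


def _kfold_indices(n: int, folds: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return np.array_split(order, folds)


def fit_alan_gdp_regression(alan_mean, alan_year, gdp, folds: int = 5, seed: int = 0):
    """OLS of annual ALAN on (site-mean ALAN, ln GDP): ALAN_i = a*ALAN_mean + b*ln(GDP_i) + c.

    Fitted pooled across observations; accuracy summarized by k-fold
    cross-validated RMSE and R-squared.

    Parameters
    ----------
    alan_mean, alan_year, gdp : 1-d arrays of equal length (site-years)
    folds : number of CV folds (default 5)
    seed : shuffling seed for the fold assignment

    Returns
    -------
    dict with keys ``a``, ``b``, ``c``, ``cv_rmse`` (per fold),
    ``cv_r2`` (per fold).
    """
    alan_mean = np.asarray(alan_mean, dtype=float)
    alan_year = np.asarray(alan_year, dtype=float)
    gdp = np.asarray(gdp, dtype=float)
    n = alan_year.size
    if not (alan_mean.size == n == gdp.size):
        raise ValueError("input series must have equal length")
    if n < folds:
        raise ValueError(f"need at least {folds} observations for {folds}-fold CV")
    if np.any(gdp <= 0):
        raise ValueError("GDP must be positive (log is taken)")

    X = np.column_stack([alan_mean, np.log(gdp), np.ones(n)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design: predictors are collinear or constant")
    coef, *_ = np.linalg.lstsq(X, alan_year, rcond=None)

    rng = np.random.default_rng(seed)
    cv_rmse, cv_r2 = [], []
    for test_idx in _kfold_indices(n, folds, rng):
        train = np.setdiff1d(np.arange(n), test_idx)
        if np.linalg.matrix_rank(X[train]) < 3:
            raise ValueError("singular design in a CV fold")
        c_fold, *_ = np.linalg.lstsq(X[train], alan_year[train], rcond=None)
        pred = X[test_idx] @ c_fold
        resid = alan_year[test_idx] - pred
        cv_rmse.append(float(np.sqrt(np.mean(resid**2))))
        ss_tot = float(np.sum((alan_year[test_idx] - alan_year[test_idx].mean()) ** 2))
        ss_res = float(np.sum(resid**2))
        cv_r2.append(1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan)

    return {
        "a": float(coef[0]),
        "b": float(coef[1]),
        "c": float(coef[2]),
        "cv_rmse": cv_rmse,
        "cv_r2": cv_r2,
    }


def project_future_alan(coefficients, alan_mean: float, gdp_path) -> np.ndarray:
    """Apply the fitted ALAN-GDP relation to a future GDP path, floored at 0."""
    gdp_path = np.asarray(gdp_path, dtype=float)
    if np.any(gdp_path <= 0):
        raise ValueError("GDP path must be positive")
    if isinstance(coefficients, dict):
        a, b, c = coefficients["a"], coefficients["b"], coefficients["c"]
    else:
        a, b, c = coefficients
    return np.maximum(a * alan_mean + b * np.log(gdp_path) + c, 0.0)
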