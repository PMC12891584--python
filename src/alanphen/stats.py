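"""Trend and sensitivity statistics.

Linear detrending to standardized anomalies, Theil-Sen slopes with the
Mann-Kendall significance test, partial correlations, preseason-window
optimization, ridge-regression driver sensitivities, moving-window
modulation of climate sensitivity by nighttime light, and the Gaussian
fit of light sensitivity against light intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from ._calendar import month_of_doy

__all__ = [
    "SensitivityEstimate",
    "GaussianResponseFit",
    "detrend_normalize",
    "theil_sen",
    "mann_kendall",
    "partial_correlation",
    "optimal_preseason",
    "ridge_sensitivities",
    "moving_window_modulation",
    "fit_gaussian_response",
    "gaussian_response",
]


@dataclass(frozen=True)
class SensitivityEstimate:
    """Preseason length and strength of one driver's association with DFS."""

    driver: str
    preseason_length: int
    partial_r: float
    p_value: float
    ridge_coeff: float | None = None

    def __post_init__(self):
        if not 1 <= self.preseason_length <= 12:
            raise ValueError("preseason_length out of range")
        if not -1.0 - 1e-12 <= self.partial_r <= 1.0 + 1e-12:
            raise ValueError("partial_r must lie in [-1, 1]")


@dataclass(frozen=True)
class GaussianResponseFit:
    """Parameters of y = amplitude * exp(-(x - center)^2 / width)."""

    amplitude: float
    center: float
    width: float
    goodness: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")

    def __call__(self, x):
        return gaussian_response(x, self.amplitude, self.center, self.width)


def detrend_normalize(series) -> np.ndarray:
    """Standardized anomalies: OLS-on-year residuals scaled to unit sd."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("need at least 4 values to detrend")
    t = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise ValueError("zero residual variance; series is exactly linear")
    return resid / sd


def mann_kendall(series) -> tuple[float, float]:
    """Mann-Kendall trend test: statistic S and two-sided normal-approx p.

    Variance uses the standard tie correction; |S| gets the usual
    continuity correction.  No pre-whitening is applied.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values for the Mann-Kendall test")
    s = 0.0
    for i in range(n - 1):
        s += np.sign(x[i + 1 :] - x[i]).sum()
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        return float(s), 1.0
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return float(s), float(p)


def theil_sen(series) -> tuple[float, float]:
    """Theil-Sen slope per step plus the Mann-Kendall p-value.

    The slope is the median of all pairwise slopes (y_j - y_i)/(j - i).
    """
    y = np.asarray(series, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 values for a Theil-Sen trend")
    slope = float(sps.theilslopes(y, np.arange(y.size)).slope)
    _, p = mann_kendall(y)
    return slope, p


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(v.size), controls])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, controls=None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing both on controls.

    Two-sided t-test with n - #controls - 2 degrees of freedom.  With no
    controls this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    n = x.size
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        z = np.empty((n, 0))
    else:
        z = np.column_stack(controls) if isinstance(controls, (list, tuple)) else np.asarray(controls, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    q = z.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > {q + 2} observations with {q} controls")
    if q > 0 and np.linalg.matrix_rank(np.column_stack([np.ones(n), z])) < q + 1:
        raise ValueError("controls are collinear")
    rx = _residualize(x, z) if q else x - x.mean()
    ry = _residualize(y, z) if q else y - y.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom <= 0:
        raise ValueError("zero variance after residualization")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    df = n - q - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


def _window_months(anchor_month: int, length: int) -> list[tuple[int, int]]:
    """(year offset, month) pairs for the window ending at the anchor month."""
    out = []
    for back in range(length - 1, -1, -1):
        m = anchor_month - back
        out.append((-1, m + 12) if m < 1 else (0, m))
    return out


def _window_mean(monthly: np.ndarray, years: np.ndarray, data_years: np.ndarray,
                 anchor_month: int, length: int) -> np.ndarray:
    """Per-year mean of a (n_data_years, 12) monthly table over a window.

    Windows may reach into the previous calendar year; a missing previous
    year raises.
    """
    months = _window_months(anchor_month, length)
    year_index = {int(y): i for i, y in enumerate(data_years)}
    out = np.empty(years.size)
    for j, y in enumerate(years):
        vals = []
        for off, m in months:
            yy = int(y) + off
            if yy not in year_index:
                raise ValueError(
                    f"monthly coverage missing for year {yy} (window of length {length} "
                    f"ending in month {anchor_month})"
                )
            vals.append(monthly[year_index[yy], m - 1])
        out[j] = np.mean(vals)
    return out


def optimal_preseason(
    dfs,
    dfs_years,
    driver_monthly,
    driver_name: str = "driver",
    other_drivers: dict | None = None,
    data_years=None,
    max_months: int = 6,
) -> SensitivityEstimate:
    """Find the preseason length whose windowed driver best explains DFS.

    The anchor month is the calendar month of the multi-year mean DFS.  For
    each candidate length L = 1..max_months the driver (and each control
    driver) is averaged over the L months ending at the anchor, detrended
    and standardized, then partially correlated with detrended DFS
    controlling for the other drivers at the same window.  Returns the L
    with the largest |partial r| (ties broken toward the shorter window).

    Parameters
    ----------
    dfs : annual senescence dates (DOY), one per entry of ``dfs_years``
    driver_monthly : (n_data_years, 12) monthly values of the driver
    other_drivers : mapping name -> (n_data_years, 12) control tables
    data_years : years indexing the monthly tables (defaults to dfs_years);
        must include the year before ``dfs_years[0]`` if any candidate
        window crosses the calendar boundary
    """
    dfs = np.asarray(dfs, dtype=float)
    dfs_years = np.asarray(dfs_years, dtype=int)
    if data_years is None:
        data_years = dfs_years
    data_years = np.asarray(data_years, dtype=int)
    other_drivers = other_drivers or {}
    if not 1 <= max_months <= 12:
        raise ValueError("max_months must lie in [1, 12]")

    ok = np.isfinite(dfs)
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-missing DFS years")
    dfs_use, years_use = dfs[ok], dfs_years[ok]
    anchor = month_of_doy(int(round(float(dfs_use.mean()))))

    dfs_anom = detrend_normalize(dfs_use)
    best = None
    for length in range(1, max_months + 1):
        drv = detrend_normalize(
            _window_mean(np.asarray(driver_monthly, float), years_use, data_years, anchor, length)
        )
        controls = [
            detrend_normalize(
                _window_mean(np.asarray(tbl, float), years_use, data_years, anchor, length)
            )
            for tbl in other_drivers.values()
        ]
        r, p = partial_correlation(drv, dfs_anom, controls if controls else None)
        if best is None or abs(r) > abs(best[1]) + 1e-15:
            best = (length, r, p)
    length, r, p = best
    return SensitivityEstimate(driver=driver_name, preseason_length=length, partial_r=r, p_value=p)


def ridge_sensitivities(dfs_anom, drivers, penalty: float = 1.0) -> np.ndarray:
    """L2-penalized regression coefficients of DFS anomalies on driver anomalies.

    The intercept is unpenalized (fitted by centering); ``penalty = 0``
    reduces to OLS.  Inputs are expected already standardized, so the
    coefficients are sensitivities in days (or sd of DFS) per standardized
    unit of each driver.
    """
    y = np.asarray(dfs_anom, dtype=float)
    X = np.asarray(drivers, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    n, p = X.shape
    if y.size != n or n <= 2:
        raise ValueError("need matching inputs with more than 2 observations")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Xc.T @ Xc + penalty * np.eye(p), Xc.T @ yc)
    return beta


def moving_window_modulation(annual_alan, climate_sensitivity, window: int = 11, step: int = 1):
    """Correlate moving-window means of ALAN with climate sensitivity.

    Returns (number of windows, Pearson r, two-sided p).  A series of 22
    years with an 11-year window and 1-year step yields 12 windows.
    """
    a = np.asarray(annual_alan, dtype=float)
    c = np.asarray(climate_sensitivity, dtype=float)
    if a.shape != c.shape or a.ndim != 1:
        raise ValueError("series must be 1-d and equal length")
    n = a.size
    if window < 2 or window > n:
        raise ValueError("window must lie in [2, series length]")
    starts = range(0, n - window + 1, step)
    alan_w = np.array([a[s : s + window].mean() for s in starts])
    clim_w = np.array([c[s : s + window].mean() for s in starts])
    n_windows = alan_w.size
    if n_windows < 2:
        raise ValueError("fewer than 2 windows; correlation undefined")
    r, p = sps.pearsonr(alan_w, clim_w)
    return n_windows, float(r), float(p)


def gaussian_response(x, amplitude, center, width):
    """Evaluate amplitude * exp(-(x - center)^2 / width)."""
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-((x - center) ** 2) / width)


def fit_gaussian_response(sv_values, alan_values, maxfev: int = 20000) -> GaussianResponseFit:
    """Nonlinear least squares of sensitivity against light intensity.

    Fits y = A exp(-(x - x0)^2 / w) from a deterministic neutral start:
    A = signed y at max |y|, x0 = the corresponding x, w = (x range)^2 / 4.
    Goodness is the Pearson correlation between fitted and observed y.
    """
    y = np.asarray(sv_values, dtype=float)
    x = np.asarray(alan_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if x.size < 10:
        raise ValueError("need at least 10 points for a 3-parameter fit")
    if np.ptp(x) <= 0:
        raise ValueError("x values are constant; fit is degenerate")
    if np.ptp(y) <= 0:
        raise ValueError("y values are constant; width is unidentifiable")

    i0 = int(np.argmax(np.abs(y)))
    p0 = (y[i0], x[i0], (np.ptp(x) ** 2) / 4.0)
    try:
        popt, _ = optimize.curve_fit(
            gaussian_response, x, y, p0=p0, maxfev=maxfev,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian response fit did not converge: {exc}") from exc
    fitted = gaussian_response(x, *popt)
    goodness = float(sps.pearsonr(fitted, y)[0]) if np.ptp(fitted) > 0 else np.nan
    return GaussianResponseFit(
        amplitude=float(popt[0]), center=float(popt[1]), width=float(popt[2]), goodness=goodness
    )
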