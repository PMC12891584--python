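"""Process-based autumn-senescence models and their light-enhanced variants.

Four model families predict the date of foliar senescence (DFS) from daily
temperature and photoperiod:

* **CDD** — cooling-degree-day accumulation below a threshold temperature.
* **DM**  — daily rate ``max(T_b - T, 0)^x * f(P)^y`` accumulated to a fixed
  critical state ``Y_crit``.
* **SIAM** — DM with ``Y_crit = a + b * LUD_anomaly`` (spring carry-over).
* **DMT** — DM with ``Y_crit = a + b * Tss`` (spring-summer mean temperature).

Each family has an ALAN-enhanced variant in which every daily increment is
multiplied by an annual coefficient ``exp(k * (ALAN_i - ALAN_max)/ALAN_max)``
so that nighttime-light intensity modulates the forcing rate.

Conventions: 365-day years, DOY 1-based, accumulation starts no earlier than
the northern summer solstice (DOY 172).  A year whose state never reaches the
threshold by DOY 365 has no predicted date (``crossing_day is None``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._calendar import DAYS_PER_YEAR, SOLSTICE_DOY, doys_of_month
from .alan import AnnualAlanSeries, alan_forcing_coefficient, day_length

__all__ = [
    "MODEL_FAMILIES",
    "SenescenceModelSpec",
    "ModelParams",
    "SenescenceTrace",
    "DEFAULT_BOUNDS",
    "param_names",
    "photoperiod_response",
    "spring_summer_mean_temp",
    "lud_anomaly",
    "predict_dfs",
    "predict_dfs_series",
]

MODEL_FAMILIES = ("CDD", "DM", "SIAM", "DMT")

_BASE_PARAMS = {
    "CDD": ("t_th", "cdd_th"),
    "DM": ("t_b", "p_s", "x", "y", "y_crit"),
    "SIAM": ("t_b", "p_s", "x", "y", "a", "b"),
    "DMT": ("t_b", "p_s", "x", "y", "a", "b"),
}

# t_th range and x, y in [0, 2] follow the published calibration ranges;
# the rest are pragmatic search boxes (see repo docs).
DEFAULT_BOUNDS = {
    "t_th": (0.0, 50.0),
    "cdd_th": (1.0, 1000.0),
    "t_b": (0.0, 40.0),
    "p_s": (6.0, 24.0),
    "x": (0.0, 2.0),
    "y": (0.0, 2.0),
    "y_crit": (1.0, 500.0),
    "a": (1.0, 500.0),
    "b": (-50.0, 50.0),
    "k": (-10.0, 10.0),
}

DEFAULT_TSS_MONTHS = frozenset({3, 4, 5, 6, 7, 8})


@dataclass(frozen=True)
class SenescenceModelSpec:
    """Which model family to run and how."""

    family: str
    alan_enabled: bool = False
    photoperiod_variant: str = "ratio"
    tss_months: frozenset = DEFAULT_TSS_MONTHS

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}")
        if self.photoperiod_variant not in ("ratio", "one_minus_ratio"):
            raise ValueError("photoperiod_variant must be 'ratio' or 'one_minus_ratio'")
        if self.family == "DMT" and not self.tss_months:
            raise ValueError("DMT requires a non-empty tss_months set")
        object.__setattr__(self, "tss_months", frozenset(int(m) for m in self.tss_months))

    @property
    def name(self) -> str:
        return self.family + ("_ALAN" if self.alan_enabled else "")

    @property
    def param_count(self) -> int:
        return len(param_names(self))


def param_names(spec: SenescenceModelSpec) -> tuple[str, ...]:
    """Ordered parameter names for a model spec (``k`` last when ALAN on)."""
    names = _BASE_PARAMS[spec.family]
    return names + ("k",) if spec.alan_enabled else names


@dataclass(frozen=True)
class ModelParams:
    """Named parameter values for one model spec, validated against bounds."""

    spec: SenescenceModelSpec
    values: dict
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        names = param_names(self.spec)
        missing = set(names) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters for {self.spec.name}: {sorted(missing)}")
        merged = {**DEFAULT_BOUNDS, **self.bounds}
        for nm in names:
            lo, hi = merged[nm]
            v = float(self.values[nm])
            if not lo <= v <= hi:
                raise ValueError(f"parameter {nm}={v} outside bounds [{lo}, {hi}]")
        object.__setattr__(self, "values", {nm: float(self.values[nm]) for nm in names})
        object.__setattr__(self, "bounds", merged)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_vector(self) -> np.ndarray:
        return np.array([self.values[nm] for nm in param_names(self.spec)])

    @classmethod
    def from_vector(cls, spec: SenescenceModelSpec, vector, bounds: dict | None = None):
        names = param_names(spec)
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(names),):
            raise ValueError(f"expected {len(names)} values for {spec.name}, got {vector.shape}")
        return cls(spec, dict(zip(names, vector)), bounds or {})


@dataclass
class SenescenceTrace:
    """Per-day accumulation record for one site-year.

    ``daily_state`` is the cumulative senescence state (365 values,
    non-decreasing from onset); ``crossing_day`` is the first DOY where it
    reaches ``threshold``, or ``None`` when the threshold is never reached
    (``valid`` stays True) or the year is structurally invalid, e.g. a
    non-positive threshold from the SIAM/DMT linear relation (``valid``
    False with a ``reason``).
    """

    year: int | None
    onset_day: int | None
    daily_increment: np.ndarray
    daily_state: np.ndarray
    crossing_day: int | None
    threshold: float
    alanin_applied: float
    valid: bool = True
    reason: str | None = None


def photoperiod_response(p, p_s: float, variant: str = "ratio"):
    """Photoperiod factor f(P): ``P/P_s`` or ``1 - P/P_s``, floored at 0."""
    if p_s <= 0:
        raise ValueError(f"p_s must be positive, got {p_s}")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 24):
        raise ValueError("photoperiod must lie in [0, 24] hours")
    if variant == "ratio":
        out = p / p_s
    elif variant == "one_minus_ratio":
        out = 1.0 - p / p_s
    else:
        raise ValueError(f"unknown photoperiod variant {variant!r}")
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def spring_summer_mean_temp(daily_temp, months) -> float:
    """Mean daily temperature over the given calendar months."""
    if not months:
        raise ValueError("months must be non-empty")
    temp = np.asarray(daily_temp, dtype=float)
    if temp.shape != (DAYS_PER_YEAR,):
        raise ValueError(f"daily_temp must have {DAYS_PER_YEAR} values")
    doys = np.concatenate([doys_of_month(m) for m in sorted(months)])
    return float(temp[doys - 1].mean())


def lud_anomaly(lud_series) -> np.ndarray:
    """Leaf-unfolding-date anomalies: LUD_i minus the multi-year mean.

    NaNs are ignored in the mean and propagated in the output; anomalies of
    the non-missing years sum to zero.
    """
    lud = np.asarray(lud_series, dtype=float)
    ok = np.isfinite(lud)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing LUD years")
    out = np.full_like(lud, np.nan)
    out[ok] = lud[ok] - lud[ok].mean()
    return out


@lru_cache(maxsize=64)
def _photoperiod_cache(latitude: float) -> np.ndarray:
    return np.asarray(day_length(latitude, np.arange(1, DAYS_PER_YEAR + 1)))


def _pow_or_zero(base: np.ndarray, exponent: float) -> np.ndarray:
    """base**exponent on the clamped non-negative base, with 0**0 := 0."""
    out = np.zeros_like(base)
    pos = base > 0
    out[pos] = base[pos] ** exponent
    return out


def _resolve_threshold(spec, params, lud_anom, tss):
    if spec.family == "CDD":
        return params["cdd_th"]
    if spec.family == "DM":
        return params["y_crit"]
    if spec.family == "SIAM":
        if lud_anom is None or not np.isfinite(lud_anom):
            raise ValueError("SIAM requires a leaf-unfolding-date anomaly for the year")
        return params["a"] + params["b"] * float(lud_anom)
    # DMT
    if tss is None or not np.isfinite(tss):
        raise ValueError("DMT requires a spring-summer mean temperature for the year")
    return params["a"] + params["b"] * float(tss)


def predict_dfs(
    spec: SenescenceModelSpec,
    params: ModelParams,
    daily_temp,
    latitude: float,
    year: int | None = None,
    alan: AnnualAlanSeries | None = None,
    lud_anomaly_value: float | None = None,
    tss: float | None = None,
) -> SenescenceTrace:
    """Run one model for one site-year and return the full daily trace.

    Onset is the first DOY at or after the summer solstice where the start
    condition holds (CDD: ``T < T_th``; DM family: ``T <= T_b`` and
    ``P <= P_s``).  From onset the daily increment is the model rate times
    the annual ALAN coefficient (1 when ALAN is off); the predicted DFS is
    the first day the cumulative state reaches the family threshold.
    """
    temp = np.asarray(daily_temp, dtype=float)
    if temp.shape != (DAYS_PER_YEAR,):
        raise ValueError(f"daily_temp must have exactly {DAYS_PER_YEAR} values")
    if params.spec != spec:
        raise ValueError("params were built for a different model spec")

    if spec.alan_enabled:
        if alan is None or year is None:
            raise ValueError("ALAN-enabled model requires the annual ALAN series and a year")
        alanin = alan_forcing_coefficient(alan.value_for(year), alan.alan_max, params["k"])
    else:
        alanin = 1.0

    if spec.family == "DMT" and tss is None:
        tss = spring_summer_mean_temp(temp, spec.tss_months)
    try:
        threshold = _resolve_threshold(spec, params, lud_anomaly_value, tss)
    except ValueError:
        raise
    zeros = np.zeros(DAYS_PER_YEAR)
    if threshold <= 0:
        return SenescenceTrace(year, None, zeros, zeros.copy(), None, float(threshold),
                               alanin, valid=False, reason="non-positive threshold")

    start = SOLSTICE_DOY - 1  # 0-based index of the solstice
    if spec.family == "CDD":
        started = temp < params["t_th"]
        rate = np.maximum(params["t_th"] - temp, 0.0)
    else:
        photo = _photoperiod_cache(float(latitude))
        started = (temp <= params["t_b"]) & (photo <= params["p_s"])
        base = np.maximum(params["t_b"] - temp, 0.0)
        f = photoperiod_response(photo, params["p_s"], spec.photoperiod_variant)
        rate = _pow_or_zero(base, params["x"]) * _pow_or_zero(np.asarray(f), params["y"])

    onset_candidates = np.nonzero(started[start:])[0]
    if onset_candidates.size == 0:
        return SenescenceTrace(year, None, zeros, zeros.copy(), None, float(threshold), alanin)
    onset_idx = start + int(onset_candidates[0])

    increment = np.zeros(DAYS_PER_YEAR)
    increment[onset_idx:] = rate[onset_idx:] * alanin
    state = np.cumsum(increment)
    crossed = np.nonzero(state >= threshold)[0]
    crossing = int(crossed[0]) + 1 if crossed.size else None
    return SenescenceTrace(
        year, onset_idx + 1, increment, state, crossing, float(threshold), float(alanin)
    )


def predict_dfs_series(
    spec: SenescenceModelSpec,
    params: ModelParams,
    daily_temp_by_year: dict,
    latitude: float,
    alan: AnnualAlanSeries | None = None,
    lud_anomalies: dict | None = None,
    tss_by_year: dict | None = None,
) -> dict:
    """Run :func:`predict_dfs` over multiple years; returns year -> trace."""
    traces = {}
    for year, temp in daily_temp_by_year.items():
        traces[year] = predict_dfs(
            spec,
            params,
            temp,
            latitude,
            year=year,
            alan=alan,
            lud_anomaly_value=None if lud_anomalies is None else lud_anomalies.get(year),
            tss=None if tss_by_year is None else tss_by_year.get(year),
        )
    return traces
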