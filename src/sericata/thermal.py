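"""Degree-hour / degree-day arithmetic and base-temperature estimation.

The thermal-summation model treats development as the accumulation of
temperature excess above a developmental zero (base temperature T0):

    ADH (degree hours) = time_h  x (T - T0)
    ADD (degree days)  = time_d  x (T - T0)

T0 is estimated as the x-intercept of an ordinary least-squares regression of
development rate on rearing temperature; the thermal constant K is the total
ADD required to complete development, ideally temperature-invariant under the
linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import constants


@dataclass(frozen=True)
class ThermalParams:
    """Thermal-summation parameters.

    Parameters
    ----------
    base_temp_c
        Developmental zero T0 in °C. Defaults to the packaged egg-to-adult
        value 9.0734 °C.
    clamp_negative
        If True (default), temperature increments below the base contribute
        zero (no development, never "negative age"). The unclamped mode is
        provided for sensitivity analysis only.
    """

    base_temp_c: float = constants.BASE_TEMP_C
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_temp_c):
            raise ValueError("base_temp_c must be finite")

    def excess(self, temp_c: float | np.ndarray) -> float | np.ndarray:
        """Effective temperature excess above base (clamped if configured)."""
        d = np.asarray(temp_c, dtype=float) - self.base_temp_c
        if self.clamp_negative:
            d = np.maximum(d, 0.0)
        return d if d.ndim else float(d)


@dataclass(frozen=True)
class TemperatureSeries:
    """Hourly mean temperatures on consecutive clock hours.

    Each value covers the half-open hour interval [t, t+1). Gaps must be
    filled before construction; sub-hourly records must be pre-averaged.
    """

    temps_c: np.ndarray
    start: object = 0  # hour index (int) or pandas Timestamp of the first hour

    def __post_init__(self) -> None:
        t = np.asarray(self.temps_c, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("temperature series needs at least one hourly value")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature series contains missing/non-finite values")
        object.__setattr__(self, "temps_c", t)

    def __len__(self) -> int:
        return self.temps_c.size

    @property
    def n_hours(self) -> int:
        return self.temps_c.size

    @classmethod
    def constant(cls, temp_c: float, hours: int, start: object = 0) -> "TemperatureSeries":
        return cls(np.full(int(hours), float(temp_c)), start)

    def concat(self, other: "TemperatureSeries") -> "TemperatureSeries":
        return TemperatureSeries(np.concatenate([self.temps_c, other.temps_c]), self.start)


@dataclass(frozen=True)
class LinearRateFit:
    """OLS fit of development rate on temperature."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    rate_scale: str = constants.RATE_SCALE_LABEL


def degree_hours(duration_h: float, temp_c: float, params: ThermalParams) -> float:
    """ADH accumulated over ``duration_h`` hours at constant ``temp_c``."""
    if duration_h < 0:
        raise ValueError("negative duration")
    return float(duration_h) * float(params.excess(temp_c))


def degree_days(duration_d: float, temp_c: float, params: ThermalParams) -> float:
    """ADD accumulated over ``duration_d`` days at constant ``temp_c``.

    Satisfies ``degree_days(d, T) == degree_hours(24 d, T) / 24`` exactly.
    """
    if duration_d < 0:
        raise ValueError("negative duration")
    return float(duration_d) * float(params.excess(temp_c))


def accumulate_adh(series: TemperatureSeries, params: ThermalParams) -> np.ndarray:
    """Cumulative ADH profile over an hourly record.

    Returns an array of length ``n_hours + 1``; ``profile[k]`` is the ADH
    accumulated over the first ``k`` hours (``profile[0] == 0``). Left-constant
    integration on half-open hour intervals; non-decreasing in clamped mode.
    """
    inc = params.excess(series.temps_c)
    out = np.empty(series.n_hours + 1)
    out[0] = 0.0
    np.cumsum(inc, out=out[1:])
    return out


def fit_rate_regression(
    points: Iterable[tuple[float, float]],
    temp_range: tuple[float, float] | None = None,
) -> LinearRateFit:
    """OLS of development rate on temperature.

    ``points`` are ``(temp_c, dev_time_days)`` pairs; each time is converted
    to a rate of ``1e4 / (dev_time_days * 24)`` (recorded in ``rate_scale``).
    ``temp_range`` optionally restricts the fit to a closed temperature
    interval, e.g. (20, 28) where the rate response is linear.
    """
    pts = [(float(t), float(d)) for t, d in points]
    if temp_range is not None:
        lo, hi = temp_range
        pts = [(t, d) for t, d in pts if lo <= t <= hi]
    if len(pts) < 3:
        raise ValueError("need at least 3 (temperature, time) points")
    temps = np.array([t for t, _ in pts])
    days = np.array([d for _, d in pts])
    if np.any(days <= 0):
        raise ValueError("development times must be positive")
    if np.ptp(temps) == 0:
        raise ValueError("zero temperature variance")
    rates = constants.RATE_SCALE / (days * 24.0)
    res = stats.linregress(temps, rates)
    return LinearRateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(pts),
    )


def base_temperature(fit: LinearRateFit) -> float:
    """Base temperature T0 as the x-intercept ``-intercept / slope``."""
    if fit.slope <= 0:
        raise ValueError("no positive thermal response")
    return -fit.intercept / fit.slope


def thermal_constant(
    times_and_temps: Sequence[tuple[float, float]], params: ThermalParams
) -> tuple[float, float]:
    """Thermal constant K: (mean, SD) of per-entry ADD.

    ``times_and_temps`` are ``(temp_c, dev_time_days)`` pairs; each entry
    contributes ``dev_time_days x (temp - base)`` ADD. SD uses the n-1
    denominator. All temperatures must exceed the base.
    """
    entries = [(float(t), float(d)) for t, d in times_and_temps]
    if len(entries) < 2:
        raise ValueError("need at least 2 entries")
    temps = np.array([t for t, _ in entries])
    days = np.array([d for _, d in entries])
    if np.any(temps <= params.base_temp_c):
        raise ValueError("all temperatures must exceed the base temperature")
    adds = days * (temps - params.base_temp_c)
    return float(adds.mean()), float(adds.std(ddof=1))
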