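"""Monthly arrival forecasting with population-growth adjustment.

Twelve-month-ahead point forecasts of monthly attendances (new patients and
follow-ups, per condition) from at least 24 months of history.  The model is
a transparent additive decomposition — level + linear trend + month-of-year
seasonality — fitted by ordinary least squares, after which month ``m`` of
the forecast is scaled by ``(1 + growth_rate)**(m/12)`` for an annual
population growth rate, and floored at zero.

Accuracy against a held-out period is reported as ``100 - MAPE`` (mean
absolute percentage error), clipped to [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import Condition

MIN_HISTORY_MONTHS = 24


@dataclass
class MonthlySeries:
    """A gap-free monthly attendance series for one condition and stream."""

    values: np.ndarray
    start_month: pd.Period = field(default_factory=lambda: pd.Period("2013-04", "M"))
    stream: str = "new"          # "new" or "followup"
    condition: Optional[Condition] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("monthly attendance values must be non-negative")
        if self.stream not in ("new", "followup"):
            raise ValueError(f"unknown stream {self.stream!r}")
        if not isinstance(self.start_month, pd.Period):
            self.start_month = pd.Period(self.start_month, "M")

    def __len__(self):
        return len(self.values)

    def month_of_year(self) -> np.ndarray:
        return (self.start_month.month - 1 + np.arange(len(self))) % 12


@dataclass
class MonthlyForecast:
    """Point forecast over ``horizon`` months, growth-adjusted."""

    point: np.ndarray
    growth_rate: float = 0.0
    start_month: Optional[pd.Period] = None
    stream: str = "new"
    condition: Optional[Condition] = None

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        if np.any(self.point < 0):
            raise ValueError("forecast values must be non-negative")

    @property
    def horizon(self) -> int:
        return len(self.point)


def _design(t: np.ndarray, moy: np.ndarray) -> np.ndarray:
    # intercept + trend + 11 month-of-year contrasts (December as baseline)
    cols = [np.ones_like(t, dtype=float), t.astype(float)]
    for m in range(11):
        cols.append((moy == m).astype(float))
    return np.column_stack(cols)


def forecast_arrivals(
    history: MonthlySeries,
    horizon: int = 12,
    growth_rate: float = 0.0,
) -> MonthlyForecast:
    """Forecast monthly arrivals by additive level+trend+seasonal smoothing.

    Requires at least 24 months of history (two passes over the seasonal
    pattern); shorter series raise an error suggesting a seasonal-naive
    fallback (repeat the last 12 observed months) which the caller must opt
    into explicitly by extending the history.
    """
    n = len(history)
    if n < MIN_HISTORY_MONTHS:
        raise ValueError(
            f"history has {n} months; need >= {MIN_HISTORY_MONTHS}. For short "
            "series use a seasonal-naive fallback (repeat the last 12 months) "
            "explicitly rather than fitting the seasonal smoother."
        )
    t = np.arange(n)
    moy = history.month_of_year()
    X = _design(t, moy)
    beta, *_ = np.linalg.lstsq(X, history.values, rcond=None)

    tf = np.arange(n, n + horizon)
    moyf = (history.start_month.month - 1 + tf) % 12
    point = _design(tf, moyf) @ beta
    m = np.arange(1, horizon + 1)
    point = point * (1.0 + growth_rate) ** (m / 12.0)
    point = np.maximum(point, 0.0)
    return MonthlyForecast(
        point=point,
        growth_rate=growth_rate,
        start_month=history.start_month + n,
        stream=history.stream,
        condition=history.condition,
    )


def forecast_accuracy(forecast, actual) -> float:
    """Forecast accuracy in percent: ``100 - MAPE``, clipped to [0, 100].

    Months with zero actual attendance are excluded from the MAPE with a
    warning (the percentage error is undefined there).
    """
    f = np.asarray(getattr(forecast, "point", forecast), dtype=float)
    a = np.asarray(getattr(actual, "values", actual), dtype=float)
    if f.shape != a.shape:
        raise ValueError(f"length mismatch: forecast {f.shape} vs actual {a.shape}")
    keep = a != 0
    if not keep.any():
        raise ValueError("actual series is all zero; accuracy undefined")
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-actual month(s) excluded from MAPE")
    mape = float(np.mean(np.abs((f[keep] - a[keep]) / a[keep]))) * 100.0
    return float(np.clip(100.0 - mape, 0.0, 100.0))


def seasonal_series(
    level: float,
    amplitude: float,
    noise_sd: float,
    n_months: int,
    seed: int,
    trend: float = 0.0,
    start_month: str | pd.Period = "2013-04",
    condition: Optional[Condition] = None,
    stream: str = "new",
) -> MonthlySeries:
    """Synthetic level+trend+sinusoidal-seasonal monthly series (test world)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_months)
    start = pd.Period(start_month, "M")
    moy = (start.month - 1 + t) % 12
    values = (level + trend * t + amplitude * np.sin(2 * np.pi * moy / 12.0)
              + rng.normal(0.0, noise_sd, n_months))
    return MonthlySeries(np.maximum(values, 0.0), start_month=start,
                         stream=stream, condition=condition)


def series_to_frame(series: Sequence[MonthlySeries]) -> pd.DataFrame:
    """Flatten series to the ``month,condition,stream,count`` CSV layout."""
    rows = []
    for s in series:
        for i, v in enumerate(s.values):
            rows.append((str(s.start_month + i),
                         s.condition.value if s.condition else "",
                         s.stream, float(v)))
    return pd.DataFrame(rows, columns=["month", "condition", "stream", "count"])


def frame_to_series(df: pd.DataFrame) -> list[MonthlySeries]:
    out = []
    for (cond, stream), grp in df.groupby(["condition", "stream"], sort=True):
        grp = grp.sort_values("month")
        months = pd.PeriodIndex(grp["month"], freq="M")
        if len(months) > 1 and not (np.diff(months.asi8) == 1).all():
            raise ValueError(f"missing months in series ({cond}, {stream})")
        out.append(MonthlySeries(
            grp["count"].to_numpy(float),
            start_month=months[0],
            stream=stream,
            condition=Condition(cond) if cond else None,
        ))
    return out
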