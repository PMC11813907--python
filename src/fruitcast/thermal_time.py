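"""Thermal time (growing degree days) after anthesis.

Greenhouse fruit growth is driven far more by accumulated heat than by
calendar time, so every downstream computation in this package works on a
physiological time axis: the cumulative sum of daily mean air temperatures
(degree-days, base 0 degC) since the flower opened (anthesis).

A :class:`TemperatureSeries` holds the greenhouse air-temperature log
reduced to daily means; a :class:`ThermalClock` binds one flower's anthesis
date to that series and maps calendar timestamps to thermal time tau
(degC d) and back.

Conventions
-----------
* Base temperature is 0 degC by default (a plain degree-day sum); a
  different base can be supplied and is subtracted from each daily mean
  (clipped at zero) before summation.
* Sub-daily logs are averaged into daily means on load. Partial trailing
  days of a query interval contribute (fraction of day) x (that day's
  mean), so internal arithmetic is in fractional days while the external
  API deals in calendar dates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, SchemaError

Timestamp = Union[str, _dt.date, _dt.datetime, np.datetime64, pd.Timestamp]

__all__ = [
    "TemperatureSeries",
    "ThermalClock",
    "cumulative_temperature",
    "invert_thermal_time",
    "mean_temperature",
    "read_temperature_csv",
]


def _to_ts(t: Timestamp) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts is pd.NaT:
        raise DomainError(f"unparseable timestamp: {t!r}")
    return ts


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily-mean air temperatures over a contiguous span of days.

    Parameters
    ----------
    days
        Consecutive calendar days (datetime64[D]).
    temps
        Daily mean temperatures, degC, finite.
    """

    days: np.ndarray
    temps: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype="datetime64[D]")
        temps = np.asarray(self.temps, dtype=float)
        if days.size == 0:
            raise DomainError("temperature series is empty")
        if days.size != temps.size:
            raise SchemaError("days and temps length mismatch")
        if not np.all(np.diff(days).astype(int) == 1):
            raise DomainError("temperature series must cover consecutive days without gaps")
        if not np.all(np.isfinite(temps)):
            raise DomainError("temperatures must be finite")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "temps", temps)
        # cumulative degree-days at each day *boundary*: _cum[k] covers days[0:k]
        object.__setattr__(self, "_cum", np.concatenate(([0.0], np.cumsum(temps))))

    # -- construction ---------------------------------------------------
    @classmethod
    def from_readings(
        cls, timestamps: Iterable[Timestamp], temps: Iterable[float]
    ) -> "TemperatureSeries":
        """Build a series from (possibly sub-daily) readings.

        Readings must be strictly increasing in time; each calendar day's
        readings are averaged into one daily mean.
        """
        ts = pd.DatetimeIndex([_to_ts(t) for t in timestamps])
        vals = np.asarray(list(temps), dtype=float)
        if len(ts) != len(vals):
            raise SchemaError("timestamps and temps length mismatch")
        if len(ts) == 0:
            raise DomainError("no readings supplied")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise DomainError("timestamps must be strictly increasing with no duplicates")
        daily = pd.Series(vals, index=ts).groupby(ts.floor("D")).mean()
        return cls(
            days=daily.index.values.astype("datetime64[D]"),
            temps=daily.to_numpy(),
        )

    # -- span -----------------------------------------------------------
    @property
    def start(self) -> _dt.date:
        """First covered day."""
        return pd.Timestamp(self.days[0]).date()

    @property
    def end(self) -> _dt.date:
        """Exclusive end: midnight after the last covered day."""
        return (pd.Timestamp(self.days[-1]) + pd.Timedelta(days=1)).date()

    def _offset_days(self, t: Timestamp) -> float:
        """Fractional days from the series start to ``t`` (validated in span)."""
        delta = (_to_ts(t) - pd.Timestamp(self.days[0])).total_seconds() / 86400.0
        if delta < 0 or delta > self.temps.size:
            raise CoverageError(
                f"{t} outside temperature record [{self.start}, {self.end})"
            )
        return delta

    def degree_days(self, start: Timestamp, end: Timestamp, base: float = 0.0) -> float:
        """Degree-days accumulated over [start, end), base-adjusted daily means."""
        a = self._offset_days(start)
        b = self._offset_days(end)
        if b < a:
            raise DomainError("end precedes start")
        if base == 0.0:
            cum = self._cum
            temps = self.temps
        else:
            temps = np.clip(self.temps - base, 0.0, None)
            cum = np.concatenate(([0.0], np.cumsum(temps)))

        def _c(x: float) -> float:
            k = int(np.floor(x))
            frac = x - k
            if k >= temps.size:  # exactly the final boundary
                return float(cum[-1])
            return float(cum[k] + frac * temps[k])

        return _c(b) - _c(a)


@dataclass(frozen=True)
class ThermalClock:
    """Maps calendar time to thermal time for one flower.

    ``anthesis`` is day zero of the clock; ``base`` is the base temperature
    subtracted from daily means before accumulation.
    """

    anthesis: _dt.date
    series: TemperatureSeries
    base: float = 0.0

    def __post_init__(self) -> None:
        a = _to_ts(self.anthesis)
        object.__setattr__(self, "anthesis", a.date() if a == a.normalize() else a)
        self.series._offset_days(self.anthesis)  # raises CoverageError if outside


def cumulative_temperature(clock: ThermalClock, t: Timestamp) -> float:
    """Thermal time tau (degC d) accumulated over [anthesis, t).

    Raises
    ------
    DomainError
        If ``t`` precedes anthesis.
    CoverageError
        If ``t`` lies beyond the temperature record.
    """
    if _to_ts(t) < _to_ts(clock.anthesis):
        raise DomainError(f"{t} precedes anthesis {clock.anthesis}")
    return clock.series.degree_days(clock.anthesis, t, base=clock.base)


def invert_thermal_time(clock: ThermalClock, target: float) -> _dt.date:
    """Earliest day boundary t with ``cumulative_temperature(clock, t) >= target``.

    Needed by the harvest rule of the simulator (harvest happens when a
    thermal threshold is crossed) and by anchor diagnostics.
    """
    if target < 0:
        raise DomainError("target thermal time must be non-negative")
    series = clock.series
    start_off = series._offset_days(clock.anthesis)
    k0 = int(np.ceil(start_off))
    if clock.base == 0.0:
        cum = series._cum
        temps = series.temps
    else:
        temps = np.clip(series.temps - clock.base, 0.0, None)
        cum = np.concatenate(([0.0], np.cumsum(temps)))
    ka = int(np.floor(start_off))
    c_anth = cum[ka] + (start_off - ka) * (temps[ka] if ka < temps.size else 0.0)
    # thermal time at each day boundary on/after anthesis
    rel = cum[k0:] - c_anth
    idx = int(np.searchsorted(rel, target, side="left"))
    if idx >= rel.size:
        raise CoverageError(
            f"target {target} degC d not reachable within record ending {series.end}"
        )
    return (pd.Timestamp(series.days[0]) + pd.Timedelta(days=k0 + idx)).date()


def mean_temperature(clock: ThermalClock, t_end: Timestamp) -> float:
    """Arithmetic mean of daily mean temperatures over [anthesis, t_end).

    Computed as accumulated degree-days divided by elapsed (fractional)
    days, so ``mean x elapsed == cumulative`` holds exactly.
    """
    a = clock.series._offset_days(clock.anthesis)
    b = clock.series._offset_days(t_end)
    if b <= a:
        raise DomainError("t_end must be after anthesis")
    return clock.series.degree_days(clock.anthesis, t_end, base=0.0) / (b - a)


def read_temperature_csv(path) -> TemperatureSeries:
    """Read a temperature log CSV with columns ``timestamp`` (ISO-8601), ``temp_c``.

    Rejects unsorted or duplicated timestamps.
    """
    df = pd.read_csv(path)
    missing = {"timestamp", "temp_c"} - set(df.columns)
    if missing:
        raise SchemaError(f"temperature CSV missing columns: {sorted(missing)}")
    return TemperatureSeries.from_readings(df["timestamp"], df["temp_c"].astype(float))
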