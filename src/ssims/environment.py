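"""Daily temperature inputs for the field simulation.

A season is driven entirely by a sequence of daily mean temperatures. Real
series are read from CSV; when no observations are available a synthetic
Upper-Midwest climatology (sinusoidal annual cycle plus AR(1) daily noise)
stands in for the St. Paul, MN growing season.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "ClimatologyParams",
    "TemperatureFormatError",
    "read_temperature_csv",
    "synthesize_season",
]


class TemperatureFormatError(ValueError):
    """Malformed temperature CSV (bad value, duplicate or skipped day)."""


@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily mean temperatures (°C) for one window.

    ``dates`` are consecutive calendar days; ``tmean`` is aligned with them.
    """

    dates: tuple[dt.date, ...]
    tmean: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tmean, dtype=float)
        object.__setattr__(self, "tmean", t)
        if len(self.dates) != len(t):
            raise TemperatureFormatError("dates and temperatures differ in length")
        if len(self.dates) == 0:
            raise TemperatureFormatError("empty temperature series")
        for i in range(1, len(self.dates)):
            delta = (self.dates[i] - self.dates[i - 1]).days
            if delta != 1:
                raise TemperatureFormatError(
                    f"dates must increase by exactly one day; "
                    f"{self.dates[i - 1]} -> {self.dates[i]} (row {i + 1})"
                )

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]

    def slice(self, start: dt.date, end: dt.date) -> "TemperatureSeries":
        """Sub-series covering [start, end] inclusive; errors if not covered."""
        if start < self.start or end > self.end:
            raise ValueError(
                f"requested window {start}..{end} outside series "
                f"{self.start}..{self.end}"
            )
        i0 = (start - self.start).days
        i1 = (end - self.start).days + 1
        return TemperatureSeries(self.dates[i0:i1], self.tmean[i0:i1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": list(self.dates), "tmean": self.tmean})


@dataclass(frozen=True)
class ClimatologyParams:
    """Synthetic climatology: sinusoidal annual cycle plus AR(1) noise.

    Defaults give a March mean near 0 °C and a July mean near 23 °C, an
    Upper-Midwest-like season.
    """

    annual_mean: float = 8.0
    amplitude: float = 16.0
    peak_doy: int = 201  # day-of-year of July 20
    noise_sd: float = 3.0
    autocorr: float = 0.6

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not (abs(self.autocorr) < 1):
            raise ValueError(f"|autocorrelation| must be < 1, got {self.autocorr}")
        if self.noise_sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.noise_sd}")


def read_temperature_csv(path) -> TemperatureSeries:
    """Read a daily temperature CSV.

    Accepts either ``date,tmean`` or ``date,tmin,tmax`` (in which case the
    mean is ``(tmin + tmax) / 2``). Dates must be ISO-formatted, strictly
    consecutive days. Errors name the offending row (1-based, counting the
    header as row 1).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise TemperatureFormatError(f"cannot parse CSV {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "date" not in cols:
        raise TemperatureFormatError(f"{path}: missing 'date' column")
    if "tmean" in cols:
        raw = df["tmean"]
    elif "tmin" in cols and "tmax" in cols:
        raw = (
            pd.to_numeric(df["tmin"], errors="coerce")
            + pd.to_numeric(df["tmax"], errors="coerce")
        ) / 2.0
    else:
        raise TemperatureFormatError(
            f"{path}: need either a 'tmean' column or both 'tmin' and 'tmax'"
        )
    dates: list[dt.date] = []
    temps: list[float] = []
    for i, (d_raw, t_raw) in enumerate(zip(df["date"], raw)):
        row = i + 2  # header occupies row 1
        try:
            d = dt.date.fromisoformat(str(d_raw).strip())
        except ValueError as exc:
            raise TemperatureFormatError(f"{path} row {row}: bad date {d_raw!r}") from exc
        t = pd.to_numeric(t_raw, errors="coerce")
        if pd.isna(t):
            raise TemperatureFormatError(
                f"{path} row {row}: unparseable temperature {t_raw!r}"
            )
        if dates:
            delta = (d - dates[-1]).days
            if delta != 1:
                raise TemperatureFormatError(
                    f"{path} row {row}: expected {dates[-1] + dt.timedelta(days=1)}, "
                    f"got {d} (missing or duplicated day)"
                )
        dates.append(d)
        temps.append(float(t))
    if not dates:
        raise TemperatureFormatError(f"{path}: no data rows")
    return TemperatureSeries(tuple(dates), np.array(temps))


def synthesize_season(
    params: ClimatologyParams,
    start: dt.date,
    end: dt.date,
    seed: int | np.random.Generator,
) -> TemperatureSeries:
    """Generate a seeded synthetic daily series covering [start, end].

    The mean curve is ``annual_mean + amplitude * cos(2π (doy − peak_doy) /
    365.25)``; daily anomalies follow a stationary AR(1) process with the
    configured marginal s.d. and lag-1 autocorrelation.
    """
    if start >= end:
        raise ValueError(f"start {start} must precede end {end}")
    rng = np.random.default_rng(seed)
    n = (end - start).days + 1
    doy = np.array(
        [(start + dt.timedelta(days=i)).timetuple().tm_yday for i in range(n)],
        dtype=float,
    )
    mean_curve = params.annual_mean + params.amplitude * np.cos(
        2.0 * np.pi * (doy - params.peak_doy) / 365.25
    )
    # Stationary AR(1): innovations scaled so the marginal sd is noise_sd.
    rho = params.autocorr
    innov_sd = params.noise_sd * np.sqrt(1.0 - rho**2)
    noise = np.empty(n)
    z = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    for i in range(n):
        noise[i] = z
        z = rho * z + (rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0)
    dates = tuple(start + dt.timedelta(days=i) for i in range(n))
    return TemperatureSeries(dates, mean_curve + noise)
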