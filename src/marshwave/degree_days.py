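"""Growing degree days, climatologies, GDD jerk and spring onset.

Cumulative growing degree days (GDD) above a base temperature (default
10 C, the minimum temperature for *Spartina* growth) are computed with the
single sine method: one sine period is fitted to each day's (tmin, tmax)
and the portion of the curve above the base is integrated analytically
(the classical Baskerville-Emin interception cases).

The "GDD jerk" is the third time-derivative of the multi-year mean
cumulative-GDD curve; its spring peak (temperature acceleration maximum)
is a widely used proxy for the onset of spring.  The cumulative curve is
smoothed by a centred moving average before differencing because third
differences of raw climatologies are noise dominated; halfwidth and the
jerk discretisation are explicit, documented parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

from .synthetic import _nonleap_doy

DAYS = 365


@dataclass(frozen=True)
class GDDConfig:
    base_temp: float = 10.0
    smoothing_halfwidth: int = 7
    onset_window: tuple = (1, 181)

    def __post_init__(self):
        if not np.isfinite(self.base_temp):
            raise ValueError("base_temp must be finite")
        if self.smoothing_halfwidth < 0:
            raise ValueError("smoothing_halfwidth must be >= 0")
        lo, hi = self.onset_window
        if not (1 <= lo < hi <= DAYS):
            raise ValueError("onset_window must lie within [1, 365]")


@dataclass
class ClimatologySeries:
    """Per-day-of-year mean cumulative GDD for one station (365 values)."""

    cum_gdd: np.ndarray
    latitude: float = np.nan
    station_id: str = ""
    years_used: tuple = ()

    def __post_init__(self):
        self.cum_gdd = np.asarray(self.cum_gdd, dtype=float)
        if self.cum_gdd.shape != (DAYS,):
            raise ValueError("climatology must have 365 day-of-year values")


@dataclass(frozen=True)
class SpringOnset:
    doy: int
    jerk_value: float


def daily_gdd_single_sine(tmin, tmax, base: float = 10.0):
    """Single-sine daily growing degree days.

    Fits one sine period with mean (tmin+tmax)/2 and amplitude
    (tmax-tmin)/2 and returns the integral of (T - base) over the part of
    the day with T > base:

    * whole day above base: ``mean - base``
    * whole day below base: ``0``
    * intercepted: ``((mean-base)*(pi/2 - theta) + amp*cos(theta)) / pi``
      with ``theta = arcsin((base-mean)/amp)``.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(~np.isfinite(tmin)) or np.any(~np.isfinite(tmax)):
        raise ValueError("tmin/tmax must be finite")
    if np.any(tmax < tmin):
        raise ValueError("tmax must be >= tmin")
    scalar = np.isscalar(tmin) and np.isscalar(tmax) or (tmin.ndim == 0 and tmax.ndim == 0)
    tmin, tmax = np.atleast_1d(tmin), np.atleast_1d(tmax)
    mean = (tmin + tmax) / 2.0
    amp = (tmax - tmin) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arcsin(np.clip((base - mean) / np.where(amp > 0, amp, 1.0), -1.0, 1.0))
        intercepted = ((mean - base) * (np.pi / 2.0 - theta) + amp * np.cos(theta)) / np.pi
    out = np.where(tmin >= base, mean - base, np.where(tmax <= base, 0.0, intercepted))
    return float(out[0]) if scalar else out


def cumulative_gdd(records: pd.DataFrame, config: GDDConfig = GDDConfig(), start_doy: int = 1) -> pd.DataFrame:
    """Per-year cumulative GDD series from daily station records.

    ``records`` needs columns ``date, tmin_c, tmax_c`` with contiguous
    daily coverage per year; gaps of at most 3 consecutive days are filled
    by linear interpolation of tmin/tmax (with a warning), longer gaps
    raise.  Leap days are dropped (365-day years).  Returns a tidy frame
    ``year, doy, cum_gdd``; the running sum starts at ``start_doy``.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df[~((df["date"].dt.month == 2) & (df["date"].dt.day == 29))]
    df["year"] = df["date"].dt.year
    df["doy"] = _nonleap_doy(pd.DatetimeIndex(df["date"]))
    out = []
    for year, grp in df.groupby("year"):
        series = grp.set_index("doy")[["tmin_c", "tmax_c"]].reindex(np.arange(1, DAYS + 1))
        missing = series["tmin_c"].isna()
        if missing.any():
            runs = _missing_runs(missing.to_numpy())
            if any(n > 3 for _s, n in runs):
                raise ValueError(f"gap of more than 3 consecutive days in year {year}")
            warnings.warn(f"filled {int(missing.sum())} missing day(s) in year {year} by linear interpolation")
            series = series.interpolate(method="linear", limit_direction="both")
        daily = daily_gdd_single_sine(series["tmin_c"].to_numpy(), series["tmax_c"].to_numpy(), config.base_temp)
        daily[: start_doy - 1] = 0.0
        out.append(pd.DataFrame({"year": year, "doy": np.arange(1, DAYS + 1), "cum_gdd": np.cumsum(daily)}))
    return pd.concat(out, ignore_index=True)


def _missing_runs(mask: np.ndarray):
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def average_climatology(per_year: pd.DataFrame, years=None, latitude: float = np.nan,
                        station_id: str = "") -> ClimatologySeries:
    """Pointwise multi-year mean of per-year cumulative series."""
    df = per_year if years is None else per_year[per_year["year"].isin(list(years))]
    if df.empty:
        raise ValueError("no complete years in the requested subset")
    mean = df.groupby("doy")["cum_gdd"].mean()
    used = tuple(sorted(df["year"].unique()))
    return ClimatologySeries(cum_gdd=mean.reindex(np.arange(1, DAYS + 1)).to_numpy(),
                             latitude=latitude, station_id=station_id, years_used=used)


def gdd_jerk(clim, config: GDDConfig = GDDConfig()) -> np.ndarray:
    """Third central difference of the smoothed cumulative-GDD curve.

    The curve is smoothed by a centred moving average of halfwidth
    ``config.smoothing_halfwidth``, then differenced with the 5-point
    third central difference at unit (1-day) spacing.  The first and last
    ``3 + halfwidth`` days are returned as NaN (undefined).
    """
    x = clim.cum_gdd if isinstance(clim, ClimatologySeries) else np.asarray(clim, dtype=float)
    h = config.smoothing_halfwidth
    n = len(x)
    if n < 7 + 2 * h:
        raise ValueError("series too short for jerk computation")
    if h > 0:
        kernel = np.ones(2 * h + 1) / (2 * h + 1)
        s = np.convolve(x, kernel, mode="same")
    else:
        s = x.astype(float)
    jerk = np.full(n, np.nan)
    core = slice(2, n - 2)
    jerk[core] = (s[4:] - 2.0 * s[3:-1] + 2.0 * s[1:-3] - s[:-4]) / 2.0
    margin = 3 + h
    jerk[:margin] = np.nan
    jerk[n - margin:] = np.nan
    return jerk


def spring_onset(jerk: np.ndarray, config: GDDConfig = GDDConfig()) -> SpringOnset:
    """Day-of-year of the maximum jerk inside the onset window (ties -> earliest)."""
    lo, hi = config.onset_window
    window = np.asarray(jerk, dtype=float)[lo - 1: hi]
    if np.all(np.isnan(window)):
        raise ValueError("jerk undefined everywhere in the onset window")
    best = np.nanmax(window)
    idx = int(np.flatnonzero(window == best)[0])
    return SpringOnset(doy=lo + idx, jerk_value=float(best))


def onset_for_station(records: pd.DataFrame, config: GDDConfig = GDDConfig(), years=None,
                      latitude: float = np.nan, station_id: str = "") -> SpringOnset:
    """Convenience chain: records -> climatology -> jerk -> spring onset."""
    per_year = cumulative_gdd(records, config)
    clim = average_climatology(per_year, years=years, latitude=latitude, station_id=station_id)
    return spring_onset(gdd_jerk(clim, config), config)


def onset_shift(clims_a, clims_b, config: GDDConfig = GDDConfig()) -> dict:
    """Paired shift in spring-onset date between two climatology periods.

    ``clims_a`` and ``clims_b`` are same-station lists of
    :class:`ClimatologySeries` (e.g. a 30-year and a 10-year averaging
    period).  Returns the per-station differences (b - a), their mean, and
    the classical matched-pairs t statistic with its two-sided p value.
    """
    if len(clims_a) != len(clims_b):
        raise ValueError("climatology sets must pair the same stations")
    if len(clims_a) < 2:
        raise ValueError("at least 2 stations required for a paired test")
    diffs = np.array([
        spring_onset(gdd_jerk(b, config), config).doy - spring_onset(gdd_jerk(a, config), config).doy
        for a, b in zip(clims_a, clims_b)
    ], dtype=float)
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0:
        t = 0.0 if diffs.mean() == 0 else np.inf * np.sign(diffs.mean())
        p = 1.0 if diffs.mean() == 0 else 0.0
    else:
        t = diffs.mean() / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"mean_shift_days": float(diffs.mean()), "t": float(t), "p": float(p),
            "df": n - 1, "per_station": diffs.tolist()}
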