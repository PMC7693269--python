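"""Synthetic data generators with known ground truth.

Emulates the four input streams of the analysis so every downstream stage
can be tested end to end without external downloads:

* a latitude-graded sinusoidal coastal climate (daily tmin/tmax records),
* logistic seasonal salt-marsh (*Spartina alterniflora*) biomass studies
  whose green-up timing shifts with latitude,
* scripted annual-cycle geolocator tracks (light + conductivity), where
  migratory flights appear as extended dry bouts and incubation as daytime
  shading of the leg-mounted light sensor,
* seasonal ramps in citizen-science observation frequency by latitude bin.

Every generator is a pure function of its parameter block (each block
carries its own seed), and every scripted ground-truth quantity is emitted
alongside the data so recovery tests can compare against truth.

Calendar convention: dates are (year, day-of-year) with day-of-year
1-based; leap days are dropped so every year has 365 days.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import solar

#: reference latitude for latitude-graded parameters (New Jersey deployment site)
REF_LATITUDE = 39.2

DAY_LIGHT = 64.0
NIGHT_SUN_ELEVATION = -6.0  # sun elevation (deg) below which light is at night level
LIGHT_SLOPE = 8.0  # light units per degree of sun elevation above night


def _nonleap_dates(start_year: int, years: int) -> pd.DatetimeIndex:
    """Daily dates spanning ``years`` calendar years with Feb 29 removed."""
    idx = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D")
    return idx[~((idx.month == 2) & (idx.day == 29))]


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateParams:
    """Sinusoidal coastal climate with a linear latitudinal gradient.

    Daily mean temperature:
    ``tmean(d) = mean_annual_temp_at_ref - lat_gradient*(lat - ref_latitude)
    + seasonal_amplitude*cos(2*pi*(d - peak_day)/365) + N(0, noise_sd)``,
    with tmin/tmax = tmean -/+ diurnal_range/2.

    Defaults emulate the US Atlantic coast: ~12.5 C mean annual temperature
    at the New Jersey reference latitude, cooling ~0.9 C per degree
    northward, an 11 C seasonal half-range peaking around July 20.
    """

    mean_annual_temp_at_ref: float = 12.5
    lat_gradient: float = 0.9
    seasonal_amplitude: float = 11.0
    peak_day: int = 201
    diurnal_range: float = 8.0
    noise_sd: float = 2.0
    years: int = 10
    seed: int = 0
    ref_latitude: float = REF_LATITUDE
    start_year: int = 2001

    def __post_init__(self):
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")


def gen_climate(params: ClimateParams, latitude: float) -> pd.DataFrame:
    """Daily temperature records for one station.

    Returns a DataFrame with columns ``date, tmin_c, tmax_c`` (one row per
    calendar day per year, leap days dropped); reproducible under a fixed
    seed.
    """
    rng = np.random.default_rng(params.seed)
    dates = _nonleap_dates(params.start_year, params.years)
    doy = _nonleap_doy(dates)
    tmean = (
        params.mean_annual_temp_at_ref
        - params.lat_gradient * (latitude - params.ref_latitude)
        + params.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - params.peak_day) / 365.0)
    )
    if params.noise_sd > 0:
        tmean = tmean + rng.normal(0.0, params.noise_sd, size=len(dates))
    half = params.diurnal_range / 2.0
    return pd.DataFrame({"date": dates, "tmin_c": tmean - half, "tmax_c": tmean + half})


def _nonleap_doy(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on the 365-day calendar (leap days assumed removed)."""
    doy = dates.dayofyear.to_numpy().astype(float)
    leap = dates.is_leap_year
    doy[leap & (doy > 59)] -= 1  # re-number days after Feb 28 in leap years
    return doy


# ---------------------------------------------------------------------------
# biomass studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomassParams:
    """Multi-study logistic seasonal biomass with latitude-shifted timing.

    True standing biomass for a study at latitude ``lat`` rises
    logistically from an overwintering standing crop
    (``winter_biomass_frac`` of the seasonal maximum -- marshes retain
    standing dead and, southward, green shoots through winter) to the
    seasonal maximum:

    ``B(d) = max * (wf + (1 - wf) / (1 + exp(-rate*(d - midpoint(lat)))))``

    with ``midpoint(lat) = logistic_midpoint_at_ref +
    midpoint_lat_shift*(lat - ref_latitude)``.

    Reported means/SEs come from ``n_reps`` draws with multiplicative
    normal noise of sd ``cv * B(d)`` plus an additive plot-to-plot floor.
    Defaults emulate the eight *Spartina* productivity studies spanning
    Georgia to Nova Scotia (31.3-45.3 deg), sampled roughly monthly from
    late winter to early autumn.
    """

    n_studies: int = 8
    latitudes: tuple = (31.33, 32.0, 34.7, 37.3, 39.5, 41.9, 44.6, 45.3)
    logistic_midpoint_at_ref: float = 170.0
    midpoint_lat_shift: float = 4.0
    logistic_rate: float = 0.04
    seasonal_max: tuple = (1300.0, 1200.0, 900.0, 800.0, 700.0, 600.0, 450.0, 400.0)
    cv: float = 0.15
    noise_floor_frac: float = 0.02
    winter_biomass_frac: float = 0.15
    sampling_dates: tuple = tuple(range(46, 259, 21))
    n_reps: int = 15
    seed: int = 0
    ref_latitude: float = REF_LATITUDE

    def __post_init__(self):
        if self.logistic_rate <= 0:
            raise ValueError("logistic_rate must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if len(self.latitudes) != self.n_studies or len(self.seasonal_max) != self.n_studies:
            raise ValueError("latitudes and seasonal_max must have n_studies entries")
        for ds in self.per_study_dates():
            if len(ds) < 2:
                raise ValueError("each study needs at least 2 sampling dates")
            if np.any(np.diff(ds) <= 0):
                raise ValueError("sampling dates must be strictly increasing within a study")

    def per_study_dates(self):
        """Sampling day-of-year list per study.

        A shared flat tuple is shifted per study with latitude (field
        campaigns track the local season: a Georgia study starts sampling
        in midwinter, a Nova Scotia study in spring); explicit per-study
        lists are used as given.
        """
        if isinstance(self.sampling_dates[0], (tuple, list)):
            return [tuple(d) for d in self.sampling_dates]
        out = []
        for lat in self.latitudes:
            shift = int(round(self.midpoint_lat_shift * (lat - self.ref_latitude)))
            out.append(tuple(int(d) + shift for d in self.sampling_dates))
        return out

    def true_midpoint(self, latitude: float) -> float:
        return self.logistic_midpoint_at_ref + self.midpoint_lat_shift * (latitude - self.ref_latitude)

    def true_biomass(self, doy, latitude: float, study: int) -> np.ndarray:
        d = np.asarray(doy, dtype=float)
        m = self.true_midpoint(latitude)
        wf = self.winter_biomass_frac
        return self.seasonal_max[study] * (
            wf + (1.0 - wf) / (1.0 + np.exp(-self.logistic_rate * (d - m)))
        )

    def stage_date_offset(self, stage: float) -> float:
        """Days between the logistic midpoint and the day the true stage hits ``stage``."""
        wf = self.winter_biomass_frac
        f = (stage - wf) / (1.0 - wf)
        if not 0.0 < f < 1.0:
            raise ValueError("stage must lie between winter_biomass_frac and 1")
        return float(np.log(f / (1.0 - f)) / self.logistic_rate)

    def true_stage_date(self, stage: float, latitude: float) -> float:
        """Day-of-year at which the true stage fraction reaches ``stage``."""
        return self.true_midpoint(latitude) + self.stage_date_offset(stage)


def gen_biomass_studies(params: BiomassParams) -> pd.DataFrame:
    """Biomass observation records: ``study_id, latitude, doy, biomass_mean, biomass_se, n``."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for s, (lat, dates) in enumerate(zip(params.latitudes, params.per_study_dates())):
        for d in dates:
            b = float(params.true_biomass(d, lat, s))
            if params.cv > 0:
                # multiplicative sampling error plus an additive plot-to-plot
                # floor so near-zero early-season biomass is not reported with
                # implausibly tiny variance
                sd = params.cv * b + params.noise_floor_frac * params.seasonal_max[s]
                reps = b + rng.normal(0.0, sd, size=params.n_reps)
                mean = float(np.mean(reps))
                se = float(np.std(reps, ddof=1) / np.sqrt(params.n_reps))
            else:
                mean, se = b, 0.0
            rows.append(
                {"study_id": f"study_{s:02d}", "latitude": lat, "doy": int(d),
                 "biomass_mean": mean, "biomass_se": se, "n": params.n_reps}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geolocator tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackScript:
    """Scripted annual cycle for one individual (the ground truth).

    Event dates are day-of-year in ``year``; they must be strictly ordered
    spring_departure < breeding_arrival < nest_initiation < fall_departure
    < winter_arrival.  ``flight_legs`` is a list of ``(start, duration_h)``
    with ``numpy.datetime64`` starts; ``northbound_waypoints`` /
    ``southbound_waypoints`` give the (lat, lon) route endpoints for the
    legs of each migration (len = n_legs + 1).  Use
    :func:`make_annual_script` to build a consistent script from event
    dates alone.
    """

    individual_id: str
    site_latitude: float
    site_longitude: float
    spring_departure: int
    breeding_arrival: int
    nest_initiation: int
    fall_departure: int
    winter_arrival: int
    winter_latitude: float = -2.6
    winter_longitude: float = -44.3
    year: int = 2011
    incubation_days: int = 26
    incubation_bouts: tuple = ()  # ((doy, start_hour_local, duration_h), ...)
    flight_legs: tuple = ()  # ((datetime64, hours), ...)
    northbound_waypoints: tuple = ()
    southbound_waypoints: tuple = ()
    sampling_interval_min: int = 10
    seed: int = 0

    def __post_init__(self):
        ev = [self.spring_departure, self.breeding_arrival, self.nest_initiation,
              self.fall_departure, self.winter_arrival]
        if any(np.diff(ev) <= 0):
            raise ValueError("event dates must be strictly ordered within the annual cycle")
        legs = sorted(self.flight_legs, key=lambda x: x[0])
        for (t0, h0), (t1, _h1) in zip(legs, legs[1:]):
            if np.datetime64(t0) + np.timedelta64(int(h0 * 3600), "s") > np.datetime64(t1):
                raise ValueError("overlapping flight legs")
        for _t, h in legs:
            if h <= 0:
                raise ValueError("flight durations must be > 0")

    def truth(self) -> dict:
        """Ground-truth event table for recovery tests."""
        return {
            "individual_id": self.individual_id,
            "spring_departure": self.spring_departure,
            "breeding_arrival": self.breeding_arrival,
            "nest_initiation": self.nest_initiation,
            "fall_departure": self.fall_departure,
            "winter_arrival": self.winter_arrival,
            "flight_hours": [float(h) for _t, h in self.flight_legs],
        }


def _doy_to_ts(year: int, doy: float) -> np.datetime64:
    return np.datetime64(f"{year:04d}-01-01", "s") + np.timedelta64(int(round((doy - 1) * 86400)), "s")


def make_annual_script(
    individual_id: str,
    site_latitude: float,
    site_longitude: float,
    spring_departure: int,
    breeding_arrival: int,
    nest_initiation: int,
    fall_departure: int,
    winter_arrival: int,
    *,
    year: int = 2011,
    seed: int = 0,
    sampling_interval_min: int = 10,
    winter_latitude: float = -2.6,
    winter_longitude: float = -44.3,
    north_stopover: tuple = (31.0, -81.1),
    south_stopover: tuple = (5.9, -55.1),
    transoceanic_hours: float = 96.0,
) -> TrackScript:
    """Build a consistent :class:`TrackScript` from annual-cycle event dates.

    Northbound migration is a transoceanic leg departing on
    ``spring_departure`` to a southeastern-US stopover, then a short coastal
    leg ending on ``breeding_arrival``.  Southbound mirrors this via a South
    American stopover.  Daily incubation bouts (2-3 shading bouts of 1.5-3.5 h
    between 09:00 and 15:30 local) run from ``nest_initiation`` for
    ``incubation_days`` days.
    """
    rng = np.random.default_rng(seed)
    # northbound: long leg at departure, short leg ending the morning of arrival
    nb1_start = _doy_to_ts(year, spring_departure) + np.timedelta64(23 * 3600, "s")
    nb1_hours = transoceanic_hours * 0.85
    nb2_hours = 26.0
    nb2_start = _doy_to_ts(year, breeding_arrival) + np.timedelta64(12 * 3600, "s") - np.timedelta64(
        int(nb2_hours * 3600), "s"
    )
    sb1_start = _doy_to_ts(year, fall_departure) + np.timedelta64(23 * 3600, "s")
    sb1_hours = transoceanic_hours
    sb2_hours = 26.0
    sb2_start = _doy_to_ts(year, winter_arrival) + np.timedelta64(9 * 3600, "s") - np.timedelta64(
        int(sb2_hours * 3600), "s"
    )
    legs = ((nb1_start, nb1_hours), (nb2_start, nb2_hours), (sb1_start, sb1_hours), (sb2_start, sb2_hours))
    incubation_days = 26
    bouts = []
    for d in range(nest_initiation, min(nest_initiation + incubation_days, fall_departure)):
        # every nesting day carries at least one mid-day shading bout
        s = float(rng.uniform(9.0, 12.0))
        dur = float(rng.uniform(1.5, 3.0))
        bouts.append((d, s, dur))
        prev_end = s + dur
        for _ in range(int(rng.integers(0, 2))):
            lo = prev_end + 0.3
            if lo >= 15.5:
                break
            s2 = float(rng.uniform(lo, 15.5))
            dur2 = float(min(rng.uniform(1.5, 3.0), 17.5 - s2))
            if dur2 < 1.2:
                break
            bouts.append((d, s2, dur2))
            prev_end = s2 + dur2
    return TrackScript(
        individual_id=individual_id,
        site_latitude=site_latitude,
        site_longitude=site_longitude,
        spring_departure=spring_departure,
        breeding_arrival=breeding_arrival,
        nest_initiation=nest_initiation,
        fall_departure=fall_departure,
        winter_arrival=winter_arrival,
        winter_latitude=winter_latitude,
        winter_longitude=winter_longitude,
        year=year,
        incubation_days=incubation_days,
        incubation_bouts=tuple(bouts),
        flight_legs=legs,
        northbound_waypoints=((winter_latitude, winter_longitude), north_stopover,
                              (site_latitude, site_longitude)),
        southbound_waypoints=((site_latitude, site_longitude), south_stopover,
                              (winter_latitude, winter_longitude)),
        sampling_interval_min=sampling_interval_min,
        seed=seed,
    )


def _position_timeline(script: TrackScript, times: np.ndarray):
    """Per-sample (lat, lon) along the scripted annual cycle."""
    lat = np.full(times.shape, np.nan)
    lon = np.full(times.shape, np.nan)
    legs = sorted(script.flight_legs, key=lambda x: np.datetime64(x[0]))
    n_nb = max(len(script.northbound_waypoints) - 1, 0)
    waypoints = list(script.northbound_waypoints) or [
        (script.winter_latitude, script.winter_longitude),
        (script.site_latitude, script.site_longitude),
    ]
    waypoints = waypoints + list(script.southbound_waypoints[1:]) if script.southbound_waypoints else waypoints
    # stationary position before each leg; legs walk through the waypoint chain
    if not legs:
        lat[:], lon[:] = script.site_latitude, script.site_longitude
        return lat, lon
    chain = waypoints
    pos_idx = 0
    cursor = chain[0]
    t0 = times[0]
    for i, (start, hours) in enumerate(legs):
        start = np.datetime64(start, "s")
        end = start + np.timedelta64(int(hours * 3600), "s")
        dest = chain[min(pos_idx + 1, len(chain) - 1)]
        sel_stat = (times >= t0) & (times < start)
        lat[sel_stat], lon[sel_stat] = cursor
        sel_fly = (times >= start) & (times < end)
        if sel_fly.any():
            frac = (times[sel_fly] - start).astype("timedelta64[s]").astype(float) / (
                (end - start).astype("timedelta64[s]").astype(float)
            )
            glat, glon = solar.great_circle_point(cursor[0], cursor[1], dest[0], dest[1], frac)
            lat[sel_fly], lon[sel_fly] = glat, glon
        cursor = dest
        pos_idx += 1
        t0 = end
    sel = times >= t0
    lat[sel], lon[sel] = cursor
    return lat, lon


def gen_geolocator_track(script: TrackScript):
    """Render a scripted track into light and conductivity series.

    Returns ``(light, conductivity, truth)`` where ``light`` has columns
    ``timestamp, light``; ``conductivity`` has ``timestamp, wet`` (1 = wet);
    and ``truth`` is the scripted event table.

    Light follows the solar day/night template at the scripted position
    (clipped-linear in sun elevation above -6 deg), forced to night level
    during scripted incubation bouts.  Conductivity shows Bernoulli wet-dry
    texture at stationary sites (wet with probability 0.8 during daylight,
    0.5 at night) and is continuously dry during flight legs.
    """
    rng = np.random.default_rng(script.seed)
    dt = np.timedelta64(script.sampling_interval_min * 60, "s")
    t0 = np.datetime64(f"{script.year:04d}-01-01T00:00:00", "s")
    t1 = np.datetime64(f"{script.year:04d}-12-31T23:59:59", "s")
    times = np.arange(t0, t1, dt)
    lat, lon = _position_timeline(script, times)
    elev = solar.solar_elevation(lat, lon, times)
    light = np.clip(LIGHT_SLOPE * (elev - NIGHT_SUN_ELEVATION), 0.0, DAY_LIGHT)

    # incubation: leg-mounted sensor shaded while the bird sits on the nest
    if script.incubation_bouts:
        days = times.astype("datetime64[D]")
        doy_arr = (days - times.astype("datetime64[Y]")).astype("timedelta64[D]").astype(int) + 1
        local_hour = (times - days).astype("timedelta64[s]").astype(float) / 3600.0 + script.site_longitude / 15.0
        for d, s, dur in script.incubation_bouts:
            m = (doy_arr == d) & (local_hour >= s) & (local_hour < s + dur)
            light[m] = 0.0

    # waders stand/roost in water: wet dominates both day and night; keeping
    # the dry probability low also keeps texture-driven extension of flight
    # dry-runs well under one sampling interval on average
    daylight = elev > NIGHT_SUN_ELEVATION
    p_wet = np.where(daylight, 0.8, 0.75)
    wet = (rng.random(times.shape) < p_wet).astype(int)
    for start, hours in script.flight_legs:
        start = np.datetime64(start, "s")
        end = start + np.timedelta64(int(hours * 3600), "s")
        wet[(times >= start) & (times < end)] = 0

    light_df = pd.DataFrame({"timestamp": times, "light": light})
    cond_df = pd.DataFrame({"timestamp": times, "wet": wet})
    return light_df, cond_df, script.truth()


def save_track(light: pd.DataFrame, cond: pd.DataFrame, truth: dict, outdir, stem: str):
    """Write a generated track as CSV pair + JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    light.to_csv(outdir / f"{stem}_light.csv", index=False)
    cond.to_csv(outdir / f"{stem}_conductivity.csv", index=False)
    (outdir / f"{stem}_truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# observation-frequency ramps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationRampParams:
    """Seasonal arrival ramps in checklist reporting frequency by latitude bin.

    The expected reporting proportion follows a logistic ramp whose
    midpoint is positioned so the cumulative-2% day of the noise-free curve
    over ``season_window`` equals ``true_arrival_doy`` for each bin; daily
    counts are Poisson around ``daily_effort * proportion``.  Defaults
    emulate a decade of two-degree-bin checklist frequencies.
    """

    latitude_bins: tuple = (32.5, 34.5, 36.5, 38.5, 40.5, 42.5, 44.5)
    true_arrival_doy: tuple = (89, 95, 100, 105, 111, 116, 122)
    ramp_steepness: float = 0.25
    season_window: tuple = (32, 181)
    daily_effort: float = 40.0
    peak_frequency: float = 0.6
    n_years: int = 10
    arrival_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.true_arrival_doy) != len(self.latitude_bins):
            raise ValueError("true_arrival_doy must match latitude_bins")
        if self.daily_effort <= 0:
            raise ValueError("daily_effort must be > 0")
        lo, hi = self.season_window
        for a in self.true_arrival_doy:
            if not lo < a < hi:
                raise ValueError("arrival dates must lie inside the season window")
        if (hi - lo) < 8.0 / self.ramp_steepness:
            raise ValueError("season window shorter than the ramp support")


def _ramp_midpoint(params: ObservationRampParams, arrival: float) -> float:
    """Solve for the logistic midpoint placing the noise-free cumulative-2% day at ``arrival``."""
    from scipy.optimize import brentq

    lo, hi = params.season_window
    days = np.arange(lo, hi + 1, dtype=float)

    def crossing(m):
        p = params.peak_frequency / (1.0 + np.exp(-params.ramp_steepness * (days - m)))
        c = np.cumsum(p)
        target = params.arrival_fraction * c[-1]
        i = int(np.searchsorted(c, target))
        if i == 0:
            return days[0] - 0.5
        # linear interpolation of the continuous crossing between days
        f = (target - c[i - 1]) / (c[i] - c[i - 1])
        return days[i - 1] + f

    f = lambda m: crossing(m) - arrival
    a, b = lo - 50.0, hi + 50.0
    if f(a) * f(b) > 0:
        raise ValueError("season window too short to place the requested arrival day")
    return brentq(f, a, b, xtol=1e-8)


def gen_observation_records(params: ObservationRampParams) -> pd.DataFrame:
    """Daily observation counts: ``year, doy, bin_latitude, n_reporting``."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.season_window
    days = np.arange(lo, hi + 1)
    frames = []
    for lat, arrival in zip(params.latitude_bins, params.true_arrival_doy):
        m = _ramp_midpoint(params, float(arrival))
        p = params.peak_frequency / (1.0 + np.exp(-params.ramp_steepness * (days - m)))
        lam = params.daily_effort * p
        for year in range(params.n_years):
            counts = rng.poisson(lam)
            frames.append(pd.DataFrame({
                "year": year + 1, "doy": days, "bin_latitude": lat, "n_reporting": counts,
            }))
    return pd.concat(frames, ignore_index=True)
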