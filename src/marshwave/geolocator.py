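"""Light-level geolocator event detection.

Turns raw light and conductivity (wet/dry) series from leg-mounted tags
into twilight times, simple threshold positions, sustained flight
intervals, incubation bouts, and a per-individual annual-cycle event
table.

Method summary:

* twilights are threshold crossings of the light series (linearly
  interpolated between samples), cleaned by the classical outlier rule
  (remove a twilight deviating > 35 min from the median of same-kind
  twilights within +-2 days);
* positions use simple threshold geolocation: longitude from
  equation-of-time-corrected local solar noon, latitude from day length
  via the sunrise equation, with latitude flagged undefined near the
  equinoxes (day length ~12 h) and inside a +-40 d equinox mask;
* migratory flights are maximal runs of consecutive dry conductivity
  samples lasting at least ``min_dry_hours`` (default 20 h) -- sedentary
  wet-dry texture never produces multi-hour dry runs, whereas
  transoceanic flights last days;
* incubation is detected as dark periods during daylight hours (the
  sitting bird shades the leg sensor); nest initiation is the first day
  opening a run of >= 3 consecutive days with at least one bout, which
  guards against one-off shading artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import solar

EQUINOX_DOYS = (79, 265)  # Mar 20 and Sep 22 on the 365-day calendar


@dataclass(frozen=True)
class PositionEstimate:
    timestamp: np.datetime64
    longitude: float
    latitude: float  # NaN when undefined (near-equinox or no solution)
    zenith_used: float


@dataclass
class AnnualCycleEvents:
    """Per-individual annual-cycle event table (day-of-year) with derived durations."""

    individual_id: str
    site: str
    spring_departure: float | None = None
    breeding_arrival: float | None = None
    nest_initiation: float | None = None
    fall_departure: float | None = None
    winter_arrival: float | None = None

    def durations(self) -> dict:
        """Durations as exact differences of their bounding events (None if a bound is missing)."""

        def diff(a, b):
            return None if a is None or b is None else b - a

        wint = None
        if self.winter_arrival is not None and self.spring_departure is not None:
            wint = self.spring_departure + 365 - self.winter_arrival
        return {
            "spring_migration_days": diff(self.spring_departure, self.breeding_arrival),
            "pre_nesting_days": diff(self.breeding_arrival, self.nest_initiation),
            "nesting_period_days": diff(self.nest_initiation, self.fall_departure),
            "fall_migration_days": diff(self.fall_departure, self.winter_arrival),
            "wintering_days": wint,
        }

    def to_dict(self) -> dict:
        d = {"individual_id": self.individual_id, "site": self.site,
             "spring_departure": self.spring_departure, "breeding_arrival": self.breeding_arrival,
             "nest_initiation": self.nest_initiation, "fall_departure": self.fall_departure,
             "winter_arrival": self.winter_arrival}
        d.update(self.durations())
        return d


def _doy(ts) -> int:
    """1-based day-of-year on the 365-day calendar."""
    t = np.datetime64(ts, "s")
    day = t.astype("datetime64[D]")
    year = t.astype("datetime64[Y]")
    doy = int((day - year).astype("timedelta64[D]").astype(int)) + 1
    yr = year.astype(int) + 1970
    leap = (yr % 4 == 0 and yr % 100 != 0) or yr % 400 == 0
    if leap and doy > 59:
        doy -= 1
    return doy


# ---------------------------------------------------------------------------
# twilights
# ---------------------------------------------------------------------------

def detect_twilights(light: pd.DataFrame, light_threshold: float = 1.0) -> pd.DataFrame:
    """Twilight events from threshold crossings of a regularly sampled light series.

    Returns a DataFrame with columns ``timestamp, kind, edited`` where
    ``kind`` is ``rise`` (upward crossing) or ``set`` (downward crossing);
    crossing times are linearly interpolated between samples.  A constant
    series yields an empty table with a warning.
    """
    t = light["timestamp"].to_numpy(dtype="datetime64[s]")
    y = light["light"].to_numpy(dtype=float)
    below = y < light_threshold
    up = below[:-1] & ~below[1:]
    down = ~below[:-1] & below[1:]
    if not up.any() and not down.any():
        warnings.warn("light series never crosses the threshold; no twilights detected")
        return pd.DataFrame(columns=["timestamp", "kind", "edited"])
    rows = []
    dt = (t[1:] - t[:-1]).astype("timedelta64[s]").astype(float)
    for idx, kind in ((np.flatnonzero(up), "rise"), (np.flatnonzero(down), "set")):
        for i in idx:
            frac = (light_threshold - y[i]) / (y[i + 1] - y[i])
            ts = t[i] + np.timedelta64(int(round(frac * dt[i])), "s")
            rows.append((ts, kind))
    out = pd.DataFrame(rows, columns=["timestamp", "kind"]).sort_values("timestamp", ignore_index=True)
    out["edited"] = "kept"
    return out


def filter_twilight_outliers(twilights: pd.DataFrame, max_deviation_min: float = 35.0,
                             neighbor_span_days: float = 2.0) -> pd.DataFrame:
    """Flag twilights deviating > ``max_deviation_min`` from their neighbours.

    Each event's clock time is compared against the median clock time of
    same-kind events within +-``neighbor_span_days``; events beyond the
    deviation limit are flagged ``removed`` in the ``edited`` column
    (single pass against the original set).  Empty input passes through.
    """
    tw = twilights.copy()
    if tw.empty:
        return tw
    t = tw["timestamp"].to_numpy(dtype="datetime64[s]")
    days = t.astype("datetime64[D]").astype(float)
    minutes = (t - t.astype("datetime64[D]")).astype("timedelta64[s]").astype(float) / 60.0
    kinds = tw["kind"].to_numpy()
    edited = np.array(["kept"] * len(tw), dtype=object)
    for i in range(len(tw)):
        same = (kinds == kinds[i]) & (np.abs(days - days[i]) <= neighbor_span_days)
        same[i] = False
        if not same.any():
            continue
        # compare on a circular clock, unwrapped around this event's time
        delta = (minutes[same] - minutes[i] + 720.0) % 1440.0 - 720.0
        if np.abs(np.median(delta)) > max_deviation_min:
            edited[i] = "removed"
    tw["edited"] = edited
    return tw


def kept(twilights: pd.DataFrame) -> pd.DataFrame:
    """Subset of twilights not flagged as removed."""
    if twilights.empty or "edited" not in twilights:
        return twilights
    return twilights[twilights["edited"] == "kept"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# positions
# ---------------------------------------------------------------------------

def threshold_position(rise, sset, zenith: float = solar.CIVIL_ZENITH,
                       daylength_tol_hours: float = 0.25) -> PositionEstimate:
    """Simple threshold geolocation from one rise/set pair.

    Longitude comes from local solar noon (midpoint of rise and set,
    equation-of-time corrected): ``lon = (720 - noon_utc_minutes - eqtime)/4``.
    Latitude solves the sunrise equation for the observed day length at the
    given zenith; it is returned as NaN when day length is within
    ``daylength_tol_hours`` of 12 h (equinox-degenerate) or no solution
    exists.
    """
    rise = np.datetime64(rise, "s")
    sset = np.datetime64(sset, "s")
    if sset <= rise:
        raise ValueError("sunset must follow sunrise")
    if (sset - rise) > np.timedelta64(24 * 3600, "s"):
        raise ValueError("rise/set pair must span less than 24 h")
    noon = rise + (sset - rise) // 2
    doy_f, hour = solar._doy_hour(noon)
    gamma = solar.fractional_year(doy_f, hour)
    eqt = float(solar.equation_of_time(gamma))
    dec = float(solar.solar_declination(gamma))
    minutes = float(hour) * 60.0
    lon = (720.0 - minutes - eqt) / 4.0
    lon = (lon + 180.0) % 360.0 - 180.0
    if lon == -180.0:
        lon = 180.0
    daylength = (sset - rise).astype("timedelta64[s]").astype(float) / 3600.0
    lat = np.nan
    if abs(daylength - 12.0) >= daylength_tol_hours:
        cos_z = np.cos(np.deg2rad(zenith))
        omega = np.deg2rad(daylength * 15.0 / 2.0)

        def f(phi_deg):
            phi = np.deg2rad(phi_deg)
            return np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(omega) - cos_z

        lo, hi = -89.5, 89.5
        if f(lo) * f(hi) < 0:
            lat = brentq(f, lo, hi, xtol=1e-6)
    return PositionEstimate(timestamp=noon, longitude=float(lon), latitude=float(lat), zenith_used=zenith)


def positions_from_twilights(twilights: pd.DataFrame, zenith: float = solar.CIVIL_ZENITH,
                             max_pair_hours: float = 20.0) -> pd.DataFrame:
    """Position per consecutive kept rise->set pair.

    Returns ``timestamp, longitude, latitude, zenith_used``.  Pairs whose
    day length would exceed ``max_pair_hours`` are skipped (they bridge a
    data gap, not a day).
    """
    tw = kept(twilights).sort_values("timestamp")
    rows = []
    recs = list(tw.itertuples(index=False))
    for a, b in zip(recs, recs[1:]):
        if a.kind == "rise" and b.kind == "set":
            dt_h = (np.datetime64(b.timestamp, "s") - np.datetime64(a.timestamp, "s")).astype(
                "timedelta64[s]").astype(float) / 3600.0
            if 0 < dt_h <= max_pair_hours:
                p = threshold_position(a.timestamp, b.timestamp, zenith=zenith)
                rows.append((p.timestamp, p.longitude, p.latitude, p.zenith_used))
    return pd.DataFrame(rows, columns=["timestamp", "longitude", "latitude", "zenith_used"])


def mask_equinox(positions: pd.DataFrame, half_window_days: int = 40) -> pd.DataFrame:
    """Suppress latitude within +-``half_window_days`` of each equinox; longitude is kept."""
    pos = positions.copy()
    if pos.empty:
        return pos
    doys = np.array([_doy(ts) for ts in pos["timestamp"]])
    masked = np.zeros(len(pos), dtype=bool)
    for eq in EQUINOX_DOYS:
        circ = np.minimum(np.abs(doys - eq), 365 - np.abs(doys - eq))
        masked |= circ <= half_window_days
    pos.loc[masked, "latitude"] = np.nan
    return pos


# ---------------------------------------------------------------------------
# conductivity / flights
# ---------------------------------------------------------------------------

def classify_flights(conductivity: pd.DataFrame, min_dry_hours: float = 20.0) -> pd.DataFrame:
    """Sustained-flight intervals from wet/dry conductivity.

    Maximal runs of consecutive dry samples lasting at least
    ``min_dry_hours`` are returned as flights (``start, end,
    duration_hours``); the run boundary is the first dry sample to the
    sample after the last dry one.
    """
    t = conductivity["timestamp"].to_numpy(dtype="datetime64[s]")
    wet = conductivity["wet"].to_numpy().astype(int)
    if len(t) < 2:
        return pd.DataFrame(columns=["start", "end", "duration_hours"])
    dt = np.median((t[1:] - t[:-1]).astype("timedelta64[s]").astype(float))
    dry = wet == 0
    edges = np.diff(dry.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if dry[0]:
        starts = [0] + starts
    if dry[-1]:
        ends = ends + [len(dry)]
    rows = []
    for s, e in zip(starts, ends):
        start = t[s]
        end = t[e - 1] + np.timedelta64(int(dt), "s")
        hours = (end - start).astype("timedelta64[s]").astype(float) / 3600.0
        if hours >= min_dry_hours:
            rows.append((start, end, hours))
    return pd.DataFrame(rows, columns=["start", "end", "duration_hours"])


# ---------------------------------------------------------------------------
# incubation
# ---------------------------------------------------------------------------

def detect_incubation(light: pd.DataFrame, twilights: pd.DataFrame, light_threshold: float = 1.0,
                      min_bout_hours: float = 1.0, persistence_days: int = 3):
    """Incubation bouts (daytime darkness) and the nest-initiation day.

    A bout is a run of below-threshold light lasting at least
    ``min_bout_hours`` strictly between the day's first rise and last set.
    Nest initiation is the first day-of-year opening a run of
    ``persistence_days`` consecutive days that each contain a bout.
    Returns ``(bouts, nest_initiation_doy_or_None)``.
    """
    # Use the full (unfiltered) twilight sequence: the outlier rule serves
    # positioning and strips shading-induced crossings, but those crossings
    # carry exactly the daylight structure needed here.
    tw = twilights
    if tw.empty:
        raise ValueError("no daylight definition available (no twilights)")
    t = light["timestamp"].to_numpy(dtype="datetime64[s]")
    y = light["light"].to_numpy(dtype=float)

    # Daylight spans must not hinge on the UTC calendar date (sunset can fall
    # past UTC midnight): split the twilight sequence at "true nights" --
    # set->rise gaps of several hours -- and take the first rise to the last
    # set of each solar day.  Short daytime set/rise pairs (shading bouts)
    # then stay inside the span instead of terminating it.
    ts = tw["timestamp"].to_numpy(dtype="datetime64[s]")
    kinds = tw["kind"].to_numpy()
    min_night_hours = 4.0
    spans = []
    cur_rise, cur_set = None, None
    for i in range(len(ts)):
        if kinds[i] == "rise":
            is_dawn = cur_set is None or (
                (ts[i] - cur_set).astype("timedelta64[s]").astype(float) / 3600.0 >= min_night_hours
            )
            if is_dawn:
                if cur_rise is not None and cur_set is not None and cur_set > cur_rise:
                    spans.append((cur_rise, cur_set))
                cur_rise, cur_set = ts[i], None
        else:
            cur_set = ts[i]
    if cur_rise is not None and cur_set is not None and cur_set > cur_rise:
        spans.append((cur_rise, cur_set))
    if not spans:
        raise ValueError("no daylight definition available (degenerate twilights)")

    dark = y < light_threshold
    edges = np.diff(dark.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if dark[0]:
        starts = [0] + starts
    if dark[-1]:
        ends = ends + [len(dark)]
    span_starts = np.array([s[0] for s in spans])
    span_ends = np.array([s[1] for s in spans])
    rows = []
    for s, e in zip(starts, ends):
        t0, t1 = t[s], t[e - 1]
        j = int(np.searchsorted(span_starts, t0, side="right")) - 1
        if j < 0:
            continue
        if t0 > span_starts[j] and t1 < span_ends[j]:
            hours = (t1 - t0).astype("timedelta64[s]").astype(float) / 3600.0
            if hours >= min_bout_hours:
                rows.append((t0, t1, _doy(span_starts[j])))
    bouts = pd.DataFrame(rows, columns=["start", "end", "doy"])
    nest = None
    if not bouts.empty:
        days = np.array(sorted(bouts["doy"].unique()))
        for d in days:
            if all(d + k in days for k in range(persistence_days)):
                nest = int(d)
                break
    return bouts, nest


# ---------------------------------------------------------------------------
# event table
# ---------------------------------------------------------------------------

def _median_longitude(positions: pd.DataFrame, t0, t1) -> float:
    sel = (positions["timestamp"] >= t0) & (positions["timestamp"] <= t1)
    vals = positions.loc[sel, "longitude"].to_numpy()
    return float(np.median(vals)) if len(vals) else np.nan


def build_event_table(flights: pd.DataFrame, positions: pd.DataFrame, site_latitude: float,
                      site_longitude: float, individual_id: str = "", site: str = "",
                      nest_initiation=None, group_gap_days: float = 30.0,
                      window_days: float = 6.0, toward_threshold_deg: float = 5.0) -> AnnualCycleEvents:
    """Assemble the per-individual annual-cycle event table.

    Flights separated by less than ``group_gap_days`` (stopovers) are
    grouped into one migration.  A migration is classified northbound or
    southbound by whether the median longitude in the ``window_days``
    window after its last flight moved toward or away from the deployment
    site, relative to the window before its first flight.  Missing phases
    leave the corresponding fields ``None``.
    """
    ev = AnnualCycleEvents(individual_id=individual_id, site=site, nest_initiation=nest_initiation)
    if flights.empty:
        return ev
    fl = flights.sort_values("start").reset_index(drop=True)
    groups = []
    current = [0]
    for i in range(1, len(fl)):
        gap_days = (np.datetime64(fl["start"][i], "s") - np.datetime64(fl["end"][i - 1], "s")).astype(
            "timedelta64[s]").astype(float) / 86400.0
        if gap_days < group_gap_days:
            current.append(i)
        else:
            groups.append(current)
            current = [i]
    groups.append(current)

    window = np.timedelta64(int(window_days * 86400), "s")
    for grp in groups:
        g_start = np.datetime64(fl["start"][grp[0]], "s")
        g_end = np.datetime64(fl["end"][grp[-1]], "s")
        lon_before = _median_longitude(positions, g_start - window, g_start)
        lon_after = _median_longitude(positions, g_end, g_end + window)
        if np.isnan(lon_before) or np.isnan(lon_after):
            continue
        d_before = abs((lon_before - site_longitude + 180.0) % 360.0 - 180.0)
        d_after = abs((lon_after - site_longitude + 180.0) % 360.0 - 180.0)
        if d_after < d_before - toward_threshold_deg:
            if ev.spring_departure is None:
                ev.spring_departure = _doy(g_start)
                ev.breeding_arrival = _doy(g_end)
        elif d_after > d_before + toward_threshold_deg:
            if ev.fall_departure is None:
                ev.fall_departure = _doy(g_start)
                ev.winter_arrival = _doy(g_end)
    return ev


def analyze_track(light: pd.DataFrame, conductivity: pd.DataFrame, site_latitude: float,
                  site_longitude: float, individual_id: str = "", site: str = "",
                  light_threshold: float = 1.0, zenith: float = solar.CIVIL_ZENITH,
                  min_dry_hours: float = 20.0) -> AnnualCycleEvents:
    """Full per-track chain: twilights -> positions -> flights/incubation -> event table."""
    tw = filter_twilight_outliers(detect_twilights(light, light_threshold))
    positions = mask_equinox(positions_from_twilights(tw, zenith=zenith))
    flights = classify_flights(conductivity, min_dry_hours=min_dry_hours)
    try:
        _bouts, nest = detect_incubation(light, tw, light_threshold=light_threshold)
    except ValueError:
        nest = None
    return build_event_table(flights, positions, site_latitude, site_longitude,
                             individual_id=individual_id, site=site, nest_initiation=nest)
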