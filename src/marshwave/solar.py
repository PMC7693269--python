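"""NOAA-style solar position arithmetic.

Implements the standard low-precision solar ephemeris (fractional-year
expansion of declination and the equation of time) used throughout the
package: the synthetic geolocator generator renders light from the solar
elevation at the tag's position, and threshold geolocation inverts the same
geometry (solar noon -> longitude, day length -> latitude via the sunrise
equation).

Accuracy is a few tenths of a degree in elevation and ~1 min in event
times, which is far below the noise floor of threshold geolocation.
Atmospheric refraction is not modelled; "twilight" is defined purely by a
geometric zenith angle (96 deg = civil twilight, sun 6 deg below horizon).

All times are UTC. A 365-day year is assumed (leap days are dropped
elsewhere in the package), which keeps the fractional-year angle consistent
with the day-of-year convention used for climatologies.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365.0

#: geometric zenith angle (degrees) for civil twilight: sun 6 deg below horizon
CIVIL_ZENITH = 96.0


def fractional_year(doy, hour):
    """Fractional-year angle (radians) for day-of-year ``doy`` (1-based) and UTC ``hour``."""
    doy = np.asarray(doy, dtype=float)
    hour = np.asarray(hour, dtype=float)
    return 2.0 * np.pi / DAYS_PER_YEAR * (doy - 1.0 + (hour - 12.0) / 24.0)


def equation_of_time(gamma):
    """Equation of time (minutes) at fractional-year angle ``gamma``."""
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2.0 * gamma)
        - 0.040849 * np.sin(2.0 * gamma)
    )


def solar_declination(gamma):
    """Solar declination (radians) at fractional-year angle ``gamma``."""
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2.0 * gamma)
        + 0.000907 * np.sin(2.0 * gamma)
        - 0.002697 * np.cos(3.0 * gamma)
        + 0.00148 * np.sin(3.0 * gamma)
    )


def _doy_hour(times):
    """Split UTC timestamps into (day-of-year, fractional hour) arrays."""
    t = np.asarray(times, dtype="datetime64[s]")
    days = t.astype("datetime64[D]")
    years = t.astype("datetime64[Y]")
    doy = (days - years).astype("timedelta64[D]").astype(float) + 1.0
    hour = (t - days).astype("timedelta64[s]").astype(float) / 3600.0
    return doy, hour


def solar_elevation(latitude, longitude, times):
    """Solar elevation angle (degrees) at a position for UTC ``times``.

    ``latitude``/``longitude`` may be scalars or arrays broadcastable
    against ``times`` (a moving tag passes per-sample positions).
    """
    doy, hour = _doy_hour(times)
    gamma = fractional_year(doy, hour)
    eqt = equation_of_time(gamma)
    dec = solar_declination(gamma)
    # true solar time in minutes; hour angle in radians
    tst = hour * 60.0 + eqt + 4.0 * np.asarray(longitude, dtype=float)
    ha = np.deg2rad(tst / 4.0 - 180.0)
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    cos_zen = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha)
    return 90.0 - np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))


def sunrise_sunset(latitude, longitude, year, doy, zenith=CIVIL_ZENITH):
    """Closed-form sunrise/sunset UTC timestamps for one civil day.

    Solves the sunrise equation cos(z) = sin(phi)sin(delta) +
    cos(phi)cos(delta)cos(H) for the hour angle H, with one refinement pass
    re-evaluating declination at the event time.  Returns ``(rise, set)``
    as ``numpy.datetime64[s]`` or ``(None, None)`` when the sun never
    crosses the requested zenith (polar day/night).
    """
    lat = np.deg2rad(latitude)
    cos_z = np.cos(np.deg2rad(zenith))

    def _events(hour_guess_rise, hour_guess_set):
        out = []
        for hguess, sign in ((hour_guess_rise, +1.0), (hour_guess_set, -1.0)):
            gamma = fractional_year(doy, hguess)
            dec = solar_declination(gamma)
            eqt = equation_of_time(gamma)
            denom = np.cos(lat) * np.cos(dec)
            if denom == 0:
                return None
            cos_ha = (cos_z - np.sin(lat) * np.sin(dec)) / denom
            if not -1.0 <= cos_ha <= 1.0:
                return None
            ha_deg = np.rad2deg(np.arccos(cos_ha))
            minutes = 720.0 - 4.0 * (longitude + sign * ha_deg) - eqt
            out.append(minutes)
        return out

    noon_guess = 12.0 - longitude / 15.0
    first = _events(noon_guess - 5.0, noon_guess + 5.0)
    if first is None:
        return None, None
    refined = _events(first[0] / 60.0, first[1] / 60.0)
    if refined is None:
        return None, None
    day0 = np.datetime64(f"{year:04d}-01-01", "s") + np.timedelta64(int(doy) - 1, "D")
    rise = day0 + np.timedelta64(int(round(refined[0] * 60.0)), "s")
    sset = day0 + np.timedelta64(int(round(refined[1] * 60.0)), "s")
    return rise, sset


def day_length_hours(latitude, declination, zenith=CIVIL_ZENITH):
    """Day length (hours) from the sunrise equation; NaN during polar day/night."""
    lat = np.deg2rad(latitude)
    cos_ha = (np.cos(np.deg2rad(zenith)) - np.sin(lat) * np.sin(declination)) / (
        np.cos(lat) * np.cos(declination)
    )
    cos_ha = np.asarray(cos_ha, dtype=float)
    out = np.where(np.abs(cos_ha) <= 1.0, np.rad2deg(np.arccos(np.clip(cos_ha, -1, 1))) * 2.0 / 15.0, np.nan)
    return out[()] if out.ndim == 0 else out


def great_circle_point(lat1, lon1, lat2, lon2, fraction):
    """Point ``fraction`` of the way along the great circle between two positions.

    Spherical linear interpolation on unit vectors; ``fraction`` may be an
    array.  Returns ``(latitude, longitude)`` in degrees.
    """
    f = np.asarray(fraction, dtype=float)

    def _vec(lat, lon):
        la, lo = np.deg2rad(lat), np.deg2rad(lon)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

    a, b = _vec(lat1, lon1), _vec(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        lat = np.broadcast_to(lat1, f.shape).astype(float)
        lon = np.broadcast_to(lon1, f.shape).astype(float)
        return lat[()] if lat.ndim == 0 else lat, lon[()] if lon.ndim == 0 else lon
    sa = np.sin((1.0 - f) * omega) / np.sin(omega)
    sb = np.sin(f * omega) / np.sin(omega)
    v = sa * a[:, None] + sb * b[:, None] if f.ndim else sa * a + sb * b
    v = v.reshape(3, -1)
    lat = np.rad2deg(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(v[1], v[0]))
    if not f.ndim:
        return float(lat[0]), float(lon[0])
    return lat, lon
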