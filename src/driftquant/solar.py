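"""Solar position geometry for defining day and night at sea.

Implements the standard NOAA/Meeus low-precision solar ephemeris: geometric
solar elevation (no atmospheric refraction) as a function of UTC time and
geographic position. Accuracy is a few hundredths of a degree, far inside the
half-degree needed to decide whether drifting larvae experience day or night.

At high latitudes in summer the sun may never set ("midnight sun"). For the
diel-vertical-migration rule this module also provides :func:`is_night`, which
falls back to a fixed window around the daily minimum solar elevation whenever
the elevation never crosses the horizon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_elevation", "is_night"]

_UNIX_EPOCH_JD = 2440587.5  # Julian date of 1970-01-01T00:00Z


def _to_unix_seconds(time) -> np.ndarray:
    """Coerce datetime-like input (scalar or array) to Unix seconds (float)."""
    t = pd.to_datetime(time, utc=False)
    if isinstance(t, pd.Timestamp):
        return np.asarray(t.value / 1e9)
    return np.asarray(pd.DatetimeIndex(t).asi8, dtype=float) / 1e9


def _solar_coordinates(unix_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (declination [rad], equation of time [minutes])."""
    jd = unix_s / 86400.0 + _UNIX_EPOCH_JD
    # Julian centuries since J2000.0
    T = (jd - 2451545.0) / 36525.0

    # Geometric mean longitude and anomaly of the sun (degrees)
    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    Mr = np.deg2rad(M)

    # Equation of center and true longitude
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    # Apparent longitude, corrected for nutation/aberration
    omega = 125.04 - 1934.136 * T
    lam = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega)))

    # Obliquity of the ecliptic (corrected)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(np.deg2rad(omega)))

    decl = np.arcsin(np.sin(eps) * np.sin(lam))

    # Equation of time (minutes), Meeus ch. 28
    y = np.tan(eps / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * 0.016708634 * np.sin(Mr)
        + 4.0 * 0.016708634 * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * 0.016708634**2 * np.sin(2 * Mr)
    )
    return decl, eot


def solar_elevation(time, lon, lat):
    """Geometric solar elevation angle in degrees above the horizon.

    Parameters
    ----------
    time
        UTC timestamp(s): anything ``pandas.to_datetime`` accepts.
    lon, lat
        Position in degrees east / degrees north. Scalars or arrays
        broadcastable against ``time``.

    Returns
    -------
    float or ndarray
        Elevation in degrees; negative when the sun is below the horizon.
    """
    unix_s = _to_unix_seconds(time)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0) or not np.all(np.isfinite(lon)):
        raise ValueError("invalid coordinates")

    decl, eot = _solar_coordinates(unix_s)

    # True solar time in minutes of day at the given longitude
    minutes_utc = np.mod(unix_s / 60.0, 1440.0)
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    hour_angle = np.deg2rad(tst / 4.0 - 180.0)

    latr = np.deg2rad(lat)
    sin_elev = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(hour_angle)
    elev = np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    if elev.ndim == 0:
        return float(elev)
    return elev


def _minutes_to_solar_midnight(time, lon) -> np.ndarray:
    """Signed minutes from ``time`` to the nearest local solar midnight."""
    unix_s = _to_unix_seconds(time)
    lon = np.asarray(lon, dtype=float)
    _, eot = _solar_coordinates(unix_s)
    tst = np.mod(unix_s / 60.0 + eot + 4.0 * lon, 1440.0)
    # Solar midnight is tst == 0 (mod 1440); wrap into [-720, 720)
    return np.mod(tst + 720.0, 1440.0) - 720.0


def is_night(time, lon, lat, *, horizon: float = 0.0, polar_window_hours: float = 3.0):
    """Decide whether it is night for the diel-migration rule.

    Night is a solar elevation below ``horizon`` (default the geometric
    horizon, 0 deg). Under midnight sun the elevation never goes negative,
    so night is instead the window of ``polar_window_hours`` on either side
    of local solar midnight, the daily elevation minimum.
    """
    elev = np.asarray(solar_elevation(time, lon, lat))
    night = elev < horizon

    lat_arr = np.asarray(lat, dtype=float)
    # Cheap "sun never sets today" test: elevation at local solar midnight.
    dt_min = _minutes_to_solar_midnight(time, lon)
    unix_s = _to_unix_seconds(time)
    midnight_unix = unix_s - dt_min * 60.0
    elev_midnight = np.asarray(
        solar_elevation(pd.to_datetime(midnight_unix * 1e9), lon, lat_arr)
    )
    polar_day = elev_midnight >= horizon
    window = np.abs(dt_min) <= polar_window_hours * 60.0
    night = np.where(polar_day, window, night)
    if night.ndim == 0:
        return bool(night)
    return night
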