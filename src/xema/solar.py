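"""Low-precision solar ephemeris and the twilight forward model.

Threshold geolocation needs only two solar quantities per day: the
declination (for the day-length/latitude relation) and the equation of
time (for the longitude/solar-noon relation). The truncated Fourier fits
of Spencer (1971) deliver ~0.1-0.2 deg and ~0.5 min accuracy, which is far
below geolocator noise. Both the forward model used by the simulator and
the inverse estimators evaluate the same ephemeris at 12:00 UTC of the
record's date, so zero-noise round trips are exact up to solver tolerance.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

from .types import POLAR_DAY, POLAR_NIGHT


@dataclass
class SolarState:
    declination_deg: float
    equation_of_time_min: float


def _fractional_year(when: dt.datetime) -> float:
    doy = when.timetuple().tm_yday
    hour = when.hour + when.minute / 60.0 + when.second / 3600.0
    year_len = 366.0 if when.year % 4 == 0 and (when.year % 100 != 0 or when.year % 400 == 0) else 365.0
    return 2.0 * math.pi / year_len * (doy - 1 + (hour - 12.0) / 24.0)


def solar_ephemeris(when) -> SolarState:
    """Solar declination (deg) and equation of time (min) at ``when``.

    ``when`` may be a date (evaluated at 12:00 UTC) or a datetime. The
    equation of time is positive when the sun is ahead of clock time, so
    solar noon (UTC hours) at longitude L is ``12 - L/15 - eot/60``.
    """
    if isinstance(when, dt.datetime):
        t = when
    else:
        t = dt.datetime(when.year, when.month, when.day, 12, 0, 0)
    if not (1990 <= t.year <= 2100):
        raise ValueError("timestamp outside supported years 1990-2100")
    g = _fractional_year(t)
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    eot = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    return SolarState(declination_deg=math.degrees(decl), equation_of_time_min=eot)


def day_length_h(lat_deg: float, decl_deg: float, sun_angle_deg: float) -> float:
    """Day length (h) between crossings of the sun angle; 24/0 for polar day/night."""
    phi = math.radians(lat_deg)
    delta = math.radians(decl_deg)
    a = math.radians(sun_angle_deg)
    denom = math.cos(phi) * math.cos(delta)
    if denom == 0.0:
        return 24.0 if math.sin(phi) * math.sin(delta) > math.sin(a) else 0.0
    x = (math.sin(a) - math.sin(phi) * math.sin(delta)) / denom
    if x <= -1.0:
        return 24.0
    if x >= 1.0:
        return 0.0
    return 2.0 * math.degrees(math.acos(x)) / 15.0


def twilight_forward(lat: float, lon: float, date: dt.date, sun_angle_deg: float):
    """Sunrise/sunset UTC decimal hours at (lat, lon) on ``date``.

    Solves the hour-angle equation
    ``cos H = (sin a - sin(phi) sin(delta)) / (cos(phi) cos(delta))``
    for the configured sun elevation ``a``. Returns ``(sunrise_h, sunset_h)``
    or the POLAR_DAY / POLAR_NIGHT sentinel when no crossing exists.
    """
    if abs(lat) > 90:
        raise ValueError("latitude outside [-90, 90]")
    eph = solar_ephemeris(date)
    length = day_length_h(lat, eph.declination_deg, sun_angle_deg)
    if length >= 24.0:
        return POLAR_DAY
    if length <= 0.0:
        return POLAR_NIGHT
    noon = 12.0 - lon / 15.0 - eph.equation_of_time_min / 60.0
    sunrise = (noon - length / 2.0) % 24.0
    sunset = (noon + length / 2.0) % 24.0
    return sunrise, sunset
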