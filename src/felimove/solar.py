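"""Solar and lunar geometry used as activity covariates.

Sunrise, sunset and day length follow the standard NOAA solar-position
equations: Fourier expansions of the equation of time and the solar
declination in the fractional year, with the conventional sunrise/sunset
zenith of 90.833 degrees (solar disc radius plus atmospheric refraction).
Moon phase is a synodic-cycle computation anchored at a reference new
moon; by convention 0 = new moon and 1 = full moon (the fraction of the
disc illuminated), configurable to the raw cycle fraction.

All angles are handled in radians internally; public interfaces use
degrees for latitude/longitude and local civil time for timestamps
(``tz_offset_hours`` east of UTC).
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = [
    "PolarDayNightError",
    "sun_times",
    "day_length_fraction",
    "moon_cycle_fraction",
    "moon_phase",
    "SYNODIC_DAYS",
    "NEW_MOON_EPOCH",
]

#: Mean synodic month (new moon to new moon), days.
SYNODIC_DAYS = 29.530588853

#: Reference new moon, UTC.
NEW_MOON_EPOCH = dt.datetime(2000, 1, 6, 18, 14)

#: Sunrise/sunset zenith angle, degrees (refraction + solar radius).
ZENITH_DEG = 90.833

#: Latitude beyond which polar day/night can occur; out of study scope.
POLAR_LAT = 66.5


class PolarDayNightError(ValueError):
    """Raised when the sun never rises or never sets on the requested day."""


def _solar_coefficients(date: dt.date) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at midday."""
    doy = date.timetuple().tm_yday
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return eqtime, decl


def _hour_angle_deg(latitude: float, decl: float) -> float:
    """Sunrise hour angle in degrees for the given declination."""
    phi = math.radians(latitude)
    cos_ha = math.cos(math.radians(ZENITH_DEG)) / (
        math.cos(phi) * math.cos(decl)
    ) - math.tan(phi) * math.tan(decl)
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise PolarDayNightError(
            f"sun never {'sets' if cos_ha < -1 else 'rises'} at latitude "
            f"{latitude:.2f} on the requested date"
        )
    return math.degrees(math.acos(cos_ha))


def sun_times(
    date: dt.date,
    latitude: float,
    longitude: float = 0.0,
    tz_offset_hours: float = 0.0,
) -> tuple[dt.datetime, dt.datetime, float]:
    """Sunrise, sunset (local civil time) and day-length fraction of 24 h.

    Parameters
    ----------
    date
        Calendar date (local).
    latitude, longitude
        Degrees; north and east positive. ``|latitude|`` must be below the
        polar circle.
    tz_offset_hours
        Offset of local civil time from UTC, hours east.

    Returns
    -------
    (sunrise, sunset, day_fraction)
        Naive datetimes in local civil time and the fraction of 24 h with
        daylight, in (0, 1).
    """
    if abs(latitude) >= POLAR_LAT:
        raise PolarDayNightError(
            f"latitude {latitude:.2f} is poleward of the {POLAR_LAT} deg limit"
        )
    eqtime, decl = _solar_coefficients(date)
    ha = _hour_angle_deg(latitude, decl)
    # Minutes past UTC midnight; longitude positive east.
    sunrise_utc = 720.0 - 4.0 * (longitude + ha) - eqtime
    sunset_utc = 720.0 - 4.0 * (longitude - ha) - eqtime
    base = dt.datetime.combine(date, dt.time()) + dt.timedelta(
        hours=tz_offset_hours
    )
    sunrise = base + dt.timedelta(minutes=sunrise_utc)
    sunset = base + dt.timedelta(minutes=sunset_utc)
    return sunrise, sunset, ha / 180.0


def day_length_fraction(date: dt.date, latitude: float) -> float:
    """Proportion of 24 h with daylight (longitude-independent)."""
    return sun_times(date, latitude)[2]


def moon_cycle_fraction(timestamp: dt.datetime) -> float:
    """Position in the synodic cycle, in [0, 1): 0 = new moon, 0.5 = full."""
    days = (timestamp - NEW_MOON_EPOCH).total_seconds() / 86400.0
    return (days / SYNODIC_DAYS) % 1.0

def moon_phase(timestamp: dt.datetime, convention: str = "illumination") -> float:
    """Moon phase on a 0.00-1.00 scale.

    ``convention="illumination"`` (default) returns the illuminated disc
    fraction, so 0 = new moon and 1 = full moon regardless of waxing or
    waning.  ``convention="cycle"`` returns the raw synodic-cycle fraction.
    """
    frac = moon_cycle_fraction(timestamp)
    if convention == "cycle":
        return frac
    if convention == "illumination":
        return 0.5 * (1.0 - math.cos(2.0 * math.pi * frac))
    raise ValueError(f"unknown moon phase convention: {convention!r}")
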