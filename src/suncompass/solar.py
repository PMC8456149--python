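"""Solar-azimuth ephemeris and sun-relative angle transforms.

Implements the NOAA solar-position equations (the low-precision Meeus
reduction used by the NOAA Solar Calculator, accurate to well under 0.2
degrees for azimuth over 1950-2050) plus the transforms an orientation
experiment needs:

* rectification — rotate headings so the sun's azimuth maps to 180 deg,
  making flights at different times comparable in a sun-relative frame;
* the clock-shift azimuth difference az(t) - az(t - shift), the heading
  change a fully time-compensating animal is expected to show after its
  circadian clock has been advanced by ``shift`` hours;
* back-transformation — removing that expected shift so clock-shifted
  headings can be compared with controls;
* an optional 4-parameter logistic fit of azimuth against time of day,
  usable in place of the raw ephemeris when azimuths come from a table.

Azimuths are degrees clockwise from true north, matching compass headings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
from scipy.optimize import curve_fit

from .circstats import wrap180, wrap360

__all__ = [
    "Site",
    "BUJARUELO",
    "AzimuthCurve",
    "solar_azimuth",
    "solar_elevation",
    "azimuth_shift",
    "fit_azimuth_curve",
    "rectify_angles",
    "back_transform",
]


@dataclass(frozen=True)
class Site:
    """An observation site: latitude/longitude (degrees, east-positive
    longitude) and the UTC offset of local civil time in hours."""

    latitude: float
    longitude: float
    utc_offset: float = 0.0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError("longitude out of range")

    def to_utc(self, when: datetime) -> datetime:
        """Interpret a naive datetime as local civil time at this site."""
        if when.tzinfo is not None:
            return when.astimezone(timezone.utc)
        return (when - timedelta(hours=self.utc_offset)).replace(tzinfo=timezone.utc)


# The Pyrenean mountain-pass site (Puerto de Bujaruelo, 42.70 N, 0.064 W);
# local civil time on the study dates was CEST (UTC+2).
BUJARUELO = Site(latitude=42.7038793, longitude=-0.0641454, utc_offset=2.0)


def _julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = (
        dt_utc.day
        + dt_utc.hour / 24.0
        + dt_utc.minute / 1440.0
        + (dt_utc.second + dt_utc.microsecond / 1e6) / 86400.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_position(site: Site, when: datetime) -> tuple[float, float]:
    """(azimuth, elevation) in degrees. NOAA Solar Calculator equations."""
    dt_utc = site.to_utc(when)
    jd = _julian_day(dt_utc)
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    m_rad = np.deg2rad(geom_mean_anom)
    eq_of_centre = (
        np.sin(m_rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m_rad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m_rad) * 0.000289
    )
    true_long = geom_mean_long + eq_of_centre
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    obliq_rad = np.deg2rad(obliq)

    app_long_rad = np.deg2rad(app_long)
    declination = np.arcsin(np.sin(obliq_rad) * np.sin(app_long_rad))

    var_y = np.tan(obliq_rad / 2.0) ** 2
    l0_rad = np.deg2rad(geom_mean_long)
    eq_time = 4.0 * np.rad2deg(
        var_y * np.sin(2 * l0_rad)
        - 2.0 * ecc * np.sin(m_rad)
        + 4.0 * ecc * var_y * np.sin(m_rad) * np.cos(2 * l0_rad)
        - 0.5 * var_y * var_y * np.sin(4 * l0_rad)
        - 1.25 * ecc * ecc * np.sin(2 * m_rad)
    )

    minutes_utc = dt_utc.hour * 60.0 + dt_utc.minute + (dt_utc.second + dt_utc.microsecond / 1e6) / 60.0
    true_solar_time = (minutes_utc + eq_time + 4.0 * site.longitude) % 1440.0
    ha = true_solar_time / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0

    lat_rad = np.deg2rad(site.latitude)
    ha_rad = np.deg2rad(ha)
    cos_zenith = np.sin(lat_rad) * np.sin(declination) + np.cos(lat_rad) * np.cos(declination) * np.cos(ha_rad)
    zenith = np.arccos(np.clip(cos_zenith, -1.0, 1.0))
    elevation = 90.0 - np.rad2deg(zenith)

    sin_zenith = np.sin(zenith)
    if sin_zenith < 1e-9:
        return 180.0, float(elevation)
    cos_az = (np.sin(lat_rad) * np.cos(zenith) - np.sin(declination)) / (np.cos(lat_rad) * sin_zenith)
    az_acos = np.rad2deg(np.arccos(np.clip(cos_az, -1.0, 1.0)))
    if ha > 0:
        azimuth = (az_acos + 180.0) % 360.0
    else:
        azimuth = (540.0 - az_acos) % 360.0
    return float(azimuth), float(elevation)


def solar_azimuth(site: Site, when: datetime) -> float:
    """Solar azimuth in degrees clockwise from true north.

    ``when`` may be timezone-aware or naive; naive datetimes are read as
    local civil time at the site (``site.utc_offset``).
    """
    return _solar_position(site, when)[0]


def solar_elevation(site: Site, when: datetime) -> float:
    """Solar elevation above the horizon in degrees (no refraction)."""
    return _solar_position(site, when)[1]


def azimuth_shift(site: Site, when: datetime, hours: float = 6.0) -> float:
    """Azimuth change over the preceding ``hours``: az(t) - az(t - hours).

    This is the heading change expected of an animal whose circadian clock
    has been advanced by ``hours`` and which fully compensates for the
    sun's movement. Wrapped to (-180, 180]. Raises if the reference time
    ``t - hours`` falls before sunrise (the sun's azimuth is then not a
    usable reference).
    """
    earlier = when - timedelta(hours=hours)
    if hours != 0.0 and solar_elevation(site, earlier) < 0.0:
        raise ValueError(
            f"reference time {earlier} is before sunrise at this site; "
            "azimuth difference is undefined"
        )
    return wrap180(solar_azimuth(site, when) - solar_azimuth(site, earlier))


@dataclass(frozen=True)
class AzimuthCurve:
    """Four-parameter logistic fit of solar azimuth against time of day.

    f(t) = c + (d - c) / (1 + exp(b * (t - e)))  with t in decimal hours.
    Over a single day's daytime window the azimuth rises monotonically
    from east through south to west and is well approximated by this
    sigmoid; c and d are the lower/upper asymptotes, e the inflection time
    (near solar transit) and b (< 0 for an increasing curve) the slope.
    """

    b: float
    c: float
    d: float
    e: float
    day: date
    residual_rms: float
    _tmin: float = field(default=0.0, repr=False)
    _tmax: float = field(default=24.0, repr=False)

    def predict(self, t_hours):
        t = np.asarray(t_hours, dtype=float)
        out = _logistic4(t, self.b, self.c, self.d, self.e)
        return float(out) if np.ndim(t_hours) == 0 else out


def _logistic4(t, b, c, d, e):
    return c + (d - c) / (1.0 + np.exp(b * (t - e)))


def fit_azimuth_curve(times, azimuths, day: date | None = None) -> AzimuthCurve:
    """Least-squares 4PL fit of azimuth (deg) vs local time (decimal hours).

    ``times`` may be decimal hours or datetimes (all on one calendar day).
    Requires at least 6 monotonically increasing azimuth samples spanning
    several hours; rejects multi-day or non-monotone input, for which a
    single sigmoid is the wrong model.
    """
    if len(times) and isinstance(times[0], datetime):
        days = {t.date() for t in times}
        if len(days) > 1:
            raise ValueError("azimuth curve must be fitted to a single day")
        day = days.pop()
        t = np.array([x.hour + x.minute / 60.0 + x.second / 3600.0 for x in times])
    else:
        t = np.asarray(times, dtype=float)
    az = np.asarray(azimuths, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 points to fit the azimuth curve")
    order = np.argsort(t)
    t, az = t[order], az[order]
    if np.any(np.diff(az) <= 0):
        raise ValueError("azimuths must be strictly increasing through the day")
    if t[-1] - t[0] < 2.0:
        raise ValueError("points must span at least 2 hours")

    span = az[-1] - az[0]
    p0 = (-1.0, az[0] - 0.1 * span, az[-1] + 0.1 * span, float(np.median(t)))
    params, _ = curve_fit(_logistic4, t, az, p0=p0, maxfev=20_000)
    b, c, d, e = (float(v) for v in params)
    rms = float(np.sqrt(np.mean((_logistic4(t, b, c, d, e) - az) ** 2)))
    return AzimuthCurve(
        b=b, c=c, d=d, e=e,
        day=day if day is not None else date.today(),
        residual_rms=rms, _tmin=float(t[0]), _tmax=float(t[-1]),
    )


def rectify_angles(angles_deg, azimuth: float):
    """Rotate headings into the sun-relative frame (sun at 180 deg).

    out = (angle - azimuth + 180) mod 360. A heading straight at the sun
    maps to 180. Being a rigid rotation it preserves r, R* and every
    dispersion measure; only mean directions move.
    """
    if not 0.0 <= azimuth < 360.0:
        raise ValueError("azimuth must lie in [0, 360)")
    out = wrap360(np.asarray(angles_deg, dtype=float) - azimuth + 180.0)
    if np.ndim(angles_deg) == 0:
        return float(out)
    return out


def back_transform(angles_deg, site: Site, when: datetime, hours: float = 6.0):
    """Remove the expected clock-shift rotation from headings.

    Subtracts az(t) - az(t - hours) so that the headings of clock-shifted
    animals, if they compensate fully, line up with unshifted controls.
    """
    delta = azimuth_shift(site, when, hours)
    out = wrap360(np.asarray(angles_deg, dtype=float) - delta)
    if np.ndim(angles_deg) == 0:
        return float(out)
    return out
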