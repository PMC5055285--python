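"""Clear-sky solar geometry.

Standard declination / hour-angle formulas. Apparent solar time is taken
from longitude alone; the equation of time (< ~4 min) is neglected, which
shifts sunrise/sunset by at most one sub-hourly sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Irradiance reaching a horizontal surface with the sun at zenith under a
#: clear sky (W/m^2). Scaled by sin(elevation) for other sun angles.
CLEAR_SKY_PEAK = 1000.0


def solar_declination(day_of_year):
    """Solar declination (radians) from day of year (1-366)."""
    day_of_year = np.asarray(day_of_year, dtype=float)
    return np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + day_of_year) / 365.0)


def solar_elevation(times, latitude: float, longitude: float) -> np.ndarray:
    """Apparent solar elevation angle (radians) at UTC instants.

    Parameters
    ----------
    times : DatetimeIndex-like
        Timestamps interpreted as UTC.
    latitude, longitude : float
        Site coordinates in decimal degrees (east positive).
    """
    t = pd.DatetimeIndex(times)
    doy = t.dayofyear.to_numpy(dtype=float)
    hour_utc = (
        t.hour.to_numpy(dtype=float)
        + t.minute.to_numpy(dtype=float) / 60.0
        + t.second.to_numpy(dtype=float) / 3600.0
    )
    solar_hour = hour_utc + longitude / 15.0
    hour_angle = np.deg2rad((solar_hour - 12.0) * 15.0)
    lat = np.deg2rad(latitude)
    dec = solar_declination(doy)
    sin_el = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(hour_angle)
    return np.arcsin(np.clip(sin_el, -1.0, 1.0))


def clear_sky_irradiance(times, latitude: float, longitude: float) -> np.ndarray:
    """Clear-sky downwelling shortwave (W/m^2); zero when the sun is below the horizon."""
    el = solar_elevation(times, latitude, longitude)
    return CLEAR_SKY_PEAK * np.clip(np.sin(el), 0.0, None)
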