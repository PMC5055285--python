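"""Hourly averaging, solar gap-filling, emersion masking and daily-max pairing.

These operations turn raw sub-hourly series into the analysis substrate:
hourly means, a complete solar record, a tide+run-up emersion mask, and
paired forecast/observed daily maxima over emersed hours of each site-local
calendar day.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd


def hourly_average(series: pd.Series, point_values: bool = False) -> pd.Series:
    """Collapse a timestamped series to one value per clock hour.

    For sub-hourly data the hourly value is the arithmetic mean of in-hour
    samples; hours with no samples are missing (NaN). For on-the-hour point
    measurements (``point_values=True``) each observation is averaged with
    the following observation; already-hourly *means* pass through unchanged
    (``point_values=False``), so the operation is idempotent.

    An empty input returns an empty series.
    """
    if len(series) == 0:
        return series.copy()
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    if len(series) == 1:
        step = pd.Timedelta(hours=1)
    else:
        step = pd.Timedelta(int(np.diff(series.index.asi8).min()), unit="ns")
    if step > pd.Timedelta(hours=1):
        raise ValueError("cadence must be sub-hourly or hourly")
    if step == pd.Timedelta(hours=1):
        if not point_values:
            out = series.copy()
            out.index = out.index.floor("h")
            return out
        paired = (series + series.shift(-1)) / 2.0
        out = paired.iloc[:-1]  # the last observation has no follower
        out.index = out.index.floor("h")
        return out
    return series.resample("1h").mean()


class FilledSolar(NamedTuple):
    """Result of :func:`fill_solar`: the filled series and days that could not be filled."""

    series: pd.Series
    flagged_days: list


def fill_solar(
    solar: pd.Series, elevation: pd.Series, utc_offset: float = 0.0
) -> FilledSolar:
    """Complete an hourly solar record limited to the 09:00-16:00 local window.

    Hours with solar elevation <= 0 are set to zero. The gaps between
    sunrise and 09:00 and between 16:00 and sunset are filled by linear
    interpolation between the window-boundary value and zero at the
    sunrise/sunset anchor (the adjacent hour with non-positive elevation).
    Values inside 09:00-16:00 pass through unchanged. Days whose 09:00-16:00
    block is incomplete cannot be filled and are flagged.

    ``elevation`` (radians or degrees — only its sign is used) must cover
    every hour of ``solar``'s index.
    """
    if not solar.index.equals(elevation.index):
        raise ValueError("solar and elevation must share an hourly index")
    local = solar.index + pd.Timedelta(hours=utc_offset)
    out = solar.copy()
    flagged: list = []
    frame = pd.DataFrame(
        {"solar": solar.to_numpy(), "elev": elevation.to_numpy(), "hour": local.hour},
        index=solar.index,
    )
    for day, grp in frame.groupby(local.date):
        night = grp["elev"] <= 0.0
        out.loc[grp.index[night]] = 0.0
        window = grp[(grp["hour"] >= 9) & (grp["hour"] <= 16) & ~night]
        if window["solar"].isna().any():
            flagged.append(day)
            continue
        hours = grp["hour"].to_numpy()
        elev = grp["elev"].to_numpy()
        # Morning: anchor at the last non-positive-elevation hour before 09.
        morning = (hours < 9) & (elev > 0.0)
        if morning.any() and 9 in hours:
            v9 = float(grp.loc[grp.index[hours == 9][0], "solar"])
            dark_before = hours[(hours < 9) & (elev <= 0.0)]
            sunrise_anchor = float(dark_before.max()) if len(dark_before) else float(hours[morning].min() - 1)
            for ts, h in zip(grp.index[morning], hours[morning]):
                out.loc[ts] = v9 * (h - sunrise_anchor) / (9.0 - sunrise_anchor)
        # Evening: anchor at the first non-positive-elevation hour after 16.
        evening = (hours > 16) & (elev > 0.0)
        if evening.any() and 16 in hours:
            v16 = float(grp.loc[grp.index[hours == 16][0], "solar"])
            dark_after = hours[(hours > 16) & (elev <= 0.0)]
            sunset_anchor = float(dark_after.min()) if len(dark_after) else float(hours[evening].max() + 1)
            for ts, h in zip(grp.index[evening], hours[evening]):
                out.loc[ts] = v16 * (sunset_anchor - h) / (sunset_anchor - 16.0)
    return FilledSolar(series=out, flagged_days=flagged)


def wave_runup(sig_wave_height, shore_slope: float, runup_coefficient: float = 1.0):
    """Wave run-up (swash) height in metres: coefficient * slope * Hs.

    A linear proxy for swash excursion above still tide level; the
    coefficient is exposed for calibration. Negative inputs are rejected.
    """
    hs = np.asarray(sig_wave_height, dtype=float)
    if np.any(hs < 0):
        raise ValueError("significant wave height must be >= 0")
    if shore_slope < 0 or runup_coefficient < 0:
        raise ValueError("shore slope and run-up coefficient must be >= 0")
    out = runup_coefficient * shore_slope * hs
    if isinstance(sig_wave_height, pd.Series):
        return pd.Series(out, index=sig_wave_height.index, name="runup")
    return out


def emersion_mask(tide: pd.Series, runup, logger_elevation: float) -> pd.Series:
    """Boolean mask, True where the logger is emersed (exposed to air).

    Emersed iff still tide height + wave run-up is strictly below the logger
    elevation; ties count as submerged.
    """
    if isinstance(runup, pd.Series):
        if not tide.index.equals(runup.index):
            raise ValueError("tide and runup must share an index")
        runup = runup.to_numpy()
    wet = tide.to_numpy(dtype=float) + np.asarray(runup, dtype=float)
    return pd.Series(wet < logger_elevation, index=tide.index, name="emersed")


def daily_max_pairs(
    forecast: pd.Series,
    observed: pd.Series,
    mask: pd.Series,
    utc_offset: float = 0.0,
) -> pd.DataFrame:
    """Pair forecast and observed daily maxima over emersed hours.

    The daily maximum is the highest hourly value among emersed hours of a
    site-local calendar day (local standard time = UTC + ``utc_offset``).
    The hour at which each side peaks need not match. Days on which either
    side has no emersed, non-missing hour are dropped.

    Returns a frame with columns ``date``, ``forecast_max``, ``observed_max``.
    """
    common = forecast.index.intersection(observed.index).intersection(mask.index)
    f = forecast.loc[common]
    o = observed.loc[common]
    m = mask.loc[common].astype(bool)
    f = f[m]
    o = o[m]
    local_days = f.index + pd.Timedelta(hours=utc_offset)
    grouper = pd.Index(local_days.date, name="date")
    fmax = f.groupby(grouper).max()
    omax = o.groupby(grouper).max()
    pairs = pd.DataFrame({"forecast_max": fmax, "observed_max": omax}).dropna()
    pairs = pairs.reset_index()
    return pairs[["date", "forecast_max", "observed_max"]]
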