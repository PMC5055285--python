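"""In-memory containers and text-file I/O for forcing and body-temperature records.

An environmental forcing record is a plain :class:`pandas.DataFrame` indexed
by naive-UTC timestamps at a fixed cadence, with the columns in
:data:`ENV_COLUMNS`. Body-temperature records carry site/microsite identity
and a source tag and are therefore wrapped in a small dataclass around a
:class:`pandas.Series`.

CSV files use an ISO-8601 UTC ``timestamp`` column plus named value columns,
one file per site or logger. Readers for the NDBC standard meteorological
text format and CO-OPS-style tide CSVs are included for real buoy/tide-gauge
records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

ENV_COLUMNS = ("air_temp", "solar", "wind", "sig_wave_height", "tide_height", "sst")

#: Allowed provenance tags for a body-temperature series.
SOURCES = ("observed", "air_proxy", "elvin_gonor", "site_regression", "heat_budget")

_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


@dataclass
class BodyTemperatureSeries:
    """Timestamped body (or logger) temperature with identity and provenance.

    Parameters
    ----------
    temps : pandas.Series
        Body temperature in deg C indexed by naive-UTC timestamps.
    site_id, microsite_id : str
        Site and within-site logger/microsite labels.
    source : str
        One of :data:`SOURCES`: ``observed`` for logger data, otherwise the
        name of the model that produced the series.
    """

    temps: pd.Series
    site_id: str
    microsite_id: str
    source: str

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if not isinstance(self.temps.index, pd.DatetimeIndex):
            raise TypeError("temps must be indexed by timestamps")

    def with_temps(self, temps: pd.Series) -> "BodyTemperatureSeries":
        return replace(self, temps=temps)


def validate_environment(df: pd.DataFrame) -> pd.DataFrame:
    """Check the environmental-series contract; return ``df`` unchanged.

    Raises ``ValueError`` on missing columns, non-monotone or irregular
    timestamps, negative solar or wave height, or missing values.
    """
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing environmental columns: {missing}")
    idx = df.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise ValueError("environmental series must have a DatetimeIndex")
    if len(df) >= 2:
        steps = np.diff(idx.asi8)
        if not (steps > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(set(steps)) != 1:
            raise ValueError("timestamps must have a constant step")
    if (df["solar"] < 0).any():
        raise ValueError("solar must be non-negative")
    if (df["sig_wave_height"] < 0).any():
        raise ValueError("sig_wave_height must be non-negative")
    if df[list(ENV_COLUMNS)].isna().any().any():
        raise ValueError("environmental series must have no missing values")
    return df


# ---------------------------------------------------------------------------
# CSV dialect: ISO-8601 UTC timestamp column + named value columns.

def _format_index(idx: pd.DatetimeIndex) -> pd.Index:
    return idx.strftime(_TS_FORMAT)


def _parse_timestamps(col) -> pd.DatetimeIndex:
    ts = pd.to_datetime(col, utc=True)
    idx = pd.DatetimeIndex(ts).tz_convert("UTC").tz_localize(None)
    return idx.rename(None)


def write_environment_csv(df: pd.DataFrame, path) -> None:
    out = df[list(ENV_COLUMNS)].copy()
    out.insert(0, "timestamp", _format_index(df.index))
    out.to_csv(path, index=False)


def read_environment_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, float_precision="round_trip")
    idx = _parse_timestamps(raw.pop("timestamp"))
    df = raw.set_index(idx)
    return validate_environment(df)


def write_body_csv(body: BodyTemperatureSeries, path) -> None:
    out = pd.DataFrame(
        {
            "timestamp": _format_index(body.temps.index),
            "body_temp": body.temps.to_numpy(),
            "site_id": body.site_id,
            "microsite_id": body.microsite_id,
            "source": body.source,
        }
    )
    out.to_csv(path, index=False)


def read_body_csv(path) -> BodyTemperatureSeries:
    raw = pd.read_csv(path, float_precision="round_trip")
    idx = _parse_timestamps(raw["timestamp"])
    temps = pd.Series(raw["body_temp"].to_numpy(dtype=float), index=idx, name="body_temp")
    return BodyTemperatureSeries(
        temps=temps,
        site_id=str(raw["site_id"].iloc[0]),
        microsite_id=str(raw["microsite_id"].iloc[0]),
        source=str(raw["source"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# External formats.

#: NDBC sentinel values that mean "missing".
_NDBC_SENTINELS = (99.0, 999.0, 9999.0)

#: NDBC standard-met column -> our column name.
_NDBC_MAP = {
    "ATMP": "air_temp",
    "WSPD": "wind",
    "WVHT": "sig_wave_height",
    "WTMP": "sst",
}


def read_ndbc(path) -> pd.DataFrame:
    """Read an NDBC standard meteorological text file.

    Whitespace-delimited with two header lines (names, then units); the
    sentinel values 99.0/999/9999 are mapped to missing. Returns a frame
    indexed by UTC timestamps with whichever of ``air_temp``, ``wind``,
    ``sig_wave_height`` and ``sst`` the file provides.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    header = lines[0].lstrip("#").split()
    # Second line is units when it also starts with '#'.
    body_start = 2 if lines[1].lstrip().startswith("#") else 1
    df = pd.read_csv(
        io.StringIO("\n".join(lines[body_start:])),
        sep=r"\s+",
        names=header,
        na_values=list(_NDBC_SENTINELS),
    )
    year_col = "YY" if "YY" in df.columns else "YYYY"
    year = df[year_col].astype(int)
    # Two-digit years in old files are 20th century.
    year = year.where(year > 100, year + 1900)
    minute = df["mm"].astype(int) if "mm" in df.columns else 0
    idx = pd.to_datetime(
        {
            "year": year,
            "month": df["MM"].astype(int),
            "day": df["DD"].astype(int),
            "hour": df["hh"].astype(int),
            "minute": minute,
        }
    )
    out = pd.DataFrame(index=pd.DatetimeIndex(idx))
    for src, dst in _NDBC_MAP.items():
        if src in df.columns:
            out[dst] = df[src].to_numpy(dtype=float)
    return out


def read_coops_tide(path) -> pd.Series:
    """Read a CO-OPS-style tide CSV (timestamp, water level in m above MLLW)."""
    raw = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in raw.columns}
    ts_col = cols.get("timestamp") or cols.get("date time") or list(raw.columns)[0]
    level_col = (
        cols.get("tide_height")
        or cols.get("water level")
        or cols.get("water_level")
        or list(raw.columns)[1]
    )
    idx = _parse_timestamps(raw[ts_col])
    return pd.Series(raw[level_col].to_numpy(dtype=float), index=idx, name="tide_height")
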