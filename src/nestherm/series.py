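"""Hourly temperature series: the common currency between modules.

A temperature series is a :class:`pandas.Series` of degrees Celsius indexed by
an hourly :class:`pandas.DatetimeIndex`; the series ``name`` identifies the
measurement location (e.g. ``"adjacent"``, ``"above"``, ``"centre"``).  The
on-disk dialect is a headered CSV with columns ``timestamp`` (ISO-8601),
``temp_c`` and optionally ``location``, matching the layout of field-logger
exports so synthetic and measured data are interchangeable.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "hourly_index",
    "ensure_hourly",
    "read_temperature_csv",
    "write_temperature_csv",
    "eight_hourly",
]


def hourly_index(start: str | pd.Timestamp, n_hours: int) -> pd.DatetimeIndex:
    """An hourly DatetimeIndex of ``n_hours`` stamps starting at ``start``."""
    return pd.date_range(pd.Timestamp(start), periods=n_hours, freq="h")


def ensure_hourly(series: pd.Series) -> pd.Series:
    """Validate that ``series`` has a strictly hourly DatetimeIndex."""
    idx = series.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise TypeError("temperature series must be indexed by timestamps")
    if len(idx) > 1:
        deltas = idx.to_series().diff().dropna().unique()
        if len(deltas) != 1 or deltas[0] != pd.Timedelta(hours=1):
            raise ValueError("temperature series must have a 1-hour cadence")
    return series


def read_temperature_csv(path) -> pd.Series | dict[str, pd.Series]:
    """Read a logger CSV.

    Returns a single series, or a ``{location: series}`` dict when the file
    carries a ``location`` column with more than one distinct value.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "temp_c" not in df.columns:
        raise ValueError(f"{path}: expected columns timestamp,temp_c[,location]")
    if "location" in df.columns and df["location"].nunique() > 1:
        out: dict[str, pd.Series] = {}
        for loc, grp in df.groupby("location", sort=False):
            out[str(loc)] = pd.Series(
                grp["temp_c"].to_numpy(), index=pd.DatetimeIndex(grp["timestamp"]), name=str(loc)
            )
        return out
    name = str(df["location"].iloc[0]) if "location" in df.columns and len(df) else None
    return pd.Series(df["temp_c"].to_numpy(), index=pd.DatetimeIndex(df["timestamp"]), name=name)


def write_temperature_csv(series: pd.Series | dict[str, pd.Series], path) -> None:
    """Write one or several series in the field CSV dialect."""
    if isinstance(series, dict):
        frames = [
            pd.DataFrame({"timestamp": s.index, "temp_c": s.to_numpy(), "location": loc})
            for loc, s in series.items()
        ]
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame({"timestamp": series.index, "temp_c": series.to_numpy()})
        if series.name:
            df["location"] = series.name
    df.to_csv(path, index=False, float_format="%.6f")


def eight_hourly(series: pd.Series) -> pd.Series:
    """Subsample to the 00:00 / 08:00 / 16:00 stamps used for model validation."""
    mask = (series.index.hour % 8 == 0) & (series.index.minute == 0)
    return series[mask]
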