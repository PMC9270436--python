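"""Reading and writing chronic band-power series.

Two interchangeable on-disk formats:

* **csv** — one record per sample with header
  ``timestamp_utc,value_uvp,subject,hemisphere,band_center_hz,band_width_hz``
  and ISO-8601 timestamps (offset included).
* **device_json** — a simplified device-export layout: a ``metadata`` block
  (subject, hemisphere, band, sample interval) plus a ``samples`` array of
  ``{"ts": <iso>, "value": <float>}`` records.

Both round-trip timestamps and values losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .series import BandPowerSeries, BandSpec

__all__ = ["read_series", "write_series", "to_local_time",
           "CSV_COLUMNS", "read_diary", "write_diary"]

CSV_COLUMNS = ["timestamp_utc", "value_uvp", "subject", "hemisphere",
               "band_center_hz", "band_width_hz"]


def _meta_from_frame(df: pd.DataFrame, path) -> dict:
    meta = {}
    for col, key in [("subject", "subject_id"), ("hemisphere", "hemisphere")]:
        vals = df[col].unique()
        if len(vals) > 1:
            raise ParseError(f"{path}: column {col!r} is not constant")
        meta[key] = vals[0]
    for col in ("band_center_hz", "band_width_hz"):
        vals = df[col].unique()
        if len(vals) > 1:
            raise ParseError(f"{path}: column {col!r} is not constant")
    meta["band"] = BandSpec(float(df["band_center_hz"].iloc[0]),
                            float(df["band_width_hz"].iloc[0]))
    return meta


def read_series(path, format: str = "csv") -> BandPowerSeries:
    """Read a band-power series from ``path``.

    Rejects schema violations (with the offending record), negative power
    values and non-monotone timestamps.
    """
    path = Path(path)
    if format == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:
            raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        if df.empty:
            return BandPowerSeries(pd.DatetimeIndex([], tz="UTC"), [])
        try:
            ts = pd.to_datetime(df["timestamp_utc"], utc=True, format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: bad timestamp ({exc})") from exc
        values = pd.to_numeric(df["value_uvp"], errors="coerce")
        if values.isna().any():
            row = int(values.isna().idxmax())
            raise ParseError(f"{path}: non-numeric value_uvp at data row {row}")
        meta = _meta_from_frame(df, path)
        series = BandPowerSeries(pd.DatetimeIndex(ts), values.to_numpy(), **meta)
    elif format == "device_json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(payload, dict) or "samples" not in payload:
            raise ParseError(f"{path}: expected object with a 'samples' array")
        md = payload.get("metadata", {})
        recs = payload["samples"]
        try:
            ts = pd.to_datetime([r["ts"] for r in recs], utc=True)
            values = np.array([float(r["value"]) for r in recs])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad sample record ({exc})") from exc
        band = BandSpec(float(md.get("band_center_hz", 25.0)),
                        float(md.get("band_width_hz", 5.0)))
        series = BandPowerSeries(
            pd.DatetimeIndex(ts), values,
            subject_id=md.get("subject", "unknown"),
            hemisphere=md.get("hemisphere", "left"), band=band,
            sample_interval=pd.Timedelta(
                minutes=float(md.get("sample_interval_min", 10))))
    else:
        raise ParseError(f"unknown series format {format!r}")
    return series.require_nonnegative()


def write_series(series: BandPowerSeries, path, format: str = "csv") -> None:
    """Write ``series`` to ``path`` losslessly (full float precision)."""
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame({
            "timestamp_utc": [t.isoformat() for t in series.timestamps],
            "value_uvp": series.values,
            "subject": series.subject_id,
            "hemisphere": series.hemisphere,
            "band_center_hz": series.band.center_hz,
            "band_width_hz": series.band.width_hz,
        }, columns=CSV_COLUMNS)
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "device_json":
        payload = {
            "metadata": {
                "subject": series.subject_id,
                "hemisphere": series.hemisphere,
                "band_center_hz": series.band.center_hz,
                "band_width_hz": series.band.width_hz,
                "sample_interval_min":
                    series.sample_interval.total_seconds() / 60.0,
            },
            "samples": [{"ts": t.isoformat(), "value": v}
                        for t, v in zip(series.timestamps, series.values)],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ParseError(f"unknown series format {format!r}")


def to_local_time(series: BandPowerSeries, tz_name: str) -> BandPowerSeries:
    """Convert timestamps to the civil time of an IANA zone.

    The underlying instants are unchanged; only clock labels move, including
    across daylight-saving transitions (a civil day may then hold 23 h or
    25 h of samples).
    """
    return series.tz_convert(tz_name)


# --------------------------------------------------------------- sleep diaries

def read_diary(path) -> pd.DataFrame:
    """Read a sleep diary CSV with columns ``date,bed_time,rise_time``.

    Times are local clock strings; an interval whose rise time is earlier
    than its bed time is taken to cross midnight.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse diary CSV ({exc})") from exc
    missing = [c for c in ("date", "bed_time", "rise_time") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing diary columns {missing}")
    return df


def write_diary(diary, path) -> None:
    diary.to_frame().to_csv(path, index=False)
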