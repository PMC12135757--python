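"""Reading, validating, writing, and minute-resampling of instrument logs.

Three log dialects are supported, all plain CSV with one header line,
'.' decimal separator and timezone-naive ISO-8601 timestamps
(``YYYY-MM-DDTHH:MM:SS``; the studies this package targets are
single-site, so local time is used throughout):

* ``wearable`` — 5-s records from a halter-mounted optical monitor:
  ``timestamp,pm1,pm2_5,pm10,n_gt_0_3,n_gt_0_5,n_gt_1_0,n_gt_2_5,
  n_gt_5_0,n_gt_10,temp_c,rh_pct,lat,lon``.  PM masses are μg/m³,
  the six ``n_gt_*`` columns are cumulative particle counts per 0.1 L
  above the named diameter, and lat/lon may be empty (indoor use).
* ``teom`` / ``comparison`` — 1-min records ``timestamp,value`` from the
  reference microbalance or the fast optical comparison monitor, with a
  sidecar metadata comment line ``# unit_id=...,size_fraction=...``
  preceding the header.

Validation enforces the physical record invariants: non-negative
concentrations, ``pm1 <= pm2_5 <= pm10``, cumulative number bins
non-increasing with threshold diameter, and relative humidity in
[0, 100].  Out-of-order timestamps are sorted with a warning (SD-card
field logs commonly contain boot-time rewinds); duplicate timestamps are
ambiguous and rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UnitSeries",
    "LogFormatError",
    "LogValidationError",
    "WEARABLE_COLUMNS",
    "NUMBER_BIN_COLUMNS",
    "VALUE_COLUMNS",
    "read_log",
    "write_log",
    "resample_to_minutes",
    "validate_records",
]

WEARABLE_COLUMNS = [
    "timestamp",
    "pm1",
    "pm2_5",
    "pm10",
    "n_gt_0_3",
    "n_gt_0_5",
    "n_gt_1_0",
    "n_gt_2_5",
    "n_gt_5_0",
    "n_gt_10",
    "temp_c",
    "rh_pct",
    "lat",
    "lon",
]
NUMBER_BIN_COLUMNS = ["n_gt_0_3", "n_gt_0_5", "n_gt_1_0", "n_gt_2_5", "n_gt_5_0", "n_gt_10"]
VALUE_COLUMNS = ["timestamp", "value"]

#: nominal sampling interval (s) per instrument kind
CADENCE_S = {"wearable": 5, "teom": 60, "comparison": 60}

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class LogFormatError(ValueError):
    """Malformed file: wrong header, unparsable row, bad metadata line."""


class LogValidationError(ValueError):
    """A structurally well-formed record violates a physical invariant."""


@dataclass
class UnitSeries:
    """Time-ordered records from one instrument.

    ``records`` is a DataFrame with a ``timestamp`` column (datetime64)
    and either the full wearable column set or a single ``value`` column
    for teom/comparison instruments.
    """

    unit_id: str
    instrument_kind: str  # wearable | teom | comparison
    size_fraction: str  # pm2_5 | pm10 | both
    cadence_s: int
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.instrument_kind not in CADENCE_S:
            raise ValueError(f"unknown instrument_kind {self.instrument_kind!r}")
        if self.size_fraction not in {"pm2_5", "pm10", "both"}:
            raise ValueError(f"unknown size_fraction {self.size_fraction!r}")

    def value_column(self, channel: str | None = None) -> str:
        """Resolve the concentration column to analyse."""
        if self.instrument_kind == "wearable":
            if channel is None:
                raise ValueError("wearable series need an explicit channel (pm2_5 or pm10)")
            return channel
        return "value"

    def __eq__(self, other: object) -> bool:  # frame-aware equality
        if not isinstance(other, UnitSeries):
            return NotImplemented
        if (self.unit_id, self.instrument_kind, self.size_fraction, self.cadence_s) != (
            other.unit_id,
            other.instrument_kind,
            other.size_fraction,
            other.cadence_s,
        ):
            return False
        try:
            pd.testing.assert_frame_equal(self.records, other.records, check_exact=True)
        except AssertionError:
            return False
        return True

    def copy(self) -> "UnitSeries":
        return replace(self, records=self.records.copy())


def _check_nonincreasing_bins(df: pd.DataFrame) -> pd.Series:
    bins = df[NUMBER_BIN_COLUMNS].to_numpy(dtype=float)
    return pd.Series((np.diff(bins, axis=1) > 1e-9).any(axis=1), index=df.index)


def validate_records(df: pd.DataFrame, instrument_kind: str) -> None:
    """Raise :class:`LogValidationError` naming the first offending record."""
    if instrument_kind == "wearable":
        for col in ("pm1", "pm2_5", "pm10"):
            bad = df.index[df[col] < 0]
            if len(bad):
                raise LogValidationError(f"negative {col} at record {bad[0]}")
        bad = df.index[(df["pm1"] > df["pm2_5"] + 1e-9) | (df["pm2_5"] > df["pm10"] + 1e-9)]
        if len(bad):
            row = df.loc[bad[0]]
            raise LogValidationError(
                f"size-fraction ordering violated at record {bad[0]}: "
                f"pm1={row['pm1']}, pm2_5={row['pm2_5']}, pm10={row['pm10']}"
            )
        bad = df.index[_check_nonincreasing_bins(df)]
        if len(bad):
            raise LogValidationError(
                f"cumulative number bins increase with threshold at record {bad[0]}: "
                f"{df.loc[bad[0], NUMBER_BIN_COLUMNS].tolist()}"
            )
        bad = df.index[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)]
        if len(bad):
            raise LogValidationError(f"rh_pct outside [0, 100] at record {bad[0]}")
    else:
        bad = df.index[df["value"] < 0]
        if len(bad):
            raise LogValidationError(f"negative value at record {bad[0]}")


def _order_timestamps(df: pd.DataFrame, where: str) -> pd.DataFrame:
    if df["timestamp"].duplicated().any():
        dup = df["timestamp"][df["timestamp"].duplicated()].iloc[0]
        raise LogValidationError(f"duplicate timestamp {dup} in {where}")
    if not df["timestamp"].is_monotonic_increasing:
        logger.warning("out-of-order timestamps in %s; sorting", where)
        df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    return df


def read_log(path: str | Path, dialect: str) -> UnitSeries:
    """Read one instrument log.

    ``dialect`` is the instrument kind (``wearable``, ``teom`` or
    ``comparison``) and fixes the expected column set.
    """
    path = Path(path)
    if dialect not in CADENCE_S:
        raise ValueError(f"unknown dialect {dialect!r}")

    unit_id = path.stem
    size_fraction = "both" if dialect == "wearable" else "pm2_5"
    skip = 0
    if dialect != "wearable":
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
        if not first.startswith("# "):
            raise LogFormatError(f"{path}:1: expected '# unit_id=...,size_fraction=...' metadata line")
        try:
            meta = dict(item.split("=", 1) for item in first[2:].split(","))
            unit_id = meta["unit_id"]
            size_fraction = meta["size_fraction"]
        except (ValueError, KeyError) as exc:
            raise LogFormatError(f"{path}:1: malformed metadata line: {first!r}") from exc
        skip = 1

    expected = WEARABLE_COLUMNS if dialect == "wearable" else VALUE_COLUMNS
    try:
        df = pd.read_csv(
            path,
            skiprows=skip,
            dtype={c: float for c in expected if c != "timestamp"},
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise LogFormatError(f"{path}: unparsable row: {exc}") from exc
    if list(df.columns) != expected:
        raise LogFormatError(f"{path}: header {list(df.columns)} does not match {dialect} dialect {expected}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT)
    except ValueError as exc:
        raise LogFormatError(f"{path}: bad timestamp: {exc}") from exc

    df = _order_timestamps(df, str(path))
    validate_records(df, dialect)
    return UnitSeries(
        unit_id=unit_id,
        instrument_kind=dialect,
        size_fraction=size_fraction,
        cadence_s=CADENCE_S[dialect],
        records=df.reset_index(drop=True),
    )


def write_log(series: UnitSeries, path: str | Path) -> Path:
    """Write a series in its dialect; ``read_log(write_log(s)) == s``."""
    path = Path(path)
    df = series.records.copy()
    df["timestamp"] = df["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    for col in df.columns:
        if df[col].dtype.kind == "f":  # shortest round-trippable decimal form
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    with open(path, "w", newline="") as fh:
        if series.instrument_kind != "wearable":
            fh.write(f"# unit_id={series.unit_id},size_fraction={series.size_fraction}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def resample_to_minutes(
    series: UnitSeries,
    channel: str | None = None,
    min_coverage: float = 0.75,
) -> pd.DataFrame:
    """Arithmetic 1-min averages of one concentration channel.

    Samples are binned into ``[minute, minute + 60 s)``.  Returns a frame
    with columns ``minute_start``, ``value``, ``n_samples`` and
    ``complete``; a minute is complete when it holds at least
    ``min_coverage`` of the samples its cadence implies (>= 9 of 12 at
    5-s cadence).  Incomplete minutes are excluded from downstream
    rolling-CV windows.  A series already at 1-min cadence maps through
    unchanged (every minute complete with one sample).
    """
    col = series.value_column(channel)
    if series.records.empty:
        return pd.DataFrame(columns=["minute_start", "value", "n_samples", "complete"])
    expected = max(1, round(60 / series.cadence_s))
    minute = series.records["timestamp"].dt.floor("min")
    grouped = series.records.groupby(minute)[col].agg(["mean", "size"])
    out = pd.DataFrame(
        {
            "minute_start": grouped.index,
            "value": grouped["mean"].to_numpy(),
            "n_samples": grouped["size"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["complete"] = out["n_samples"] >= min_coverage * expected
    return out
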