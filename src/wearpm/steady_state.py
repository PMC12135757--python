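"""Quasi-steady-state detection, reference-lag estimation, interval matching.

A slow gravimetric-equivalent reference (TEOM) can only be compared with
fast optical monitors while the chamber concentration is stable.  A
quasi-steady-state interval is found on the 1-min averaged reference
series: every rolling window of at least ``min_duration_min`` minutes
must have a coefficient of variation (sample SD / mean) below
``cv_threshold`` (default 1%).  Maximal qualifying runs are then reduced
to consecutive non-overlapping 5-min reporting intervals taken from the
run start, which keeps the regression observations disjoint.

The reference's response lag is estimated against a fast comparison
monitor by the argmax over integer minute shifts of the Pearson
correlation, ties broken toward the smaller lag.  Sign convention
throughout: the reference LAGS the room air, so when a reference segment
``[a, b)`` is matched to the fast instruments their averaging window is
shifted *earlier*, to ``[a - lag, b - lag)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_logs import UnitSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SteadySegment",
    "LagEstimate",
    "MatchedInterval",
    "InsufficientDataError",
    "rolling_cv",
    "detect_steady_segments",
    "estimate_lag",
    "build_matched_intervals",
]


class InsufficientDataError(ValueError):
    """Not enough overlapping or covering data for the requested estimate."""


@dataclass(frozen=True)
class SteadySegment:
    """One quasi-steady reporting interval on the reference series."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: int
    teom_mean: float
    cv: float


@dataclass(frozen=True)
class LagEstimate:
    lag_min: int  # reference lags the comparison monitor by this many minutes
    peak_correlation: float


@dataclass
class MatchedInterval:
    """Lag-aligned per-instrument means over one steady interval."""

    segment: SteadySegment
    teom_mean: float
    unit_means: dict[str, float] = field(default_factory=dict)
    comparison_mean: float | None = None


def _contiguous_runs(minutes: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a minute frame at gaps and at incomplete minutes."""
    if minutes.empty:
        return []
    ok = minutes[minutes.get("complete", True) == True]  # noqa: E712  (column may be absent)
    if ok.empty:
        return []
    step = ok["minute_start"].diff().dt.total_seconds().fillna(60.0)
    group = (step != 60.0).cumsum()
    return [g.reset_index(drop=True) for _, g in ok.groupby(group)]


def rolling_cv(minutes: pd.DataFrame, window_min: int) -> pd.DataFrame:
    """Sample CV over every contiguous window of ``window_min`` minutes.

    Returns columns ``window_start`` and ``cv``.  Windows whose mean is
    non-positive are undefined and skipped; gaps and incomplete minutes
    split windows.
    """
    if window_min < 2:
        raise ValueError("window_min must be >= 2")
    frames = []
    for run in _contiguous_runs(minutes):
        if len(run) < window_min:
            continue
        vals = run["value"].to_numpy(dtype=float)
        roll = pd.Series(vals).rolling(window_min)
        mean = roll.mean().to_numpy()[window_min - 1 :]
        sd = roll.std(ddof=1).to_numpy()[window_min - 1 :]
        starts = run["minute_start"].to_numpy()[: len(vals) - window_min + 1]
        keep = mean > 0
        frames.append(pd.DataFrame({"window_start": starts[keep], "cv": (sd / mean)[keep]}))
    if not frames:
        return pd.DataFrame(columns=["window_start", "cv"])
    return pd.concat(frames, ignore_index=True)


def detect_steady_segments(
    minutes: pd.DataFrame,
    cv_threshold: float = 0.01,
    min_duration_min: int = 5,
) -> list[SteadySegment]:
    """Disjoint steady 5-min (``min_duration_min``) reporting intervals.

    A maximal run is a stretch of consecutive complete minutes in which
    every full-length window has CV below threshold; each run is chopped
    into ``floor(run/min_duration_min)`` disjoint intervals from its
    start.  Each interval carries its own mean and CV.
    """
    w = min_duration_min
    segments: list[SteadySegment] = []
    for run in _contiguous_runs(minutes):
        n = len(run)
        if n < w:
            continue
        vals = run["value"].to_numpy(dtype=float)
        roll = pd.Series(vals).rolling(w)
        mean = roll.mean().to_numpy()[w - 1 :]
        sd = roll.std(ddof=1).to_numpy()[w - 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = (mean > 0) & (sd / mean < cv_threshold)
        # ok[s] qualifies window of minutes [s, s+w); merge overlapping
        # qualifying windows into maximal steady runs of minutes
        s = 0
        n_win = len(ok)
        while s < n_win:
            if not ok[s]:
                s += 1
                continue
            e = s
            while e + 1 < n_win and ok[e + 1]:
                e += 1
            first_minute, last_minute = s, e + w  # minutes [first, last)
            length = last_minute - first_minute
            for k in range(length // w):
                lo = first_minute + k * w
                hi = lo + w
                chunk = vals[lo:hi]
                m = float(chunk.mean())
                segments.append(
                    SteadySegment(
                        start=run["minute_start"].iloc[lo],
                        end=run["minute_start"].iloc[hi - 1] + pd.Timedelta(minutes=1),
                        duration_min=w,
                        teom_mean=m,
                        cv=float(chunk.std(ddof=1) / m),
                    )
                )
            s = e + 1
    return segments


def estimate_lag(
    reference: pd.DataFrame,
    comparison: pd.DataFrame,
    max_lag_min: int = 15,
    min_overlap_min: int = 30,
) -> LagEstimate:
    """Integer-minute response lag of the reference instrument.

    ``lag = argmax_k r(comparison(t), reference(t + k))`` over
    ``k in [0, max_lag_min]``, ties toward smaller ``k``.
    """
    ref = reference.set_index("minute_start")["value"]
    cmp_ = comparison.set_index("minute_start")["value"]
    best_k, best_r = None, -np.inf
    for k in range(max_lag_min + 1):
        shifted = ref.copy()
        shifted.index = shifted.index - pd.Timedelta(minutes=k)
        joined = pd.concat([cmp_, shifted], axis=1, join="inner", keys=["c", "r"]).dropna()
        if len(joined) < min_overlap_min:
            raise InsufficientDataError(
                f"only {len(joined)} overlapping minutes at lag {k}; need >= {min_overlap_min}"
            )
        r = float(np.corrcoef(joined["c"], joined["r"])[0, 1])
        if r > best_r:
            best_k, best_r = k, r
    return LagEstimate(lag_min=int(best_k), peak_correlation=best_r)


def _window_mean(series: UnitSeries, channel: str | None, start: pd.Timestamp, end: pd.Timestamp,
                 min_coverage: float = 0.75) -> float | None:
    col = series.value_column(channel)
    ts = series.records["timestamp"]
    sel = series.records.loc[(ts >= start) & (ts < end), col]
    expected = (end - start).total_seconds() / series.cadence_s
    if len(sel) < min_coverage * expected:
        return None
    return float(sel.mean())


def build_matched_intervals(
    segments: list[SteadySegment],
    lag_min: int,
    wearables: list[UnitSeries],
    comparison: UnitSeries | None,
    channel: str,
) -> list[MatchedInterval]:
    """Per-instrument means over each steady interval, lag-aligned.

    The fast instruments (wearables, comparison) are averaged over
    ``[start - lag, end - lag)``; intervals in which any instrument is
    missing more than 25% of its expected samples are dropped with a
    logged reason.  ``channel`` selects the wearable column matching the
    reference's size fraction.
    """
    shift = pd.Timedelta(minutes=lag_min)
    out: list[MatchedInterval] = []
    for seg in segments:
        a, b = seg.start - shift, seg.end - shift
        unit_means: dict[str, float] = {}
        complete = True
        for unit in wearables:
            m = _window_mean(unit, channel, a, b)
            if m is None:
                logger.info("dropping interval %s: unit %s covers <75%% of %s–%s", seg.start, unit.unit_id, a, b)
                complete = False
                break
            unit_means[unit.unit_id] = m
        if not complete:
            continue
        comp_mean = None
        if comparison is not None:
            comp_mean = _window_mean(comparison, None, a, b)
            if comp_mean is None:
                logger.info("dropping interval %s: comparison covers <75%%", seg.start)
                continue
        out.append(
            MatchedInterval(
                segment=seg,
                teom_mean=seg.teom_mean,
                unit_means=unit_means,
                comparison_mean=comp_mean,
            )
        )
    return out
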