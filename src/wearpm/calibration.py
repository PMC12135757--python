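"""Linear calibration of wearable units against the reference, and precision.

The reference (TEOM) mean of each steady interval is regressed on the
raw wearable mean — univariate OLS with intercept — giving a correction
``corrected = slope * raw + intercept`` per unit.  Averaging the three
units' interval means first and regressing once more yields the
"universal" calibration applicable to any unit of the monitor family.

Precision across co-located units is summarised two ways: a pooled
inter-unit CV (root-mean-square over intervals of the per-interval
cross-unit sample-SD/mean) and the pairwise Pearson correlation matrix
of interval means.

RMSE is reported in the sqrt(SSE/n) (population) convention common in
sensor-calibration work; the serialized model states the convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io_logs import UnitSeries
from .steady_state import MatchedInterval

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "PrecisionReport",
    "fit_ols",
    "shapiro_wilk",
    "fit_universal",
    "fit_per_unit",
    "apply_calibration",
    "interunit_cv",
    "pairwise_correlations",
    "precision_report",
]


@dataclass(frozen=True)
class CalibrationModel:
    """One fitted correction ``corrected = slope * raw + intercept``."""

    size_fraction: str
    unit_id: str  # a unit label, or "averaged" for the universal model
    slope: float
    intercept: float
    r2: float
    rmse: float  # μg/m³, sqrt(SSE/n)
    n_obs: int
    p_slope: float
    shapiro_w: float
    shapiro_p: float

    def correct(self, raw):
        return self.slope * np.asarray(raw, dtype=float) + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["rmse_ug_m3"] = d.pop("rmse")
        d["rmse_convention"] = "sse_over_n"
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        d["rmse"] = d.pop("rmse_ug_m3")
        d.pop("rmse_convention", None)
        return cls(**d)


@dataclass
class PrecisionReport:
    size_fraction: str
    cv_percent: float
    pairwise_r: pd.DataFrame  # symmetric, unit labels on both axes
    n_intervals: int

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "size_fraction": self.size_fraction,
            "cv_percent": self.cv_percent,
            "n_intervals": self.n_intervals,
            "units": list(self.pairwise_r.columns),
            "pairwise_r": self.pairwise_r.to_numpy().tolist(),
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def fit_ols(x, y, size_fraction: str = "pm2_5", unit_id: str = "unit") -> CalibrationModel:
    """OLS of reference means ``y`` on raw unit means ``x``, with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = res.resid
    rmse = float(np.sqrt(np.mean(resid**2)))
    if len(resid) >= 3 and np.ptp(resid) > 0:
        w, p = shapiro_wilk(resid)
    else:
        w, p = float("nan"), float("nan")
    return CalibrationModel(
        size_fraction=size_fraction,
        unit_id=unit_id,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        rmse=rmse,
        n_obs=int(len(x)),
        p_slope=float(res.pvalues[1]),
        shapiro_w=w,
        shapiro_p=p,
    )


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro–Wilk normality statistic and p-value for model residuals."""
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro–Wilk defined for 3 <= n <= 5000, got {n}")
    w, p = scipy.stats.shapiro(residuals)
    return float(w), float(p)


def _interval_table(matched: list[MatchedInterval]) -> pd.DataFrame:
    """teom mean + one column per unit, one row per matched interval."""
    rows = []
    for mi in matched:
        row = {"teom": mi.teom_mean, **mi.unit_means}
        rows.append(row)
    return pd.DataFrame(rows)


def fit_per_unit(matched: list[MatchedInterval], size_fraction: str) -> dict[str, CalibrationModel]:
    """One calibration per wearable unit over the matched intervals."""
    tab = _interval_table(matched).dropna()
    units = [c for c in tab.columns if c != "teom"]
    return {
        u: fit_ols(tab[u], tab["teom"], size_fraction=size_fraction, unit_id=u) for u in units
    }


def fit_universal(matched: list[MatchedInterval], size_fraction: str) -> CalibrationModel:
    """Calibration of the across-unit mean reading (unit_id ``averaged``).

    A fresh regression on the per-interval arithmetic mean of the unit
    means — not the average of the per-unit coefficients.  Intervals
    missing any unit are excluded (logged).
    """
    tab = _interval_table(matched)
    n0 = len(tab)
    tab = tab.dropna()
    if len(tab) < n0:
        logger.info("fit_universal: excluded %d intervals missing a unit", n0 - len(tab))
    if len(tab) < 3:
        raise ValueError(f"need >= 3 complete intervals, got {len(tab)}")
    units = [c for c in tab.columns if c != "teom"]
    mean_raw = tab[units].mean(axis=1)
    return fit_ols(mean_raw, tab["teom"], size_fraction=size_fraction, unit_id="averaged")


def apply_calibration(model: CalibrationModel, series: UnitSeries) -> UnitSeries:
    """Affine correction of the channel matching the model's size fraction.

    Values are NOT floored per-sample: the correction is affine, so
    window means may be corrected directly, and flooring happens only at
    the reporting (window-mean) stage.
    """
    out = series.copy()
    col = series.value_column(model.size_fraction if series.instrument_kind == "wearable" else None)
    if series.instrument_kind == "wearable" and model.size_fraction not in ("pm2_5", "pm10"):
        raise ValueError(f"cannot apply a {model.size_fraction} model to a wearable channel")
    if series.instrument_kind != "wearable" and series.size_fraction not in (model.size_fraction, "both"):
        raise ValueError(
            f"size fraction mismatch: model {model.size_fraction}, series {series.size_fraction}"
        )
    out.records[col] = model.correct(out.records[col].to_numpy())
    return out


def interunit_cv(matched: list[MatchedInterval], size_fraction: str = "") -> float:
    """Pooled inter-unit CV in percent.

    Per interval, CV = cross-unit sample SD / cross-unit mean; pooled by
    root-mean-square over intervals.  Intervals with non-positive
    cross-unit mean are excluded (logged).
    """
    tab = _interval_table(matched).dropna()
    units = [c for c in tab.columns if c != "teom"]
    if len(units) < 2 or len(tab) < 2:
        raise ValueError("need >= 2 units and >= 2 intervals")
    vals = tab[units].to_numpy(dtype=float)
    means = vals.mean(axis=1)
    keep = means > 0
    if (~keep).any():
        logger.info("interunit_cv: excluded %d intervals with non-positive mean", int((~keep).sum()))
    cvs = vals[keep].std(axis=1, ddof=1) / means[keep]
    return float(100.0 * np.sqrt(np.mean(cvs**2)))


def pairwise_correlations(matched: list[MatchedInterval], size_fraction: str = "") -> pd.DataFrame:
    """Pearson r between every unit pair's interval means.

    Constant units yield undefined (NaN) off-diagonal entries.
    """
    tab = _interval_table(matched).dropna()
    units = [c for c in tab.columns if c != "teom"]
    if len(tab) < 3:
        raise ValueError(f"need >= 3 intervals, got {len(tab)}")
    mat = pd.DataFrame(np.eye(len(units)), index=units, columns=units)
    for i, a in enumerate(units):
        for b in units[i + 1 :]:
            xa, xb = tab[a].to_numpy(), tab[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                r = float("nan")
            else:
                r = float(scipy.stats.pearsonr(xa, xb).statistic)
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def precision_report(matched: list[MatchedInterval], size_fraction: str) -> PrecisionReport:
    tab = _interval_table(matched).dropna()
    return PrecisionReport(
        size_fraction=size_fraction,
        cv_percent=interunit_cv(matched),
        pairwise_r=pairwise_correlations(matched),
        n_intervals=len(tab),
    )
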