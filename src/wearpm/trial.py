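"""Windowed exposure averages and lognormal repeated-measures models.

Each horse-day log yields two calibrated exposure averages per size
fraction: the *short* window (first 20 min after forage is offered —
the eating peak) and the *extended* window (the full 8 h).  Treatment
effects are estimated with a linear mixed model on the natural log of
the window means with a random horse intercept — the standard
formulation of a "repeated-measures model under a lognormal
assumption"; for two occasions per horse it coincides with the
compound-symmetry repeated-measures model.  Estimation is REML
(statsmodels ``MixedLM``); the cross-over design is balanced after
exclusions, so the small-sample (Satterthwaite) denominator degrees of
freedom have closed forms: ``n - 1`` for the within-horse treatment
contrast in the two-cell model, ``(k - 1)(n - 1)`` for within-horse
contrasts among ``k`` cells, and the two-component Satterthwaite
combination for least-squares-mean intervals.  Least-squares means are
back-transformed by exponentiation, estimating geometric-mean-like
exposures; with >1 pairwise comparison (the 2x2 treatment-by-duration
model) p-values are Tukey-adjusted via the studentized range.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .calibration import CalibrationModel
from .io_logs import UnitSeries
from .steady_state import InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureRecord",
    "TrialModelResult",
    "WINDOW_MINUTES",
    "window_exposure",
    "exposure_table",
    "fit_treatment_model",
    "fit_duration_model",
    "percent_reduction",
    "plot_lsmeans",
]

WINDOW_MINUTES = {"short": 20, "extended": 480}
#: zero window means (possible after flooring) are replaced by this before logging
ZERO_REPLACEMENT_UG_M3 = 0.1


@dataclass(frozen=True)
class ExposureRecord:
    """One horse-day-window calibrated exposure average."""

    horse_id: str
    treatment: str  # dry | soaked
    metric: str  # pm2_5 | pm10
    window: str  # short | extended
    mean_conc: float  # μg/m³, floored at 0
    n_samples: int


@dataclass
class TrialModelResult:
    """Back-transformed least-squares means and effect tests for one model."""

    metric: str
    model_kind: str  # treatment_only | treatment_x_duration
    window: str | None  # set for treatment_only models
    lsmeans: dict[str, tuple[float, float, float]]  # cell -> (mean, lo95, hi95), μg/m³
    effects: dict[str, float]  # effect name -> p-value
    pairwise_tukey: dict[str, float] = field(default_factory=dict)
    sd_horse_log: float = float("nan")
    sd_resid_log: float = float("nan")
    n_horses: int = 0
    degenerate: bool = False  # zero-variance input; p-values undefined

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "metric": self.metric,
            "model_kind": self.model_kind,
            "window": self.window,
            "lsmeans_ug_m3": {k: list(v) for k, v in self.lsmeans.items()},
            "p_values": self.effects,
            "pairwise_tukey_p": self.pairwise_tukey,
            "sd_horse_log": self.sd_horse_log,
            "sd_resid_log": self.sd_resid_log,
            "n_horses": self.n_horses,
            "confidence_level": 0.95,
        }
        text = json.dumps(d, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def window_exposure(
    log: UnitSeries,
    model: CalibrationModel,
    feed_time: pd.Timestamp,
    window: str,
    horse_id: str | None = None,
    treatment: str | None = None,
    min_coverage: float = 0.75,
) -> ExposureRecord:
    """Calibrated mean over ``[feed_time, feed_time + window)``.

    The raw 5-s values are averaged arithmetically, the affine
    calibration is applied to the window mean (equivalent to per-sample
    correction), and the result is floored at 0.
    """
    if window not in WINDOW_MINUTES:
        raise ValueError(f"window must be one of {sorted(WINDOW_MINUTES)}")
    feed_time = pd.Timestamp(feed_time)
    end = feed_time + pd.Timedelta(minutes=WINDOW_MINUTES[window])
    col = log.value_column(model.size_fraction)
    ts = log.records["timestamp"]
    sel = log.records.loc[(ts >= feed_time) & (ts < end), col]
    expected = WINDOW_MINUTES[window] * 60 / log.cadence_s
    if len(sel) < min_coverage * expected:
        raise InsufficientDataError(
            f"log {log.unit_id} covers {len(sel)}/{expected:.0f} samples of "
            f"[{feed_time}, {end}); need >= {min_coverage:.0%}"
        )
    corrected = float(model.correct(sel.mean()))
    if horse_id is None or treatment is None:
        parts = log.unit_id.rsplit("_", 1)
        horse_id = horse_id or parts[0]
        treatment = treatment or (parts[1] if len(parts) > 1 else "unknown")
    return ExposureRecord(
        horse_id=horse_id,
        treatment=treatment,
        metric=model.size_fraction,
        window=window,
        mean_conc=max(0.0, corrected),
        n_samples=int(len(sel)),
    )


def exposure_table(
    logs: dict[tuple[str, str], UnitSeries],
    metadata: pd.DataFrame,
    models: dict[str, CalibrationModel],
) -> pd.DataFrame:
    """All horse-day-window-metric exposures as a tidy frame."""
    rows = []
    for _, m in metadata.iterrows():
        log = logs[(m["horse_id"], m["treatment"])]
        for metric, model in models.items():
            for window in WINDOW_MINUTES:
                rec = window_exposure(
                    log, model, pd.Timestamp(m["feed_time"]), window,
                    horse_id=m["horse_id"], treatment=m["treatment"],
                )
                rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def _prepare(df: pd.DataFrame, cells: list[str], cell_col: str) -> pd.DataFrame:
    """Log-transform, replace zeros, enforce the complete cross-over."""
    df = df.copy()
    n_zero = int((df["mean_conc"] <= 0).sum())
    if n_zero:
        logger.info("replacing %d zero window means with %.1f μg/m³ before logging",
                    n_zero, ZERO_REPLACEMENT_UG_M3)
        df.loc[df["mean_conc"] <= 0, "mean_conc"] = ZERO_REPLACEMENT_UG_M3
    df["logy"] = np.log(df["mean_conc"])
    counts = df.groupby("horse_id")[cell_col].nunique()
    unpaired = counts.index[counts < len(cells)]
    if len(unpaired):
        logger.warning("excluding horses without all design cells: %s", list(unpaired))
        df = df[~df["horse_id"].isin(unpaired)]
    n = df["horse_id"].nunique()
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete horses, got {n}")
    return df


def _fit_cell_means(df: pd.DataFrame, cells: list[str], cell_col: str):
    """REML random-intercept fit in the cell-means parametrization.

    Returns (mu: dict cell->log-scale lsmean, sigma2_b, sigma2_e, n, degenerate).
    """
    n = df["horse_id"].nunique()
    # residual variance after horse + cell effects; ~0 means a deterministic
    # (zero-noise) input where the iterative fit degenerates
    pivot = df.pivot_table(index="horse_id", columns=cell_col, values="logy")
    resid = pivot - pivot.mean(axis=0) - np.asarray(pivot.mean(axis=1))[:, None] + pivot.to_numpy().mean()
    if float(np.nanvar(resid.to_numpy())) < 1e-12:
        mu = pivot.mean(axis=0).to_dict()
        sb2 = float(pivot.mean(axis=1).var(ddof=1)) if n > 1 else 0.0
        return mu, sb2, 0.0, n, True
    exog = pd.get_dummies(df[cell_col], dtype=float)[cells]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(df["logy"].to_numpy(), exog.to_numpy(), groups=df["horse_id"].to_numpy())
        res = md.fit(reml=True)
    mu = dict(zip(cells, (float(v) for v in res.fe_params)))
    return mu, float(np.asarray(res.cov_re)[0, 0]), float(res.scale), n, False


def _lsmean_ci(mu_j: float, sb2: float, se2: float, n: int, k: int) -> tuple[float, float, float]:
    """Back-transformed lsmean with 95% CI (Satterthwaite df combination)."""
    var = (sb2 + se2) / n
    if var <= 0:
        return (float(np.exp(mu_j)),) * 3
    ms_b, ms_e = k * sb2 + se2, se2  # expected mean squares, df n-1 and (k-1)(n-1)
    num = (ms_b + (k - 1) * ms_e) ** 2
    den = ms_b**2 / (n - 1) + ((k - 1) * ms_e) ** 2 / max((k - 1) * (n - 1), 1)
    dfree = num / den if den > 0 else n - 1
    half = scipy.stats.t.ppf(0.975, dfree) * np.sqrt(var)
    return float(np.exp(mu_j)), float(np.exp(mu_j - half)), float(np.exp(mu_j + half))


def _contrast_p(L: np.ndarray, mu: np.ndarray, se2: float, n: int, dfree: int) -> float:
    """Two-sided p for a within-horse contrast (sum-zero L on cell means)."""
    var = se2 * float(np.sum(L**2)) / n
    if var <= 0:
        return float("nan")
    t = float(L @ mu) / np.sqrt(var)
    return float(2 * scipy.stats.t.sf(abs(t), dfree))


def fit_treatment_model(records) -> TrialModelResult:
    """Treatment effect on one metric x window (two cells per horse)."""
    df = _records_frame(records)
    metrics, windows = df["metric"].unique(), df["window"].unique()
    if len(metrics) != 1 or len(windows) != 1:
        raise ValueError("fit_treatment_model expects a single metric and window")
    cells = ["dry", "soaked"]
    df = _prepare(df, cells, "treatment")
    mu, sb2, se2, n, degenerate = _fit_cell_means(df, cells, "treatment")
    muv = np.array([mu[c] for c in cells])
    lsmeans = {c: _lsmean_ci(mu[c], sb2, se2, n, 2) for c in cells}
    p = _contrast_p(np.array([1.0, -1.0]), muv, se2, n, n - 1)
    return TrialModelResult(
        metric=str(metrics[0]),
        model_kind="treatment_only",
        window=str(windows[0]),
        lsmeans=lsmeans,
        effects={"treatment": p},
        sd_horse_log=float(np.sqrt(max(sb2, 0.0))),
        sd_resid_log=float(np.sqrt(max(se2, 0.0))),
        n_horses=n,
        degenerate=degenerate,
    )


def fit_duration_model(records) -> TrialModelResult:
    """Treatment, duration and interaction for one metric (four cells)."""
    df = _records_frame(records)
    metrics = df["metric"].unique()
    if len(metrics) != 1:
        raise ValueError("fit_duration_model expects a single metric")
    df["cell"] = df["treatment"] + ":" + df["window"]
    cells = ["dry:short", "dry:extended", "soaked:short", "soaked:extended"]
    missing = set(cells) - set(df["cell"])
    if missing:
        raise ValueError(f"missing design cells: {sorted(missing)}")
    df = _prepare(df, cells, "cell")
    mu, sb2, se2, n, degenerate = _fit_cell_means(df, cells, "cell")
    muv = np.array([mu[c] for c in cells])
    k = 4
    dfree = (k - 1) * (n - 1)
    effects = {
        "treatment": _contrast_p(np.array([0.5, 0.5, -0.5, -0.5]), muv, se2, n, dfree),
        "duration": _contrast_p(np.array([0.5, -0.5, 0.5, -0.5]), muv, se2, n, dfree),
        "interaction": _contrast_p(np.array([1.0, -1.0, -1.0, 1.0]), muv, se2, n, dfree),
    }
    tukey = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(cells), 2):
        if se2 <= 0:
            tukey[f"{a} vs {b}"] = float("nan")
            continue
        t = (muv[i] - muv[j]) / np.sqrt(2 * se2 / n)
        tukey[f"{a} vs {b}"] = float(
            scipy.stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfree)
        )
    lsmeans = {c: _lsmean_ci(mu[c], sb2, se2, n, k) for c in cells}
    return TrialModelResult(
        metric=str(metrics[0]),
        model_kind="treatment_x_duration",
        window=None,
        lsmeans=lsmeans,
        effects=effects,
        pairwise_tukey=tukey,
        sd_horse_log=float(np.sqrt(max(sb2, 0.0))),
        sd_resid_log=float(np.sqrt(max(se2, 0.0))),
        n_horses=n,
        degenerate=degenerate,
    )


def percent_reduction(result: TrialModelResult) -> float:
    """Percent reduction of the soaked-hay lsmean relative to dry hay."""
    ls = result.lsmeans
    if "dry" in ls and "soaked" in ls:
        dry, soaked = ls["dry"][0], ls["soaked"][0]
    else:  # duration model: marginal geometric means over windows
        dry = float(np.exp(np.mean([np.log(v[0]) for c, v in ls.items() if c.startswith("dry")])))
        soaked = float(
            np.exp(np.mean([np.log(v[0]) for c, v in ls.items() if c.startswith("soaked")]))
        )
    return 100.0 * (1.0 - soaked / dry)


def plot_lsmeans(result: TrialModelResult, records=None, path: str | Path | None = None):
    """Least-squares means with 95% CI whiskers and individual horse-days."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = list(result.lsmeans)
    fig, ax = plt.subplots(figsize=(1.4 * len(cells) + 1.5, 4))
    for i, c in enumerate(cells):
        est, lo, hi = result.lsmeans[c]
        ax.errorbar([i], [est], yerr=[[est - lo], [hi - est]], fmt="o", color="k",
                    capsize=4, zorder=3)
    if records is not None:
        df = _records_frame(records)
        key = "treatment" if result.model_kind == "treatment_only" else None
        for i, c in enumerate(cells):
            if key:
                vals = df.loc[df[key] == c, "mean_conc"]
            else:
                trt, win = c.split(":")
                vals = df.loc[(df["treatment"] == trt) & (df["window"] == win), "mean_conc"]
            ax.plot(np.full(len(vals), i) + 0.12, vals, "o", mfc="none", mec="grey", ms=4)
    ax.set_xticks(range(len(cells)), cells)
    label = {"pm2_5": "PM$_{2.5}$", "pm10": "PM$_{10}$"}.get(result.metric, result.metric)
    ax.set_ylabel(f"{label} (μg/m³)")
    ax.set_title(f"{label} exposure — {result.model_kind.replace('_', ' ')}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
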