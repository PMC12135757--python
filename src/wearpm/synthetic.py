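"""Seeded generators for co-location-chamber and cross-over feed-trial data.

Two experiments are emulated so every pipeline stage can be exercised
without the deposited field data:

* **Co-location chamber** (:func:`simulate_colocation`): a true chamber
  concentration path made of quasi-steady plateaus joined by linear
  ramps, observed by (a) a slow reference instrument — the truth passed
  through a pure integer-minute delay plus first-order exponential
  smoothing, sampled at 1-min cadence; (b) a fast comparison monitor
  reporting 1-min means of the truth with zero lag; and (c) three
  wearable units whose expected raw 5-s reading is
  ``(true - alpha_i) / beta_i`` — i.e. each unit *under*-reports by its
  sensitivity ``beta_i`` — with multiplicative lognormal noise.
* **Feed trial** (:func:`simulate_feed_trial`): per horse and treatment,
  a piecewise two-level true exposure profile whose 20-min and 8-h
  window means hit the configured lognormal group-mean model exactly.
  Logs are emitted in RAW sensor units by inverting the universal
  calibration, so the analysis pipeline must apply the calibration to
  recover truth.

Both generators are reproducible from their integer ``seed``; the horse
effect and window residuals are shared between the PM2.5 and PM10
channels (one horse-day's air drives both fractions), with only the 5-s
sensor noise independent per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_logs import UnitSeries, WEARABLE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "ColocationConfig",
    "TrialConfig",
    "ColocationResult",
    "TrialResult",
    "ConfigError",
    "simulate_colocation",
    "simulate_feed_trial",
    "default_configs",
    "PM2_5_UNIT_PARAMS",
    "PM10_UNIT_PARAMS",
    "UNIVERSAL_CALIBRATION",
    "GROUP_MEANS",
]


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


# Per-unit (sensitivity beta, offset alpha): expected raw = (true - alpha) / beta.
PM2_5_UNIT_PARAMS: dict[str, tuple[float, float]] = {
    "bb1": (4.48, -5.17),
    "bb2": (4.16, -2.82),
    "bb3": (3.60, -2.58),
}
PM10_UNIT_PARAMS: dict[str, tuple[float, float]] = {
    "bb1": (45.8, -113.7),
    "bb2": (44.6, -51.6),
    "bb3": (42.0, -65.3),
}
#: averaged-unit ("universal") correction corrected = slope * raw + intercept
UNIVERSAL_CALIBRATION: dict[str, tuple[float, float]] = {
    "pm2_5": (4.07, -3.82),
    "pm10": (44.3, -81.5),
}
#: (short 20-min, extended 8-h) geometric group means, μg/m³
GROUP_MEANS: dict[tuple[str, str], tuple[float, float]] = {
    ("dry", "pm2_5"): (160.0, 76.0),
    ("soaked", "pm2_5"): (53.0, 31.0),
    ("dry", "pm10"): (2829.0, 1581.0),
    ("soaked", "pm10"): (970.0, 488.0),
}


def _lognorm_sigma(cv: float) -> float:
    """Log-scale SD of a unit-median lognormal with the given CV."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass
class ColocationConfig:
    """Chamber schedule, instrument response model and unit sensitivities.

    Plateau levels default to spans of 3.5–163.3 μg/m³ (PM2.5) and
    9.7–2543 μg/m³ (PM10), the operating range a hay-dust chamber
    produces.  The reference response model is a ``teom_lag_min`` pure
    delay followed by first-order smoothing with time constant
    ``teom_smoothing_min``; its default (0.5 min) is small so that the
    net correlation lag equals the pure delay and plateau interiors stay
    steady — see docs/methods.md.
    """

    plateau_levels: dict[str, list[float]] = field(
        default_factory=lambda: {
            "pm2_5": [3.5, 10.0, 25.0, 45.0, 70.0, 95.0, 120.0, 145.0, 163.3],
            "pm10": [9.7, 60.0, 200.0, 500.0, 900.0, 1400.0, 1900.0, 2300.0, 2543.0],
        }
    )
    plateau_duration_min: int = 10
    transition_duration_min: int = 3
    teom_lag_min: int = 4
    teom_smoothing_min: float = 0.5
    unit_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {"pm2_5": dict(PM2_5_UNIT_PARAMS), "pm10": dict(PM10_UNIT_PARAMS)}
    )
    noise_cv: float = 0.05
    teom_noise_cv: float = 0.005
    start: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2025-02-10T09:00:00"))
    seed: int = 0

    def validate(self) -> None:
        if self.plateau_duration_min < 5:
            raise ConfigError("plateau_duration_min must be >= 5 (a steady interval is 5 min)")
        if self.teom_lag_min < 0:
            raise ConfigError("teom_lag_min must be >= 0")
        if self.teom_smoothing_min < 0:
            raise ConfigError("teom_smoothing_min must be >= 0")
        lens = {f: len(v) for f, v in self.plateau_levels.items()}
        if len(set(lens.values())) != 1:
            raise ConfigError(f"plateau level lists differ in length: {lens}")
        for f, levels in self.plateau_levels.items():
            if any(lv <= 0 for lv in levels):
                raise ConfigError(f"non-positive plateau level in {f}")
        for f, units in self.unit_params.items():
            for u, (beta, _alpha) in units.items():
                if beta <= 0:
                    raise ConfigError(f"unit {u} ({f}): beta must be > 0")

    @property
    def n_minutes(self) -> int:
        k = len(next(iter(self.plateau_levels.values())))
        return k * self.plateau_duration_min + (k - 1) * self.transition_duration_min


@dataclass
class TrialConfig:
    """Cross-over feed-trial generative model.

    ``group_means[(treatment, metric)] = (M20, M8)``: the short-window
    (20-min) and extended-window (8-h) geometric group means in μg/m³.
    Per horse ``h`` and treatment, window means are drawn as
    ``log m = log M + b_h + e`` with a horse effect
    ``b_h ~ N(0, horse_sd_log²)`` shared across treatments (the
    cross-over's repeated-measures structure) and independent window
    residuals ``e ~ N(0, resid_sd_log²)``.  Raw logs are produced by
    inverting ``calibration`` (slope, intercept per metric).
    """

    n_horses: int = 10
    group_means: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_MEANS)
    )
    horse_sd_log: float = 0.35
    resid_sd_log: float = 0.25
    noise_cv: float = 0.05
    duration_h: float = 8.0
    feed_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2025-03-03T08:00:00"))
    calibration: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(UNIVERSAL_CALIBRATION)
    )
    floor_ug_m3: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_horses < 2:
            raise ConfigError("n_horses must be >= 2")
        for (trt, metric), (m20, m8) in self.group_means.items():
            if not (m20 >= m8 > 0):
                raise ConfigError(
                    f"group means for ({trt}, {metric}) must satisfy M20 >= M8 > 0, got {m20}, {m8}"
                )
        if self.horse_sd_log < 0 or self.resid_sd_log < 0 or self.noise_cv < 0:
            raise ConfigError("SDs and noise CV must be >= 0")


@dataclass
class ColocationResult:
    teom: dict[str, UnitSeries]  # one reference series per size fraction
    wearables: list[UnitSeries]
    comparison: UnitSeries
    truth: pd.DataFrame  # 5-s truth: timestamp, pm2_5, pm10
    config: ColocationConfig


@dataclass
class TrialResult:
    logs: dict[tuple[str, str], UnitSeries]  # (horse_id, treatment) -> wearable log
    metadata: pd.DataFrame  # horse_id, date, treatment, feed_time, log_path
    truth: pd.DataFrame  # horse_id, treatment, metric, m20, m8 (generated window means)
    config: TrialConfig


def _truth_path(levels: list[float], plateau_min: int, ramp_min: int, n_steps: int, dt_s: float) -> np.ndarray:
    """Piecewise plateau/linear-ramp concentration at ``dt_s`` resolution."""
    xp, fp = [], []
    t = 0.0
    for i, lv in enumerate(levels):
        xp += [t, t + plateau_min * 60.0]
        fp += [lv, lv]
        t += plateau_min * 60.0
        if i < len(levels) - 1:
            t += ramp_min * 60.0
    tgrid = np.arange(n_steps) * dt_s
    return np.interp(tgrid, xp, fp)


def _first_order_smooth(x: np.ndarray, tau_s: float, dt_s: float) -> np.ndarray:
    if tau_s <= 0:
        return x.copy()
    decay = float(np.exp(-dt_s / tau_s))
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, len(x)):
        y[i] = x[i] + (y[i - 1] - x[i]) * decay
    return y


def _wearable_frame(timestamps: pd.Series | pd.DatetimeIndex, raw: dict[str, np.ndarray],
                    temp_c: float = 22.3, rh_pct: float = 18.0) -> pd.DataFrame:
    """Assemble a full wearable record frame from raw pm2_5/pm10 channels.

    The pm1 channel and the six cumulative number bins are plausible
    deterministic functions of the pm2_5 channel (they are carried but
    never calibrated); the max-chain guarantees pm1 <= pm2_5 <= pm10.
    """
    pm2_5 = np.asarray(raw["pm2_5"], dtype=float)
    pm10 = np.maximum(np.asarray(raw["pm10"], dtype=float), pm2_5)
    pm1 = 0.55 * pm2_5
    n03 = 200.0 * pm2_5 + 20.0
    df = pd.DataFrame(
        {
            "timestamp": np.asarray(timestamps),
            "pm1": pm1,
            "pm2_5": pm2_5,
            "pm10": pm10,
            "n_gt_0_3": n03,
            "n_gt_0_5": 0.6 * n03,
            "n_gt_1_0": 0.25 * n03,
            "n_gt_2_5": 0.08 * n03,
            "n_gt_5_0": 0.02 * n03,
            "n_gt_10": 0.005 * n03,
            "temp_c": temp_c,
            "rh_pct": rh_pct,
            "lat": np.nan,
            "lon": np.nan,
        }
    )
    return df[WEARABLE_COLUMNS]


def simulate_colocation(config: ColocationConfig | None = None) -> ColocationResult:
    """Generate one co-location chamber run (reference, comparison, wearables)."""
    config = config or ColocationConfig()
    config.validate()
    dt = 5.0
    n_min = config.n_minutes
    n_steps = n_min * 12
    fractions = list(config.plateau_levels)
    truth = {
        f: _truth_path(
            config.plateau_levels[f],
            config.plateau_duration_min,
            config.transition_duration_min,
            n_steps,
            dt,
        )
        for f in fractions
    }
    ts5 = config.start + pd.to_timedelta(np.arange(n_steps) * dt, unit="s")
    minute_starts = config.start + pd.to_timedelta(np.arange(n_min), unit="min")

    ss = np.random.SeedSequence(config.seed)
    rng_teom, rng_comp, rng_units = (np.random.default_rng(s) for s in ss.spawn(3))

    # reference: pure delay + first-order smoothing, 1-min means, noise
    lag_steps = config.teom_lag_min * 12
    teom: dict[str, UnitSeries] = {}
    sigma_t = _lognorm_sigma(config.teom_noise_cv)
    for f in fractions:
        smooth = _first_order_smooth(truth[f], config.teom_smoothing_min * 60.0, dt)
        delayed = np.concatenate([np.full(lag_steps, smooth[0]), smooth])[:n_steps]
        minute_mean = delayed.reshape(n_min, 12).mean(axis=1)
        if sigma_t > 0:
            minute_mean = minute_mean * np.exp(rng_teom.normal(0.0, sigma_t, n_min))
        teom[f] = UnitSeries(
            unit_id=f"teom_{f}",
            instrument_kind="teom",
            size_fraction=f,
            cadence_s=60,
            records=pd.DataFrame({"timestamp": minute_starts, "value": minute_mean}),
        )

    # fast comparison monitor: 1-min means of truth, zero lag, small noise
    comp_mean = truth[fractions[0]].reshape(n_min, 12).mean(axis=1)
    if sigma_t > 0:
        comp_mean = comp_mean * np.exp(rng_comp.normal(0.0, sigma_t, n_min))
    comparison = UnitSeries(
        unit_id="comparison1",
        instrument_kind="comparison",
        size_fraction=fractions[0],
        cadence_s=60,
        records=pd.DataFrame({"timestamp": minute_starts, "value": comp_mean}),
    )

    # wearable units: raw = max(0, (true - alpha)/beta) * exp(eps) at 5 s
    sigma_w = _lognorm_sigma(config.noise_cv)
    wearables: list[UnitSeries] = []
    unit_ids = sorted(config.unit_params[fractions[0]])
    for uid in unit_ids:
        raw = {}
        for f in fractions:
            beta, alpha = config.unit_params[f][uid]
            expect = np.maximum(0.0, (truth[f] - alpha) / beta)
            noise = np.exp(rng_units.normal(0.0, sigma_w, n_steps)) if sigma_w > 0 else 1.0
            raw[f] = expect * noise
        wearables.append(
            UnitSeries(
                unit_id=uid,
                instrument_kind="wearable",
                size_fraction="both",
                cadence_s=5,
                records=_wearable_frame(ts5, raw),
            )
        )

    truth_df = pd.DataFrame({"timestamp": ts5, **{f: truth[f] for f in fractions}})
    return ColocationResult(teom=teom, wearables=wearables, comparison=comparison,
                           truth=truth_df, config=config)


def simulate_feed_trial(config: TrialConfig | None = None) -> TrialResult:
    """Generate the cross-over trial: one raw 8-h wearable log per horse-day."""
    config = config or TrialConfig()
    config.validate()
    dt = 5.0
    n_steps = int(round(config.duration_h * 3600 / dt))
    short_steps = int(round(20 * 60 / dt))
    metrics = sorted({m for (_t, m) in config.group_means})
    treatments = ["dry", "soaked"]

    ss = np.random.SeedSequence(config.seed)
    rng_effects, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    sigma_w = _lognorm_sigma(config.noise_cv)

    horse_ids = [f"h{i + 1:02d}" for i in range(config.n_horses)]
    b = rng_effects.normal(0.0, config.horse_sd_log, config.n_horses)

    logs: dict[tuple[str, str], UnitSeries] = {}
    meta_rows, truth_rows = [], []
    total_min = config.duration_h * 60.0
    for hi, horse in enumerate(horse_ids):
        # dry fed on the first occasion, soaked on the second, same week
        day0 = config.feed_time + pd.Timedelta(days=7 * hi)
        for ti, trt in enumerate(treatments):
            feed = day0 + pd.Timedelta(days=3 * ti)
            e20, e8 = rng_effects.normal(0.0, config.resid_sd_log, 2)
            raw = {}
            for metric in metrics:
                m20_g, m8_g = config.group_means[(trt, metric)]
                m20 = m20_g * np.exp(b[hi] + e20)
                m8 = m8_g * np.exp(b[hi] + e8)
                l2 = (total_min * m8 - 20.0 * m20) / (total_min - 20.0)
                if l2 < config.floor_ug_m3:
                    logger.warning(
                        "trial %s/%s %s: post-feeding level floored (%.2f -> %.2f μg/m³)",
                        horse, trt, metric, l2, config.floor_ug_m3,
                    )
                    l2 = config.floor_ug_m3
                true = np.full(n_steps, l2)
                true[:short_steps] = m20
                slope, intercept = config.calibration[metric]
                expect = np.maximum(0.0, (true - intercept) / slope)
                noise = np.exp(rng_noise.normal(0.0, sigma_w, n_steps)) if sigma_w > 0 else 1.0
                raw[metric] = expect * noise
                truth_rows.append(
                    {"horse_id": horse, "treatment": trt, "metric": metric, "m20": m20, "m8": m8}
                )
            ts = feed + pd.to_timedelta(np.arange(n_steps) * dt, unit="s")
            logs[(horse, trt)] = UnitSeries(
                unit_id=f"{horse}_{trt}",
                instrument_kind="wearable",
                size_fraction="both",
                cadence_s=5,
                records=_wearable_frame(ts, raw),
            )
            meta_rows.append(
                {
                    "horse_id": horse,
                    "date": feed.date().isoformat(),
                    "treatment": trt,
                    "feed_time": feed.strftime("%Y-%m-%dT%H:%M:%S"),
                    "log_path": f"{horse}_{trt}.csv",
                }
            )
    return TrialResult(
        logs=logs,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def default_configs(seed: int = 0) -> tuple[ColocationConfig, TrialConfig]:
    """Chamber and trial configurations with the published-study anchors.

    Co-location unit sensitivities are the three per-unit (slope,
    intercept) pairs for each size fraction; trial group means are the
    four PM2.5 and four PM10 treatment-window geometric means.
    """
    coloc = ColocationConfig(seed=seed)
    trial = TrialConfig(seed=seed)
    coloc.validate()
    trial.validate()
    return coloc, trial


def config_to_dict(config: ColocationConfig | TrialConfig) -> dict:
    """JSON/YAML-safe dict form (tuple keys flattened, timestamps ISO)."""
    d = asdict(config)
    for key in ("start", "feed_time"):
        if key in d:
            d[key] = pd.Timestamp(d[key]).strftime("%Y-%m-%dT%H:%M:%S")
    if "group_means" in d:
        d["group_means"] = {
            f"{trt}/{metric}": list(v) for (trt, metric), v in d["group_means"].items()
        }
    if "unit_params" in d:
        d["unit_params"] = {
            f: {u: list(p) for u, p in units.items()} for f, units in d["unit_params"].items()
        }
    if "calibration" in d:
        d["calibration"] = {f: list(v) for f, v in d["calibration"].items()}
    return d


def trial_config_from_dict(d: dict) -> TrialConfig:
    d = dict(d)
    if "feed_time" in d:
        d["feed_time"] = pd.Timestamp(d["feed_time"])
    if "group_means" in d:
        d["group_means"] = {
            tuple(k.split("/")): tuple(v) for k, v in d["group_means"].items()
        }
    if "calibration" in d:
        d["calibration"] = {f: tuple(v) for f, v in d["calibration"].items()}
    cfg = TrialConfig(**d)
    cfg.validate()
    return cfg


def colocation_config_from_dict(d: dict) -> ColocationConfig:
    d = dict(d)
    if "start" in d:
        d["start"] = pd.Timestamp(d["start"])
    if "unit_params" in d:
        d["unit_params"] = {
            f: {u: tuple(p) for u, p in units.items()} for f, units in d["unit_params"].items()
        }
    cfg = ColocationConfig(**d)
    cfg.validate()
    return cfg
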