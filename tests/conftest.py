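import numpy as np
import pandas as pd
import pytest

from wearpm.calibration import CalibrationModel
from wearpm.io_logs import UnitSeries, resample_to_minutes
from wearpm.synthetic import ColocationConfig, TrialConfig, simulate_colocation


def make_model(fraction: str, slope: float, intercept: float) -> CalibrationModel:
    return CalibrationModel(
        size_fraction=fraction, unit_id="averaged", slope=slope, intercept=intercept,
        r2=1.0, rmse=0.0, n_obs=29, p_slope=0.0, shapiro_w=1.0, shapiro_p=1.0,
    )


def minutes_frame(values, start="2025-02-10T09:00:00") -> pd.DataFrame:
    """Complete 1-min minute-average frame from a value list."""
    start = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "minute_start": start + pd.to_timedelta(np.arange(len(values)), unit="min"),
            "value": np.asarray(values, dtype=float),
            "n_samples": 1,
            "complete": True,
        }
    )


def value_series(values, kind="teom", cadence_s=60, unit_id="u", fraction="pm2_5",
                 start="2025-02-10T09:00:00") -> UnitSeries:
    start = pd.Timestamp(start)
    ts = start + pd.to_timedelta(np.arange(len(values)) * cadence_s, unit="s")
    return UnitSeries(
        unit_id=unit_id, instrument_kind=kind, size_fraction=fraction, cadence_s=cadence_s,
        records=pd.DataFrame({"timestamp": ts, "value": np.asarray(values, dtype=float)}),
    )


@pytest.fixture(scope="session")
def default_colocation():
    """One default-noise chamber run shared across read-only tests."""
    return simulate_colocation(ColocationConfig(seed=11))


@pytest.fixture(scope="session")
def default_colocation_minutes(default_colocation):
    res = default_colocation
    return {
        "teom": {f: resample_to_minutes(s) for f, s in res.teom.items()},
        "comparison": resample_to_minutes(res.comparison),
    }


@pytest.fixture
def zero_noise_colocation_config():
    """Noise-free chamber with unit (beta=4, alpha=0) style parameters."""
    return ColocationConfig(
        unit_params={
            "pm2_5": {"bb1": (4.0, 0.0), "bb2": (4.0, 0.0), "bb3": (4.0, 0.0)},
            "pm10": {"bb1": (40.0, 0.0), "bb2": (40.0, 0.0), "bb3": (40.0, 0.0)},
        },
        noise_cv=0.0,
        teom_noise_cv=0.0,
        teom_lag_min=0,
        teom_smoothing_min=0.0,
        seed=0,
    )


@pytest.fixture
def small_trial_config():
    return TrialConfig(n_horses=4, seed=3)
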