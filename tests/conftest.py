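import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from falldetect.elasticnet_classifier import (
    TrainingSet,
    calibrate_threshold,
    fit,
    training_set_from_windows,
)
from falldetect.imu_core import GRID_STEP_MS, N_GRID, SensorWindow, WINDOW_MS
from falldetect.synthetic_imu import SyntheticConfig, gen_training_windows

settings.register_profile(
    "fixed", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

TRAIN_SEED = 11


def make_grid_window(accel, gyro=None, t_start=0, label="unlabeled"):
    """A valid SensorWindow whose raw samples sit exactly on the 20 ms grid."""
    accel = np.asarray(accel, dtype=float).reshape(-1, 3)
    assert accel.shape[0] == N_GRID
    gyro = np.zeros_like(accel) if gyro is None else np.asarray(gyro, float).reshape(-1, 3)
    t = t_start + GRID_STEP_MS * np.arange(N_GRID, dtype=np.int64)
    return SensorWindow(
        t_start=t_start, t_end=t_start + WINDOW_MS,
        t_raw=t, accel_raw=accel, gyro_raw=gyro,
        valid=True, accel_interp=accel.copy(), gyro_interp=gyro.copy(),
        label=label,
    )


def random_window(seed, scale=1.0):
    rng = np.random.default_rng(seed)
    accel = rng.normal(0, 0.5, (N_GRID, 3)) * scale + [0, 0, 1]
    gyro = rng.normal(0, 0.3, (N_GRID, 3)) * scale
    return make_grid_window(accel, gyro)


@pytest.fixture(scope="session")
def train_config():
    return SyntheticConfig(n_participants=6, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def training_set(train_config) -> TrainingSet:
    """Screen-passing labeled windows from 200 synthetic fall events plus
    stumble/phone-drop confounders, grouped into 6 pseudo-participants."""
    windows, groups = gen_training_windows(2000, 2000, train_config, seed=TRAIN_SEED)
    return training_set_from_windows(windows, groups)


@pytest.fixture(scope="session")
def deployment_model(training_set):
    """Fitted elastic-net model with the alert threshold calibrated at the
    5th percentile of training-fall posteriors."""
    model = fit(training_set)
    model.threshold = calibrate_threshold(model, training_set.X[training_set.y == 1])
    return model
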