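"""The 40 windowed IMU features (20 per sensor) fed to the classifier.

For each sensor (accelerometer, gyroscope) the scalar statistics — mean,
median, sample standard deviation, skewness, kurtosis, IQR, minimum, maximum —
are computed on the magnitude (Euclidean norm) series of the interpolated
250x3 window; the "derivative of" features are the IQR / minimum / maximum of
the first-difference of that magnitude series; maximum, minimum and IQR are
additionally computed per axis. Conventions are pinned for reproducibility:
standard deviation uses the n-1 denominator; skewness m3/m2^1.5 and kurtosis
m4/m2^2 use population central moments (kurtosis is non-excess, Gaussian -> 3);
percentiles interpolate linearly; a zero-variance series takes skew = kurt = 0
so resting windows stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .imu_core import SensorWindow, magnitude

_PER_SENSOR = (
    "mean", "median", "std", "skew", "kurt", "iqr", "d_iqr",
    "min", "d_min", "max", "d_max",
    "max_x", "max_y", "max_z", "min_x", "min_y", "min_z",
    "iqr_x", "iqr_y", "iqr_z",
)
#: Canonical ordered feature names: acc_* then gyr_*, 20 each.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{sensor}_{feat}" for sensor in ("acc", "gyr") for feat in _PER_SENSOR
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 40


class ScalarStats(NamedTuple):
    mean: float
    median: float
    std: float
    skew: float
    kurt: float
    iqr: float
    min: float
    max: float


@dataclass(frozen=True)
class FeatureVector:
    """The 40 features of one window, in canonical order."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75.0, 25.0])
    return float(q75 - q25)


def scalar_stats(series: np.ndarray) -> ScalarStats:
    """Scalar statistics of a 1-d series under the pinned conventions."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be 1-d with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    mean = float(np.mean(x))
    m2 = float(np.mean((x - mean) ** 2))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    return ScalarStats(
        mean=mean,
        median=float(np.median(x)),
        std=float(np.std(x, ddof=1)),
        skew=skew,
        kurt=kurt,
        iqr=_iqr(x),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


def derivative(series: np.ndarray) -> np.ndarray:
    """First difference per 20 ms grid step (not divided by dt)."""
    x = np.asarray(series, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    return np.diff(x)


def _sensor_features(data: np.ndarray) -> list[float]:
    """The 20 features of one sensor's interpolated 250x3 window."""
    mag = magnitude(data)
    s = scalar_stats(mag)
    d = derivative(mag)
    out = [
        s.mean, s.median, s.std, s.skew, s.kurt, s.iqr, _iqr(d),
        s.min, float(np.min(d)), s.max, float(np.max(d)),
    ]
    out.extend(float(np.max(data[:, k])) for k in range(3))
    out.extend(float(np.min(data[:, k])) for k in range(3))
    out.extend(_iqr(data[:, k]) for k in range(3))
    return out


def compute_features(window: SensorWindow) -> FeatureVector:
    """Compute the 40 canonical features of a valid (interpolated) window."""
    if not window.valid or window.accel_interp is None or window.gyro_interp is None:
        raise ValueError("compute_features requires a valid, interpolated window")
    values = _sensor_features(window.accel_interp) + _sensor_features(window.gyro_interp)
    return FeatureVector(np.array(values))


def feature_frame(
    features: Sequence[FeatureVector],
    labels: Sequence[str],
    window_ids: Sequence[str],
) -> pd.DataFrame:
    """Assemble the export table: window_id, label, then the 40 feature columns."""
    if not (len(features) == len(labels) == len(window_ids)):
        raise ValueError("features, labels and window_ids must align")
    df = pd.DataFrame(
        np.vstack([fv.values for fv in features]) if features else
        np.empty((0, N_FEATURES)),
        columns=list(FEATURE_NAMES),
    )
    df.insert(0, "label", list(labels))
    df.insert(0, "window_id", list(window_ids))
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["window_id", "label", *FEATURE_NAMES]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected[:4]}... in canonical order")
    return df
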