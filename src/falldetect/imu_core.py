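"""Sensor-stream data model, CSV I/O, windowing, interpolation and quality gating.

A recording is a single participant's timestamped 6-axis stream: tri-axial
acceleration in units of g (gravity-inclusive) and tri-axial angular velocity
in rad/s, sampled by a smartphone at a nominal 50 Hz but with irregular
spacing. Detection operates on 5-second windows; a window is usable only if it
contains enough samples and no large sampling gaps, and is then linearly
interpolated onto an even 20 ms grid (250 samples) with no further filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Window length in milliseconds; windows are half-open [t_start, t_start + 5000).
WINDOW_MS = 5000
#: Interpolation grid: 250 samples at 20 ms spacing (50 Hz).
N_GRID = 250
GRID_STEP_MS = 20
#: Quality gates: minimum raw samples per window and maximum tolerated gap.
MIN_SAMPLES = 200
MAX_GAP_MS = 200
#: Impact search half-width around a researcher-logged fall timestamp.
IMPACT_SEARCH_MS = 2500

CSV_COLUMNS = ("t_ms", "ax_g", "ay_g", "az_g", "gx_rads", "gy_rads", "gz_rads")


class ImuSample(NamedTuple):
    """One raw sample: time in ms since epoch, acceleration (g), gyro (rad/s)."""

    t: int
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float


class ParseError(ValueError):
    """Malformed recording CSV (bad header or non-numeric field)."""


class ImpactNotFoundError(ValueError):
    """No sample inside the ±2.5 s impact-search interval."""


@dataclass
class ImuRecording:
    """A participant's full sensor stream, stored as column arrays.

    ``t`` is int64 milliseconds, strictly increasing with no duplicates;
    ``accel`` (g) and ``gyro`` (rad/s) are (n, 3) float arrays.
    """

    participant_id: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.accel = np.asarray(self.accel, dtype=np.float64).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=np.float64).reshape(-1, 3)
        if not (len(self.t) == len(self.accel) == len(self.gyro)):
            raise ValueError("t, accel and gyro must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.t) and self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("all channels must be finite")

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, i: int) -> ImuSample:
        return ImuSample(int(self.t[i]), *self.accel[i], *self.gyro[i])

    @property
    def samples(self) -> Iterator[ImuSample]:
        for i in range(len(self.t)):
            yield self.sample(i)


@dataclass
class SensorWindow:
    """A 5-second half-open window [t_start, t_end) of raw samples.

    If the window passes the quality gates, ``accel_interp`` and
    ``gyro_interp`` hold the 250x3 arrays on the even 20 ms grid whose first
    point sits at ``t_start``; otherwise they are ``None``.
    """

    t_start: int
    t_end: int
    t_raw: np.ndarray
    accel_raw: np.ndarray
    gyro_raw: np.ndarray
    valid: bool = False
    accel_interp: Optional[np.ndarray] = None
    gyro_interp: Optional[np.ndarray] = None
    label: str = "unlabeled"  # fall | non_fall | unlabeled (free sub-tags allowed)
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.t_end - self.t_start != WINDOW_MS:
            raise ValueError("window must span exactly 5000 ms")

    @property
    def n_raw(self) -> int:
        return len(self.t_raw)


@dataclass
class FallLabelEvent:
    """A researcher-logged fall timestamp, optionally resolved to its impact."""

    participant_id: str
    t_label: int
    t_impact: Optional[int] = None

    def __post_init__(self) -> None:
        if self.t_impact is not None and abs(self.t_impact - self.t_label) > IMPACT_SEARCH_MS:
            raise ValueError("resolved impact must lie within 2.5 s of the label")


def magnitude(series: np.ndarray) -> np.ndarray:
    """Per-row Euclidean norm of an (n, 3) array (the signal magnitude vector)."""
    return np.linalg.norm(np.asarray(series, dtype=np.float64).reshape(-1, 3), axis=1)


def read_recording(path, participant_id: str) -> ImuRecording:
    """Read a recording CSV (header ``t_ms,ax_g,...,gz_rads``) into an ImuRecording.

    Rows with non-finite values are dropped (count logged); duplicate
    timestamps keep the first occurrence; output is sorted by time.
    Raises :class:`ParseError` for a bad header or a non-numeric field,
    naming the first offending line.
    """
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file, expected header {','.join(CSV_COLUMNS)}")
    if tuple(df.columns) != CSV_COLUMNS:
        raise ParseError(
            f"{path}: malformed header {list(df.columns)!r}, expected {list(CSV_COLUMNS)!r}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0, 0])
        col = bad.columns[int(np.argwhere(bad.iloc[row].to_numpy())[0, 0])]
        # +2: 1-based lines plus the header row
        raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row + 2}")
    values = numeric.to_numpy(dtype=np.float64)
    finite = np.all(np.isfinite(values), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_recording(%s): dropped %d non-finite rows", path, n_dropped)
    values = values[finite]
    order = np.argsort(values[:, 0], kind="stable")
    values = values[order]
    t = values[:, 0].astype(np.int64)
    keep = np.ones(len(t), dtype=bool)
    if len(t) > 1:
        keep[1:] = np.diff(t) > 0
    n_dup = int((~keep).sum())
    if n_dup:
        logger.info("read_recording(%s): dropped %d duplicate timestamps", path, n_dup)
    values = values[keep]
    return ImuRecording(participant_id, values[:, 0].astype(np.int64), values[:, 1:4], values[:, 4:7])


def write_recording(recording: ImuRecording, path) -> None:
    """Write a recording in the CSV dialect read by :func:`read_recording`."""
    df = pd.DataFrame(
        np.column_stack([recording.t, recording.accel, recording.gyro]),
        columns=list(CSV_COLUMNS),
    )
    df["t_ms"] = df["t_ms"].astype(np.int64)
    df.to_csv(path, index=False)


def read_fall_labels(path) -> list[FallLabelEvent]:
    """Read a fall-label CSV with header ``participant_id,t_label_ms``."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if tuple(df.columns) != ("participant_id", "t_label_ms"):
        raise ParseError(f"{path}: expected header participant_id,t_label_ms")
    return [
        FallLabelEvent(str(row.participant_id), int(row.t_label_ms))
        for row in df.itertuples(index=False)
    ]


def write_fall_labels(labels: Sequence[FallLabelEvent], path) -> None:
    pd.DataFrame(
        {
            "participant_id": [ev.participant_id for ev in labels],
            "t_label_ms": [ev.t_label for ev in labels],
        }
    ).to_csv(path, index=False)


def locate_impact(recording: ImuRecording, t_label: int) -> int:
    """Resolve a logged fall timestamp to the impact time.

    Returns the timestamp of the sample maximising acceleration magnitude
    within the closed interval [t_label - 2500, t_label + 2500] ms; ties break
    toward the earliest sample.
    """
    lo = np.searchsorted(recording.t, t_label - IMPACT_SEARCH_MS, side="left")
    hi = np.searchsorted(recording.t, t_label + IMPACT_SEARCH_MS, side="right")
    if hi <= lo:
        raise ImpactNotFoundError(
            f"no samples within ±{IMPACT_SEARCH_MS} ms of t={t_label}"
        )
    mag = magnitude(recording.accel[lo:hi])
    return int(recording.t[lo + int(np.argmax(mag))])  # argmax takes the first max


def quality_check(window: SensorWindow) -> bool:
    """Apply the window quality gates and record the result on the window.

    A window passes iff it has at least 200 raw samples, no gap between
    consecutive samples exceeds 200 ms, and neither edge of the window is more
    than 200 ms from its nearest sample (so interpolation never extrapolates
    across more than 200 ms).
    """
    ok = window.n_raw >= MIN_SAMPLES
    if ok:
        t = window.t_raw
        gaps_ok = len(t) < 2 or int(np.max(np.diff(t))) <= MAX_GAP_MS
        edges_ok = (int(t[0]) - window.t_start <= MAX_GAP_MS) and (
            window.t_end - int(t[-1]) <= MAX_GAP_MS
        )
        ok = gaps_ok and edges_ok
    window.valid = bool(ok)
    if not ok:
        window.accel_interp = None
        window.gyro_interp = None
    return window.valid


def interpolate(window: SensorWindow) -> SensorWindow:
    """Linearly interpolate both sensors onto the even 250-point 20 ms grid.

    Grid points outside the raw sample range take the nearest raw value
    (constant extrapolation). No filtering is applied. Requires a valid
    window.
    """
    if not window.valid:
        raise ValueError("interpolate called on a window that failed quality_check")
    grid = window.t_start + GRID_STEP_MS * np.arange(N_GRID, dtype=np.int64)
    t = window.t_raw.astype(np.float64)
    g = grid.astype(np.float64)
    window.accel_interp = np.column_stack(
        [np.interp(g, t, window.accel_raw[:, k]) for k in range(3)]
    )
    window.gyro_interp = np.column_stack(
        [np.interp(g, t, window.gyro_raw[:, k]) for k in range(3)]
    )
    return window


def cut_window(
    recording: ImuRecording,
    t_start: int,
    label: str = "unlabeled",
    source_id: str = "",
) -> SensorWindow:
    """Cut the half-open 5 s window starting at ``t_start``, gate and interpolate it."""
    lo = np.searchsorted(recording.t, t_start, side="left")
    hi = np.searchsorted(recording.t, t_start + WINDOW_MS, side="left")
    window = SensorWindow(
        t_start=int(t_start),
        t_end=int(t_start) + WINDOW_MS,
        t_raw=recording.t[lo:hi].copy(),
        accel_raw=recording.accel[lo:hi].copy(),
        gyro_raw=recording.gyro[lo:hi].copy(),
        label=label,
        source_id=source_id or recording.participant_id,
    )
    if quality_check(window):
        interpolate(window)
    return window


def augment_fall_windows(
    recording: ImuRecording,
    t_impact: int,
    n: int = 10,
    seed: int = 0,
) -> list[SensorWindow]:
    """Create ``n`` randomly placed 5 s windows, each containing the impact.

    Window starts are drawn uniformly from [t_impact - 4999, t_impact] ms so
    the impact sample lies inside every window; all windows are labeled
    ``fall``. Windows that fail the quality gates are kept but flagged
    invalid. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, WINDOW_MS, size=n)
    return [
        cut_window(recording, int(t_impact - off), label="fall")
        for off in offsets
    ]


def tumbling_windows(recording: ImuRecording) -> Iterator[SensorWindow]:
    """Tile the recording with non-overlapping 5 s windows (a generator).

    The first window starts at the first sample's timestamp rounded down to
    the nearest second; each window is quality-gated and, if valid,
    interpolated. Yields nothing for an empty recording.
    """
    if len(recording) == 0:
        return
    t0 = (int(recording.t[0]) // 1000) * 1000
    t_last = int(recording.t[-1])
    while t0 <= t_last:
        yield cut_window(recording, t0)
        t0 += WINDOW_MS
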