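"""The deployed two-stage online detector.

Stage 1 is a cheap screen: a window can only be a fall if its peak
interpolated acceleration magnitude strictly exceeds 2 g. Stage 2 applies the
elastic-net logistic classifier to screened windows; a posterior above the
calibrated threshold (default 0.908) raises an alert, a posterior above 0.5
marks a potential fall event. Both cut-offs are strict inequalities.

The engine is total: windows that fail the quality gates are recorded with a
processing-failure flag rather than raised, so bookkeeping (failures +
classified = all windows) always balances. Alerts invoke a caller-supplied
hook exactly once and are enriched with contextual information (time,
location, pre-fall movement speed, weather, recognised activity) through a
pluggable provider; providers must degrade to "unknown", never fail the
detection path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Callable, Iterable, Optional, Protocol, Sequence

import numpy as np

from .elasticnet_classifier import ElasticNetModel, predict_posterior
from .feature_extraction import compute_features
from .imu_core import ImuRecording, SensorWindow, magnitude, tumbling_windows

logger = logging.getLogger(__name__)

EVENT_LOG_SCHEMA_VERSION = 1
STAGE1_THRESHOLD_G = 2.0
POTENTIAL_THRESHOLD = 0.5
RETENTION_MS = 15 * 60 * 1000

WEATHER_CATEGORIES = ("clear", "cloudy", "rainy", "snowy", "unknown")


@dataclass
class EventContext:
    """Portal-record context attached to an alert."""

    timestamp: str = ""
    location: Optional[tuple[float, float]] = None
    speed_before: Optional[float] = None  # m/s, mean over the 5 min before
    weather: str = "unknown"
    activity: Optional[str] = None
    activity_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weather not in WEATHER_CATEGORIES:
            raise ValueError(f"weather must be one of {WEATHER_CATEGORIES}")
        if self.activity is not None and self.activity_confidence is not None:
            if not (0.0 <= self.activity_confidence <= 1.0):
                raise ValueError("activity confidence must be in [0, 1]")


class ContextProvider(Protocol):
    """Context lookups for alert enrichment; implementations must be total."""

    def locate(self, t_ms: int) -> Optional[tuple[float, float]]: ...

    def lookup_weather(self, t_ms: int, location: Optional[tuple[float, float]]) -> str: ...

    def classify_activity(self, t_ms: int) -> tuple[Optional[str], Optional[float]]: ...

    def speed_before(self, t_ms: int) -> Optional[float]: ...


class StubContextProvider:
    """Deterministic stand-in for the external location/weather/activity APIs."""

    def __init__(
        self,
        location: Optional[tuple[float, float]] = None,
        weather: str = "unknown",
        activity: Optional[str] = None,
        confidence: Optional[float] = None,
        speed: Optional[float] = None,
    ) -> None:
        self._location = location
        self._weather = weather
        self._activity = activity
        self._confidence = confidence
        self._speed = speed

    def locate(self, t_ms: int):
        return self._location

    def lookup_weather(self, t_ms: int, location):
        return self._weather

    def classify_activity(self, t_ms: int):
        return self._activity, self._confidence

    def speed_before(self, t_ms: int):
        return self._speed


@dataclass
class DetectionEvent:
    """The outcome of classifying one 5 s window."""

    participant_id: str
    t_start: int
    posterior: Optional[float]
    stage1_pass: bool
    status: str  # alert | potential | none
    peak_accel: Optional[float]  # peak interpolated magnitude, g
    processing_failure: bool = False
    context: Optional[EventContext] = None

    def __post_init__(self) -> None:
        if self.status not in ("alert", "potential", "none"):
            raise ValueError("status must be alert, potential or none")
        if self.status == "alert" and not self.stage1_pass:
            raise ValueError("an alert requires a stage-1 pass")

    def to_json_dict(self) -> dict:
        doc = asdict(self)
        doc["schema_version"] = EVENT_LOG_SCHEMA_VERSION
        if self.context is not None and self.context.location is not None:
            doc["context"]["location"] = list(self.context.location)
        return doc

    @classmethod
    def from_json_dict(cls, doc: dict) -> "DetectionEvent":
        doc = dict(doc)
        doc.pop("schema_version", None)
        ctx = doc.pop("context", None)
        event = cls(**doc)
        if ctx is not None:
            if ctx.get("location") is not None:
                ctx["location"] = tuple(ctx["location"])
            event.context = EventContext(**ctx)
        return event


def stage1_screen(window: SensorWindow) -> bool:
    """True iff the peak interpolated acceleration magnitude strictly exceeds 2 g."""
    if not window.valid or window.accel_interp is None:
        raise ValueError("stage1_screen requires a valid, interpolated window")
    return float(np.max(magnitude(window.accel_interp))) > STAGE1_THRESHOLD_G


def classify_window(
    window: SensorWindow,
    model: ElasticNetModel,
    participant_id: str = "",
) -> DetectionEvent:
    """Run the two-stage detector on one window (total: never raises).

    Invalid windows become processing failures; windows failing the screen
    get status ``none`` with no posterior computed; otherwise the posterior
    decides alert (> threshold), potential (> 0.5) or none.
    """
    pid = participant_id or window.source_id
    if not window.valid or window.accel_interp is None:
        return DetectionEvent(
            participant_id=pid,
            t_start=window.t_start,
            posterior=None,
            stage1_pass=False,
            status="none",
            peak_accel=None,
            processing_failure=True,
        )
    peak = float(np.max(magnitude(window.accel_interp)))
    if peak <= STAGE1_THRESHOLD_G:
        return DetectionEvent(
            participant_id=pid,
            t_start=window.t_start,
            posterior=None,
            stage1_pass=False,
            status="none",
            peak_accel=peak,
        )
    posterior = float(predict_posterior(model, compute_features(window)))
    if posterior > model.threshold:
        status = "alert"
    elif posterior > POTENTIAL_THRESHOLD:
        status = "potential"
    else:
        status = "none"
    return DetectionEvent(
        participant_id=pid,
        t_start=window.t_start,
        posterior=posterior,
        stage1_pass=True,
        status=status,
        peak_accel=peak,
    )


def _enrich(event: DetectionEvent, provider: Optional[ContextProvider]) -> None:
    ts = datetime.fromtimestamp(event.t_start / 1000.0, tz=timezone.utc).isoformat()
    ctx = EventContext(timestamp=ts)
    if provider is not None:
        try:
            ctx.location = provider.locate(event.t_start)
            ctx.weather = provider.lookup_weather(event.t_start, ctx.location)
            ctx.activity, ctx.activity_confidence = provider.classify_activity(event.t_start)
            ctx.speed_before = provider.speed_before(event.t_start)
        except Exception:
            logger.warning("context provider failed for t=%d; fields left unknown",
                           event.t_start, exc_info=True)
            ctx = EventContext(timestamp=ts)
    event.context = ctx


def stream_detect(
    recording: ImuRecording,
    model: ElasticNetModel,
    provider: Optional[ContextProvider] = None,
    alert_hook: Optional[Callable[[DetectionEvent], None]] = None,
) -> list[DetectionEvent]:
    """Run the detector over a recording's tumbling windows, in time order.

    Every alert event is context-enriched and triggers ``alert_hook`` exactly
    once; a hook failure is logged and the stream continues.
    """
    events: list[DetectionEvent] = []
    for window in tumbling_windows(recording):
        event = classify_window(window, model, participant_id=recording.participant_id)
        if event.status == "alert":
            _enrich(event, provider)
            if alert_hook is not None:
                try:
                    alert_hook(event)
                except Exception:
                    logger.warning("alert hook raised for t=%d; continuing",
                                   event.t_start, exc_info=True)
        events.append(event)
    return events


def retention_filter(
    events: Sequence[DetectionEvent],
    windows: Sequence[SensorWindow],
) -> set[int]:
    """Window starts to retain for transmission under the 15-minute rule.

    A window is retained iff its start lies within ±15 min (closed) of some
    event with posterior > 0.5.
    """
    anchors = np.array(
        [e.t_start for e in events
         if e.posterior is not None and e.posterior > POTENTIAL_THRESHOLD],
        dtype=np.int64,
    )
    if len(anchors) == 0:
        return set()
    starts = np.array([w.t_start for w in windows], dtype=np.int64)
    keep = np.min(np.abs(starts[:, None] - anchors[None, :]), axis=1) <= RETENTION_MS
    return {int(s) for s in starts[keep]}


def write_events_jsonl(events: Iterable[DetectionEvent], path) -> None:
    """One DetectionEvent per line, schema-versioned JSON."""
    with open(path, "w") as fh:
        for event in events:
            fh.write(json.dumps(event.to_json_dict()) + "\n")


def read_events_jsonl(path) -> list[DetectionEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(DetectionEvent.from_json_dict(json.loads(line)))
    return events
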