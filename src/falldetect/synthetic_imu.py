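"""Seeded generator of labeled smartphone IMU recordings.

Emulates a waist-carried smartphone sampling at a nominal 50 Hz with
timestamp jitter and occasional dropout gaps, recording activities of daily
living (rest with slow orientation drift, walking with a gait-band sinusoid)
interleaved with planted events:

* falls — brief free-fall (magnitude decaying toward ~0.3 g), a sharp
  half-sine impact of 3-6 g, a damped settling oscillation, then a quiet rest
  at a new orientation, with a large gyroscope burst during the fall;
* stumbles — a 1.8-3 g spike during walking with gait resuming immediately;
* phone drops — deep free-fall (phone off-body), a sharp impact, then
  complete stillness;
* sit-stand transitions — a smooth sub-2 g magnitude swing.

Orientation is modelled as a slowly drifting gravity direction; no rigid-body
dynamics. Every stream is fully determined by the config seed. The generator
writes the recording CSV dialect, the fall-label CSV and a JSON manifest of
every planted event, so the whole detection pipeline is testable without any
real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import yaml

from .imu_core import (
    FallLabelEvent,
    ImuRecording,
    SensorWindow,
    augment_fall_windows,
    cut_window,
    magnitude,
    write_fall_labels,
    write_recording,
)

G_MS2 = 9.80665  # 1 g, for reference; all accelerations are stored in g

CONFOUNDER_KINDS = ("stumble", "phone_drop", "sit_stand")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the deployment regime.

    Participants carry the phone ~10 h per awake day for a 90-day study;
    scaled-down runs override ``days`` / ``hours_per_day`` explicitly.
    """

    n_participants: int = 8
    hours_per_day: float = 10.0
    days: int = 90
    nominal_rate_hz: float = 50.0
    timestamp_jitter_ms: float = 3.0
    dropout_prob: float = 0.001  # per second of recording
    dropout_len_ms: tuple[float, float] = (300.0, 1500.0)
    falls_per_participant: int = 4
    stumbles_per_participant: int = 3
    drops_per_participant: int = 2
    impact_peak_g: tuple[float, float] = (3.0, 6.0)
    stumble_peak_g: tuple[float, float] = (1.8, 3.0)
    freefall_ms: tuple[float, float] = (300.0, 500.0)
    walk_amp_g: tuple[float, float] = (0.2, 0.8)
    walk_freq_hz: tuple[float, float] = (1.5, 2.5)
    noise_std_g: float = 0.03
    gyro_burst_rads: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_len_ms", "impact_peak_g", "stumble_peak_g",
                     "freefall_ms", "walk_amp_g", "walk_freq_hz", "gyro_burst_rads"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered")
            setattr(self, name, (float(lo), float(hi)))
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be a probability")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.nominal_rate_hz

    def to_dict(self) -> dict:
        doc = asdict(self)
        for key, val in doc.items():
            if isinstance(val, tuple):
                doc[key] = list(val)
        return doc

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        fields = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
        return cls(**fields)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


class Segment(NamedTuple):
    """A contiguous piece of signal: times (ms), accel (g), gyro (rad/s)."""

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _jittered_grid(t0: int, duration_ms: float, config: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Nominal-rate timestamps with bounded Gaussian jitter (strictly increasing)."""
    # floor, and bound jitter below half a step, so a piece never overruns its
    # nominal span and concatenated pieces stay strictly increasing
    n = int(duration_ms // config.dt_ms)
    jitter = np.clip(rng.normal(0.0, config.timestamp_jitter_ms, n),
                     -config.dt_ms / 2 + 1, config.dt_ms / 2 - 1)
    t = t0 + config.dt_ms * np.arange(n) + jitter
    return np.round(t).astype(np.int64)


def _drift_dirs(tt_s: np.ndarray, base: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Slowly drifting gravity direction: base + low-frequency wobble, normalized."""
    freqs = rng.uniform(0.01, 0.05, 3)
    phases = rng.uniform(0, 2 * np.pi, 3)
    wobble = 0.1 * np.sin(2 * np.pi * freqs[None, :] * tt_s[:, None] + phases[None, :])
    dirs = base[None, :] + wobble
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _gait(tt_s: np.ndarray, g_dir: np.ndarray, amp: float, freq: float,
          phase: float, perp: np.ndarray) -> np.ndarray:
    """Walking acceleration: gravity-axis gait sinusoid plus small lateral sway."""
    main = 1.0 + amp * np.sin(2 * np.pi * freq * tt_s + phase)
    sway = 0.2 * amp * np.sin(2 * np.pi * 2 * freq * tt_s + phase)
    return g_dir * main[:, None] + perp[None, :] * sway[:, None]


def _apply_dropouts(segment: Segment, t0: int, duration_ms: float,
                    config: SyntheticConfig,
                    rng: np.random.Generator) -> tuple[Segment, list[tuple[int, int]]]:
    n_seconds = int(duration_ms // 1000)
    hit = np.flatnonzero(rng.random(n_seconds) < config.dropout_prob)
    dropouts: list[tuple[int, int]] = []
    keep = np.ones(len(segment.t), dtype=bool)
    for sec in hit:
        start = t0 + int(sec) * 1000 + int(rng.uniform(0, 1000))
        length = int(rng.uniform(*config.dropout_len_ms))
        keep &= ~((segment.t >= start) & (segment.t < start + length))
        dropouts.append((start, start + length))
    return Segment(segment.t[keep], segment.accel[keep], segment.gyro[keep]), dropouts


def gen_adl_segment(
    duration_ms: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    t0: int = 0,
    with_dropouts: bool = True,
) -> tuple[Segment, list[tuple[int, int]]]:
    """Background activities of daily living: alternating rest / walking epochs.

    Rest sits near 1 g with slow orientation drift and near-zero gyro; walking
    adds a gait-band sinusoid (amplitude and frequency drawn per epoch from
    the config ranges) on both sensors. Timestamps are jittered; dropout gaps
    are inserted with the configured per-second probability and returned as
    declared intervals.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    t = _jittered_grid(t0, duration_ms, config, rng)
    n = len(t)
    tt = (t - t0) / 1000.0
    g_dir = _drift_dirs(tt, _rand_unit(rng), rng)
    accel = g_dir.copy()
    gyro = np.zeros((n, 3))

    cursor = 0.0
    walking = rng.random() < 0.5
    rel = t.astype(np.float64) - t0
    while cursor < duration_ms:
        epoch = rng.uniform(10.0, 30.0) * 1000.0
        mask = (rel >= cursor) & (rel < cursor + epoch)
        if walking and mask.any():
            amp = rng.uniform(*config.walk_amp_g)
            freq = rng.uniform(*config.walk_freq_hz)
            phase = rng.uniform(0, 2 * np.pi)
            perp_raw = np.cross(g_dir[mask][0], _rand_unit(rng))
            perp = perp_raw / np.linalg.norm(perp_raw)
            accel[mask] = _gait(tt[mask], g_dir[mask], amp, freq, phase, perp)
            g_amp = rng.uniform(0.5, 1.5)
            g_axis = _rand_unit(rng)
            gyro[mask] = g_axis[None, :] * (
                g_amp * np.sin(2 * np.pi * freq * tt[mask] + phase))[:, None]
        walking = not walking
        cursor += epoch
    accel += rng.normal(0.0, config.noise_std_g, (n, 3))
    gyro += rng.normal(0.0, 0.02, (n, 3))
    segment = Segment(t, accel, gyro)
    if with_dropouts:
        return _apply_dropouts(segment, t0, duration_ms, config, rng)
    return segment, []


def _walk_piece(duration_ms: float, config: SyntheticConfig,
                rng: np.random.Generator, t0: int,
                g_dir_base: Optional[np.ndarray] = None) -> Segment:
    """A short always-walking piece (used as pre-event context)."""
    t = _jittered_grid(t0, duration_ms, config, rng)
    tt = (t - t0) / 1000.0
    base = g_dir_base if g_dir_base is not None else _rand_unit(rng)
    g_dir = np.repeat(base[None, :], len(t), axis=0)
    amp = rng.uniform(*config.walk_amp_g)
    freq = rng.uniform(*config.walk_freq_hz)
    phase = rng.uniform(0, 2 * np.pi)
    perp_raw = np.cross(base, _rand_unit(rng))
    perp = perp_raw / np.linalg.norm(perp_raw)
    accel = _gait(tt, g_dir, amp, freq, phase, perp)
    g_amp = rng.uniform(0.5, 1.5)
    gyro = _rand_unit(rng)[None, :] * (
        g_amp * np.sin(2 * np.pi * freq * tt + phase))[:, None]
    accel += rng.normal(0.0, config.noise_std_g, accel.shape)
    gyro += rng.normal(0.0, 0.02, gyro.shape)
    return Segment(t, accel, gyro)


def _rest_piece(duration_ms: float, config: SyntheticConfig,
                rng: np.random.Generator, t0: int, g_dir: np.ndarray,
                noise_g: Optional[float] = None,
                gyro_noise: float = 0.02) -> Segment:
    t = _jittered_grid(t0, duration_ms, config, rng)
    noise = config.noise_std_g if noise_g is None else noise_g
    accel = np.repeat(g_dir[None, :], len(t), axis=0)
    accel += rng.normal(0.0, noise, accel.shape)
    gyro = rng.normal(0.0, gyro_noise, (len(t), 3))
    return Segment(t, accel, gyro)


def _concat(*segments: Segment) -> Segment:
    return Segment(
        np.concatenate([s.t for s in segments]),
        np.vstack([s.accel for s in segments]),
        np.vstack([s.gyro for s in segments]),
    )


def _force_apex(segment: Segment, t_apex: float, peak: float,
                direction: np.ndarray) -> int:
    """Pin the sample nearest the impact apex to exactly the peak magnitude.

    Guarantees the planted impact is the unique magnitude maximum of the
    event and returns its timestamp.
    """
    i = int(np.argmin(np.abs(segment.t - t_apex)))
    segment.accel[i] = direction * peak
    return int(segment.t[i])


def gen_fall_event(
    config: SyntheticConfig,
    rng: np.random.Generator,
    t0: int = 0,
    impact_peak_g: Optional[tuple[float, float]] = None,
) -> tuple[Segment, int]:
    """One fall: walking, free-fall, impact, settling oscillation, quiet rest.

    Returns the signal segment and the impact timestamp (the unique magnitude
    maximum). ``impact_peak_g`` overrides the config range, e.g. to produce
    the low-impact falls that slip under the 2 g screen.
    """
    peak_range = impact_peak_g or config.impact_peak_g
    pre = _walk_piece(2000, config, rng, t0)
    t_ff0 = t0 + 2000
    t_ff = rng.uniform(*config.freefall_ms)
    tf = _jittered_grid(t_ff0, t_ff, config, rng)
    tau = (tf - t_ff0) / max(t_ff, 1.0)
    fall_dir = _rand_unit(rng)
    mag_ff = 0.3 + 0.7 * np.exp(-3.0 * tau)
    accel_ff = fall_dir[None, :] * mag_ff[:, None]
    # sustained body rotation toward the ground: non-zero-mean burst
    burst = rng.uniform(*config.gyro_burst_rads)
    burst_axis = _rand_unit(rng)
    envelope = burst * (0.6 + 0.4 * np.sin(2 * np.pi * 5.0 * tau
                                           + rng.uniform(0, 2 * np.pi)))
    gyro_ff = burst_axis[None, :] * envelope[:, None]
    freefall = Segment(tf, accel_ff + rng.normal(0, config.noise_std_g, accel_ff.shape),
                       gyro_ff + rng.normal(0, 0.05, gyro_ff.shape))

    t_i0 = t_ff0 + int(round(t_ff))
    ti = _jittered_grid(t_i0, 100, config, rng)
    peak = rng.uniform(*peak_range)
    impact_dir = _rand_unit(rng)
    half_sine = peak * np.sin(np.pi * np.clip((ti - t_i0) / 100.0, 0, 1))
    accel_i = impact_dir[None, :] * half_sine[:, None]
    gyro_i = burst_axis[None, :] * rng.normal(0, burst / 2, (len(ti), 1))
    impact = Segment(ti, accel_i + rng.normal(0, config.noise_std_g, accel_i.shape),
                     gyro_i + rng.normal(0, 0.05, gyro_i.shape))
    t_impact = _force_apex(impact, t_i0 + 50.0, peak, impact_dir)

    t_o0 = t_i0 + 100
    to = _jittered_grid(t_o0, 500, config, rng)
    new_dir = _rand_unit(rng)
    osc_tau = (to - t_o0) / 1000.0
    osc = 1.0 + 0.8 * np.exp(-osc_tau / 0.15) * np.sin(2 * np.pi * 8.0 * osc_tau)
    accel_o = new_dir[None, :] * osc[:, None]
    settle = Segment(to, accel_o + rng.normal(0, config.noise_std_g, accel_o.shape),
                     rng.normal(0, 0.1, (len(to), 3)))

    # a fallen person keeps moving slightly (breathing, righting attempts),
    # unlike a dropped phone lying dead still
    rest = _rest_piece(5000, config, rng, t_o0 + 500, new_dir, gyro_noise=0.15)
    return _concat(pre, freefall, impact, settle, rest), t_impact


def gen_confounder_event(
    kind: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    t0: int = 0,
) -> tuple[Segment, int]:
    """A non-fall event; returns the segment and the time of its peak sample.

    ``stumble``: a brief high spike during walking with gait resuming;
    ``phone_drop``: off-body free-fall, sharp impact, then complete stillness;
    ``sit_stand``: a smooth 0.5-1.5 g magnitude swing over about a second.
    """
    if kind == "stumble":
        pre = _walk_piece(1500, config, rng, t0)
        t_s0 = t0 + 1500
        ts = _jittered_grid(t_s0, 80, config, rng)
        peak = rng.uniform(*config.stumble_peak_g)
        spike_dir = _rand_unit(rng)
        half_sine = peak * np.sin(np.pi * np.clip((ts - t_s0) / 80.0, 0, 1))
        accel_s = spike_dir[None, :] * half_sine[:, None]
        gyro_amp = rng.uniform(1.0, 2.5)
        spike = Segment(ts, accel_s + rng.normal(0, config.noise_std_g, accel_s.shape),
                        rng.normal(0, gyro_amp / 3, (len(ts), 3)))
        t_peak = _force_apex(spike, t_s0 + 40.0, peak, spike_dir)
        post = _walk_piece(2500, config, rng, t_s0 + 80)
        return _concat(pre, spike, post), t_peak

    if kind == "phone_drop":
        hold_dir = _rand_unit(rng)
        pre = _rest_piece(1000, config, rng, t0, hold_dir)
        t_ff0 = t0 + 1000
        t_ff = rng.uniform(300.0, 600.0)
        tf = _jittered_grid(t_ff0, t_ff, config, rng)
        tau = (tf - t_ff0) / max(t_ff, 1.0)
        mag_ff = 0.05 + 0.95 * np.exp(-6.0 * tau)  # true free fall, near 0 g
        accel_ff = hold_dir[None, :] * mag_ff[:, None]
        spin = _rand_unit(rng) * rng.uniform(0.5, 2.0)  # mild off-body tumble
        freefall = Segment(tf, accel_ff + rng.normal(0, 0.01, accel_ff.shape),
                           spin[None, :] + rng.normal(0, 0.1, (len(tf), 3)))
        t_i0 = t_ff0 + int(round(t_ff))
        ti = _jittered_grid(t_i0, 60, config, rng)
        peak = rng.uniform(*config.impact_peak_g)
        impact_dir = _rand_unit(rng)
        half_sine = peak * np.sin(np.pi * np.clip((ti - t_i0) / 60.0, 0, 1))
        accel_i = impact_dir[None, :] * half_sine[:, None]
        impact = Segment(ti, accel_i + rng.normal(0, 0.02, accel_i.shape),
                         rng.normal(0, 0.3, (len(ti), 3)))
        t_peak = _force_apex(impact, t_i0 + 30.0, peak, impact_dir)
        still_dir = _rand_unit(rng)
        still = _rest_piece(5000, config, rng, t_i0 + 60, still_dir, noise_g=0.005)
        still = Segment(still.t, still.accel, rng.normal(0, 0.002, still.gyro.shape))
        return _concat(pre, freefall, impact, still), t_peak

    if kind == "sit_stand":
        d0 = _rand_unit(rng)
        pre = _rest_piece(1000, config, rng, t0, d0)
        t_s0 = t0 + 1000
        ts = _jittered_grid(t_s0, 1000, config, rng)
        tau = (ts - t_s0) / 1000.0
        mag = 1.0 - 0.5 * np.sin(2 * np.pi * tau)  # dips to 0.5 g, peaks at 1.5 g
        accel_s = d0[None, :] * mag[:, None]
        swing = Segment(ts, accel_s + rng.normal(0, config.noise_std_g, accel_s.shape),
                        rng.normal(0, 0.5, (len(ts), 3)))
        i_peak = int(np.argmax(magnitude(swing.accel)))
        post = _rest_piece(1000, config, rng, t_s0 + 1000, d0)
        return _concat(pre, swing, post), int(swing.t[i_peak])

    raise ValueError(f"unknown confounder kind {kind!r}; expected {CONFOUNDER_KINDS}")


EVENT_DURATIONS_MS = {
    "fall": 8200,       # 2 s walk + <=0.5 s free-fall + impact + settle + 5 s rest
    "stumble": 4100,
    "phone_drop": 6700,
    "sit_stand": 3000,
}
_PLACEMENT_MARGIN_MS = 10_000


def _splice(base: Segment, event: Segment) -> Segment:
    lo = int(np.searchsorted(base.t, event.t[0], side="left"))
    hi = int(np.searchsorted(base.t, event.t[-1], side="right"))
    return Segment(
        np.concatenate([base.t[:lo], event.t, base.t[hi:]]),
        np.vstack([base.accel[:lo], event.accel, base.accel[hi:]]),
        np.vstack([base.gyro[:lo], event.gyro, base.gyro[hi:]]),
    )


@dataclass
class StudyData:
    """In-memory result of :func:`gen_study`."""

    recordings: dict[str, ImuRecording]
    truth: list[FallLabelEvent]
    manifest: dict


def _schedule_events(kinds: Sequence[str], day_starts: Sequence[int],
                     day_ms: float, rng: np.random.Generator) -> list[tuple[str, int]]:
    placed: list[tuple[str, int]] = []
    for kind in kinds:
        dur = EVENT_DURATIONS_MS[kind]
        for _attempt in range(100):
            day = int(rng.integers(0, len(day_starts)))
            latest = day_ms - dur - _PLACEMENT_MARGIN_MS
            t_start = day_starts[day] + _PLACEMENT_MARGIN_MS + int(
                rng.uniform(0, max(latest - _PLACEMENT_MARGIN_MS, 1)))
            if all(abs(t_start - s) > EVENT_DURATIONS_MS[k] + _PLACEMENT_MARGIN_MS
                   for k, s in placed):
                placed.append((kind, t_start))
                break
        else:
            raise RuntimeError("could not place events without overlap after 100 tries")
    return placed


def gen_study(config: SyntheticConfig, out_dir=None) -> StudyData:
    """Generate a full multi-participant study, optionally writing it to disk.

    Per participant: ``days`` daily recordings of ``hours_per_day`` of ADL
    background with the configured falls, stumbles and phone drops planted at
    non-overlapping random daytimes. Returns recordings, researcher-style
    fall labels (logged within ±1 s of the true impact) and a manifest of
    every planted event and dropout. Fully reproducible from the seed.
    """
    day_ms = config.hours_per_day * 3_600_000.0
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    recordings: dict[str, ImuRecording] = {}
    truth: list[FallLabelEvent] = []
    manifest: dict = {"seed": config.seed, "config": config.to_dict(), "participants": []}

    for p, seed_seq in enumerate(child_seeds):
        pid = f"P{p:02d}"
        rng = np.random.default_rng(seed_seq)
        # wear starts at 08:00 each day
        day_starts = [d * 86_400_000 + 28_800_000 for d in range(config.days)]
        kinds = (["fall"] * config.falls_per_participant
                 + ["stumble"] * config.stumbles_per_participant
                 + ["phone_drop"] * config.drops_per_participant)
        events = _schedule_events(kinds, day_starts, day_ms, rng)

        segments: list[Segment] = []
        dropouts_all: list[tuple[int, int]] = []
        for t_day in day_starts:
            seg, dropouts = gen_adl_segment(day_ms, config, rng, t0=t_day)
            segments.append(seg)
            dropouts_all.extend(dropouts)
        stream = _concat(*segments)

        event_records = []
        for kind, t_start in sorted(events, key=lambda ks: ks[1]):
            if kind == "fall":
                seg, t_peak = gen_fall_event(config, rng, t0=t_start)
            else:
                seg, t_peak = gen_confounder_event(kind, config, rng, t0=t_start)
            stream = _splice(stream, seg)
            record = {"kind": kind, "t_start": int(t_start), "t_peak": int(t_peak),
                      "peak_g": float(np.max(magnitude(
                          seg.accel[np.abs(seg.t - t_peak) <= 100])))}
            event_records.append(record)
            if kind == "fall":
                t_label = int(t_peak + rng.integers(-1000, 1001))
                truth.append(FallLabelEvent(pid, t_label))

        recordings[pid] = ImuRecording(pid, stream.t, stream.accel, stream.gyro)
        manifest["participants"].append({
            "participant_id": pid,
            "events": event_records,
            "dropouts": [[int(a), int(b)] for a, b in sorted(dropouts_all)],
        })

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, rec in recordings.items():
            write_recording(rec, out / f"{pid}.csv")
        write_fall_labels(truth, out / "falls.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return StudyData(recordings, truth, manifest)


def _event_recording(kind: str, config: SyntheticConfig,
                     rng: np.random.Generator) -> tuple[ImuRecording, int]:
    """A standalone padded event recording (for window-level training data)."""
    pad_pre, _ = gen_adl_segment(6000, config, rng, t0=1000, with_dropouts=False)
    if kind == "fall":
        seg, t_peak = gen_fall_event(config, rng, t0=7000)
    else:
        seg, t_peak = gen_confounder_event(kind, config, rng, t0=7000)
    t_end = int(seg.t[-1]) + 20
    pad_post, _ = gen_adl_segment(8000, config, rng, t0=t_end, with_dropouts=False)
    stream = _concat(pad_pre, seg, pad_post)
    return ImuRecording("synthetic", stream.t, stream.accel, stream.gyro), t_peak


def gen_training_windows(
    n_fall_windows: int,
    n_confounder_windows: int,
    config: SyntheticConfig,
    seed: Optional[int] = None,
    screen_g: float = 2.0,
) -> tuple[list[SensorWindow], list[str]]:
    """Labeled, screen-passing 5 s windows for classifier training.

    Fall windows come in groups of 10 from the standard fall-window
    augmentation (random placements containing the impact); confounder
    windows alternate stumbles and phone drops and are kept only when they
    pass the 2 g screen — mirroring how the two-stage training set is built.
    Returns windows plus pseudo-participant group ids for LOSO use.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    windows: list[SensorWindow] = []
    groups: list[str] = []

    def peak_of(w: SensorWindow) -> float:
        return float(np.max(magnitude(w.accel_interp)))

    n_events = 0
    while sum(1 for w in windows if w.label == "fall") < n_fall_windows:
        rec, t_impact = _event_recording("fall", config, rng)
        for w in augment_fall_windows(rec, t_impact, n=10,
                                      seed=int(rng.integers(2**31))):
            if w.valid and peak_of(w) > screen_g:
                windows.append(w)
                groups.append(f"P{n_events % config.n_participants:02d}")
        n_events += 1
    del windows[n_fall_windows:]
    del groups[n_fall_windows:]

    kinds = ("stumble", "phone_drop")
    n_conf = 0
    while n_conf < n_confounder_windows:
        kind = kinds[n_conf % 2]
        rec, t_peak = _event_recording(kind, config, rng)
        w = cut_window(rec, int(t_peak - rng.integers(0, 5000)), label="non_fall")
        w.label = "non_fall"
        if w.valid and peak_of(w) > screen_g:
            windows.append(w)
            groups.append(f"P{n_conf % config.n_participants:02d}")
            n_conf += 1
    return windows, groups
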