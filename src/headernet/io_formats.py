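"""Readers and writers for on-disk pipeline artifacts.

All artifacts are plain comma-separated text so datasets stay diffable:

* sensor event tables — one row per triggered event, 300 wide acceleration
  columns (``ap_000`` … ``is_099``) plus metadata columns;
* video header logs — one row per video-adjudicated header;
* match schedules — half intervals and per-player on-pitch intervals;
* labeled datasets — event table plus ``label`` / match provenance columns;
* YAML pipeline configuration.

Acceleration values are serialized with 17 significant digits and parsed
with round-trip float precision, so a write/read cycle is bit-exact and
z-normalization downstream is fully reproducible.

Timestamps are decimal seconds since session start; sensor/video world-clock
synchronization is assumed to have happened upstream.  All intervals are
closed: an event exactly at a half's end time is inside the half.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Axis order of the wearable's accelerometer: anterior-posterior,
#: left-right, inferior-superior.
AXES = ("ap", "lr", "is")
#: Samples per triggered recording: 100 ms at 1000 Hz.
N_SAMPLES = 100
SAMPLE_RATE_HZ = 1000
#: Number formatting used for acceleration values; 17 significant digits
#: make text round-trips bit-exact for float64.
FLOAT_FORMAT = "%.17g"

VH = "VH"
NH = "NH"

_TRACE_COLUMNS = [f"{ax}_{i:03d}" for ax in AXES for i in range(N_SAMPLES)]


class SchemaError(ValueError):
    """A file or record violates the declared on-disk schema."""


class ConfigError(ValueError):
    """A configuration value is missing, malformed or out of range."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class SensorEventRecord:
    """One triggered 3-axis, 100-sample acceleration event in g."""

    event_id: str
    player_id: str
    session_id: str
    timestamp_s: float
    trace: np.ndarray  # shape (3, 100), g
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.trace.shape != (len(AXES), N_SAMPLES):
            raise SchemaError(
                f"event {self.event_id!r}: trace shape {self.trace.shape}, "
                f"expected {(len(AXES), N_SAMPLES)}"
            )
        if not np.all(np.isfinite(self.trace)):
            raise SchemaError(f"event {self.event_id!r}: non-finite trace values")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise SchemaError(
                f"event {self.event_id!r}: sample_rate_hz {self.sample_rate_hz}"
            )
        if self.timestamp_s < 0:
            raise SchemaError(f"event {self.event_id!r}: negative timestamp")

    def resultant(self) -> np.ndarray:
        """Per-sample resultant acceleration magnitude in g."""
        return np.sqrt((self.trace ** 2).sum(axis=0))


@dataclass
class VideoHeaderRecord:
    """One video-adjudicated header with its synchronized timestamp."""

    video_id: str
    player_id: str
    session_id: str
    timestamp_s: float
    half_index: int

    def __post_init__(self) -> None:
        if self.half_index not in (1, 2):
            raise SchemaError(f"video {self.video_id!r}: half_index must be 1 or 2")
        if self.timestamp_s < 0:
            raise SchemaError(f"video {self.video_id!r}: negative timestamp")


@dataclass
class MatchSchedule:
    """Half intervals and per-player on-pitch intervals for one session.

    All intervals are closed ``[start, end]`` in seconds since session start.
    """

    session_id: str
    halves: list[tuple[float, float]]
    on_pitch: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        self.halves = [(float(a), float(b)) for a, b in self.halves]
        for a, b in self.halves:
            if not a < b:
                raise SchemaError(f"schedule {self.session_id!r}: half {a}..{b}")
        for (a0, b0), (a1, b1) in zip(self.halves, self.halves[1:]):
            if b0 >= a1:
                raise SchemaError(
                    f"schedule {self.session_id!r}: overlapping halves"
                )
        end = self.session_end_s
        for player, ivals in self.on_pitch.items():
            for a, b in ivals:
                if not (0 <= a < b <= end):
                    raise SchemaError(
                        f"schedule {self.session_id!r}: on-pitch interval "
                        f"{a}..{b} for player {player!r} outside [0, {end}]"
                    )

    @property
    def session_end_s(self) -> float:
        return max(b for _, b in self.halves)

    def in_match(self, t: float) -> bool:
        return any(a <= t <= b for a, b in self.halves)

    def player_on_pitch(self, player_id: str, t: float) -> bool:
        if player_id not in self.on_pitch:
            raise KeyError(f"player {player_id!r} absent from schedule")
        return any(a <= t <= b for a, b in self.on_pitch[player_id])


@dataclass
class LabeledEvent:
    """A sensor event with its video-verified header / non-header label."""

    event: SensorEventRecord
    label: str  # VH or NH
    matched_video_id: str | None = None
    match_offset_s: float | None = None
    augmented: bool = False

    def __post_init__(self) -> None:
        if self.label not in (VH, NH):
            raise SchemaError(f"label must be {VH!r} or {NH!r}, got {self.label!r}")
        if (self.label == VH) != (self.matched_video_id is not None):
            raise SchemaError("label VH iff matched_video_id present")
        if self.match_offset_s is not None and abs(self.match_offset_s) > 2.0 + 1e-12:
            raise SchemaError("match offset outside +/-2 s window")


# ---------------------------------------------------------------------------
# Sensor event tables
# ---------------------------------------------------------------------------

def _events_to_frame(events: Sequence[SensorEventRecord]) -> pd.DataFrame:
    meta = {
        "event_id": [e.event_id for e in events],
        "player_id": [e.player_id for e in events],
        "session_id": [e.session_id for e in events],
        "timestamp_s": [e.timestamp_s for e in events],
    }
    traces = (
        np.stack([e.trace.reshape(-1) for e in events])
        if events
        else np.empty((0, len(_TRACE_COLUMNS)))
    )
    return pd.concat(
        [pd.DataFrame(meta), pd.DataFrame(traces, columns=_TRACE_COLUMNS)],
        axis=1)


def write_sensor_events(events: Sequence[SensorEventRecord], path: str | Path) -> None:
    _events_to_frame(events).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sensor_events(path: str | Path) -> list[SensorEventRecord]:
    frame = pd.read_csv(path, dtype={"event_id": str, "player_id": str, "session_id": str},
                        float_precision="round_trip")
    missing = [c for c in ["event_id", "player_id", "session_id", "timestamp_s", *_TRACE_COLUMNS]
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing[:4]}{'...' if len(missing) > 4 else ''}")
    events = []
    for i, row in enumerate(frame.itertuples(index=False)):
        trace = np.asarray([getattr(row, c) for c in _TRACE_COLUMNS], dtype=float)
        try:
            events.append(
                SensorEventRecord(
                    event_id=row.event_id,
                    player_id=row.player_id,
                    session_id=row.session_id,
                    timestamp_s=float(row.timestamp_s),
                    trace=trace.reshape(len(AXES), N_SAMPLES),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}, data row {i + 1}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# Video logs and schedules
# ---------------------------------------------------------------------------

def write_video_log(records: Sequence[VideoHeaderRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "video_id": [r.video_id for r in records],
            "player_id": [r.player_id for r in records],
            "session_id": [r.session_id for r in records],
            "timestamp_s": [r.timestamp_s for r in records],
            "half_index": [r.half_index for r in records],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_video_log(path: str | Path) -> list[VideoHeaderRecord]:
    frame = pd.read_csv(path, dtype={"video_id": str, "player_id": str, "session_id": str})
    try:
        return [
            VideoHeaderRecord(
                video_id=row.video_id,
                player_id=row.player_id,
                session_id=row.session_id,
                timestamp_s=float(row.timestamp_s),
                half_index=int(row.half_index),
            )
            for row in frame.itertuples(index=False)
        ]
    except (AttributeError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed video log ({exc})") from exc


def write_schedule(schedule: MatchSchedule, path: str | Path) -> None:
    rows = [
        {"session_id": schedule.session_id, "kind": "half", "player_id": "",
         "start_s": a, "end_s": b}
        for a, b in schedule.halves
    ]
    for player, ivals in schedule.on_pitch.items():
        rows.extend(
            {"session_id": schedule.session_id, "kind": "on_pitch",
             "player_id": player, "start_s": a, "end_s": b}
            for a, b in ivals
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_schedule(path: str | Path) -> MatchSchedule:
    frame = pd.read_csv(path, dtype={"session_id": str, "player_id": str, "kind": str},
                        keep_default_na=False)
    if frame.empty:
        raise SchemaError(f"{path}: empty schedule")
    session_ids = frame["session_id"].unique()
    if len(session_ids) != 1:
        raise SchemaError(f"{path}: schedule must describe one session, got {list(session_ids)}")
    halves, on_pitch = [], {}
    for row in frame.itertuples(index=False):
        interval = (float(row.start_s), float(row.end_s))
        if row.kind == "half":
            halves.append(interval)
        elif row.kind == "on_pitch":
            on_pitch.setdefault(row.player_id, []).append(interval)
        else:
            raise SchemaError(f"{path}: unknown schedule row kind {row.kind!r}")
    return MatchSchedule(session_id=session_ids[0], halves=sorted(halves), on_pitch=on_pitch)


# ---------------------------------------------------------------------------
# Labeled datasets
# ---------------------------------------------------------------------------

def write_labeled_events(labeled: Sequence[LabeledEvent], path: str | Path) -> None:
    frame = _events_to_frame([le.event for le in labeled])
    extra = pd.DataFrame(
        {
            "label": [le.label for le in labeled],
            "matched_video_id": [le.matched_video_id or "" for le in labeled],
            "match_offset_s": [np.nan if le.match_offset_s is None else le.match_offset_s
                               for le in labeled],
            "augmented": [int(le.augmented) for le in labeled],
        }
    )
    pd.concat([frame, extra], axis=1).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_labeled_events(path: str | Path) -> list[LabeledEvent]:
    frame = pd.read_csv(
        path,
        dtype={"event_id": str, "player_id": str, "session_id": str,
               "label": str, "matched_video_id": str},
        keep_default_na=False,
        na_values={"match_offset_s": [""]},
        float_precision="round_trip",
    )
    labeled = []
    for i, row in enumerate(frame.itertuples(index=False)):
        trace = np.asarray([getattr(row, c) for c in _TRACE_COLUMNS], dtype=float)
        try:
            event = SensorEventRecord(
                event_id=row.event_id,
                player_id=row.player_id,
                session_id=row.session_id,
                timestamp_s=float(row.timestamp_s),
                trace=trace.reshape(len(AXES), N_SAMPLES),
            )
            offset = float(row.match_offset_s)
            labeled.append(
                LabeledEvent(
                    event=event,
                    label=row.label,
                    matched_video_id=row.matched_video_id or None,
                    match_offset_s=None if np.isnan(offset) else offset,
                    augmented=bool(int(row.augmented)),
                )
            )
        except (SchemaError, ValueError) as exc:
            raise SchemaError(f"{path}, data row {i + 1}: {exc}") from exc
    return labeled


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated bundle of simulation, prep, training and evaluation settings.

    Sub-configurations live with the modules that consume them; this record
    only assembles and cross-validates them from a single YAML document.
    """

    simulation: "object"
    waveform: "object"
    network: "object"
    training: "object"
    split: "object"
    augmentation: "object"
    evaluation: "object"


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> PipelineConfig:
    """Load a YAML config, apply documented defaults, validate all ranges.

    An absent or empty file yields the package defaults.  Unknown keys and
    out-of-range values raise :class:`ConfigError` naming the offending key.
    """
    from . import classifier, evaluation, prep, simulator  # local: avoid cycle

    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}

    sections = {
        "simulation": simulator.SessionConfig,
        "waveform": simulator.WaveformParams,
        "network": classifier.NetworkConfig,
        "training": classifier.TrainingConfig,
        "split": prep.SplitSpec,
        "augmentation": prep.AugmentationSpec,
        "evaluation": evaluation.ScenarioSpec,
    }
    unknown = set(raw) - set(sections)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    built = {}
    for name, cls in sections.items():
        body = raw.get(name, {}) or {}
        if not isinstance(body, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        valid_fields = {f for f in cls.__dataclass_fields__}
        bad = set(body) - valid_fields
        if bad:
            raise ConfigError(f"section {name!r}: unknown key(s) {sorted(bad)}")
        try:
            built[name] = cls(**body)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"section {name!r}: {exc}") from exc
    return PipelineConfig(**built)
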