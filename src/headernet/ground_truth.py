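"""Video-verified ground-truth labeling of triggered sensor events.

The labeling pipeline mirrors how header surveillance studies build their
reference datasets: sensor events recorded outside verified match times are
excluded, events from players not on the pitch are excluded, and each
remaining event is matched to the video header log of the same player
within a +/-2 s window.  A matched event is a valid header (VH); every
retained unmatched event is a non-header (NH).  Video headers with no
sensor event inside the window (the sub-threshold headers the device never
captured) are dropped from the ground truth and reported as unmatched.

Where several sensor events compete for one video header (or vice versa)
the assignment is a globally greedy one-to-one minimum-|dt| matching with
deterministic tie-breaking (earlier sensor timestamp, then event id), which
makes the result independent of input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import (
    NH,
    VH,
    LabeledEvent,
    MatchSchedule,
    SensorEventRecord,
    VideoHeaderRecord,
)

DEFAULT_WINDOW_S = 2.0


@dataclass
class LabelingReport:
    """Count bookkeeping of the labeling pipeline; every event is accounted for."""

    raw_events: int
    removed_out_of_match: int
    removed_off_pitch: int
    retained: int
    vh: int
    nh: int
    unmatched_video_headers: int

    def __post_init__(self) -> None:
        if self.retained != self.vh + self.nh:
            raise ValueError("retained != VH + NH")
        if self.raw_events != self.retained + self.removed_out_of_match + self.removed_off_pitch:
            raise ValueError("raw != retained + removed")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _schedule_for(event, schedules: dict[str, MatchSchedule]) -> MatchSchedule:
    try:
        return schedules[event.session_id]
    except KeyError:
        raise KeyError(f"event {event.event_id!r} references unknown session "
                       f"{event.session_id!r}") from None


def _as_schedule_map(schedule) -> dict[str, MatchSchedule]:
    if isinstance(schedule, MatchSchedule):
        return {schedule.session_id: schedule}
    return {s.session_id: s for s in schedule}


def filter_match_time(events: list[SensorEventRecord], schedule):
    """Partition events into (kept, removed) by the closed half intervals."""
    schedules = _as_schedule_map(schedule)
    kept, removed = [], []
    for e in events:
        (kept if _schedule_for(e, schedules).in_match(e.timestamp_s)
         else removed).append(e)
    return kept, removed


def filter_on_pitch(events: list[SensorEventRecord], schedule):
    """Partition events into (kept, removed) by the player's on-pitch intervals."""
    schedules = _as_schedule_map(schedule)
    kept, removed = [], []
    for e in events:
        sched = _schedule_for(e, schedules)
        (kept if sched.player_on_pitch(e.player_id, e.timestamp_s)
         else removed).append(e)
    return kept, removed


def match_events(events: list[SensorEventRecord],
                 video_headers: list[VideoHeaderRecord],
                 window_s: float = DEFAULT_WINDOW_S):
    """One-to-one minimum-|dt| matching of sensor events to video headers.

    Candidate pairs are same player and session with |dt| <= ``window_s``;
    pairs are consumed greedily by ascending |dt|, ties broken by earlier
    sensor timestamp then lexicographic event id.  Returns
    ``(assignments, unmatched_headers)`` where assignments maps
    ``event_id -> (video_id, signed offset sensor - video)``.
    """
    if window_s < 0:
        raise ValueError("matching window must be nonnegative")
    candidates = []
    for vi, v in enumerate(video_headers):
        for e in events:
            if e.player_id != v.player_id or e.session_id != v.session_id:
                continue
            dt = e.timestamp_s - v.timestamp_s
            if abs(dt) <= window_s:
                candidates.append((abs(dt), e.timestamp_s, e.event_id, vi, dt))
    candidates.sort()
    assignments: dict[str, tuple[str, float]] = {}
    used_videos: set[int] = set()
    for _, _, event_id, vi, dt in candidates:
        if event_id in assignments or vi in used_videos:
            continue
        assignments[event_id] = (video_headers[vi].video_id, dt)
        used_videos.add(vi)
    unmatched = [v for i, v in enumerate(video_headers) if i not in used_videos]
    return assignments, unmatched


def build_ground_truth(events: list[SensorEventRecord],
                       video_log: list[VideoHeaderRecord],
                       schedule,
                       window_s: float = DEFAULT_WINDOW_S):
    """Filter, match and label sensor events; returns (labeled, report)."""
    in_match, out_of_match = filter_match_time(events, schedule)
    on_pitch, off_pitch = filter_on_pitch(in_match, schedule)
    assignments, unmatched = match_events(on_pitch, video_log, window_s)
    labeled = []
    for e in on_pitch:
        if e.event_id in assignments:
            video_id, dt = assignments[e.event_id]
            labeled.append(LabeledEvent(event=e, label=VH,
                                        matched_video_id=video_id,
                                        match_offset_s=dt))
        else:
            labeled.append(LabeledEvent(event=e, label=NH))
    report = LabelingReport(
        raw_events=len(events),
        removed_out_of_match=len(out_of_match),
        removed_off_pitch=len(off_pitch),
        retained=len(on_pitch),
        vh=len(assignments),
        nh=len(on_pitch) - len(assignments),
        unmatched_video_headers=len(unmatched),
    )
    return labeled, report
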