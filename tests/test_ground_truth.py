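"""Filtering, +/-2 s matching and label bookkeeping."""

import numpy as np
import pytest

import headernet as hn
from headernet.ground_truth import (
    LabelingReport,
    build_ground_truth,
    filter_match_time,
    filter_on_pitch,
    match_events,
)
from headernet.io_formats import MatchSchedule, SensorEventRecord, VideoHeaderRecord


def _event(eid, player, t, rng):
    return SensorEventRecord(event_id=eid, player_id=player, session_id="S001",
                             timestamp_s=t, trace=rng.normal(size=(3, 100)))


def _video(vid, player, t, half=1):
    return VideoHeaderRecord(video_id=vid, player_id=player, session_id="S001",
                             timestamp_s=t, half_index=half)


@pytest.fixture()
def schedule():
    return MatchSchedule(
        session_id="S001",
        halves=[(100.0, 2800.0), (3700.0, 6400.0)],
        on_pitch={"P00": [(100.0, 6400.0)], "P01": [(100.0, 4000.0)]})


class TestFilters:
    def test_half_time_event_removed(self, schedule, rng):
        kept, removed = filter_match_time([_event("E0", "P00", 3000.0, rng)], schedule)
        assert kept == [] and len(removed) == 1

    def test_event_at_half_start_kept(self, schedule, rng):
        kept, removed = filter_match_time([_event("E0", "P00", 100.0, rng)], schedule)
        assert len(kept) == 1 and removed == []

    def test_partition_is_exhaustive_and_disjoint(self, schedule, rng):
        events = [_event(f"E{i}", "P00", t, rng)
                  for i, t in enumerate([0.0, 150.0, 2900.0, 4000.0, 6500.0])]
        kept, removed = filter_match_time(events, schedule)
        assert len(kept) + len(removed) == len(events)
        assert {e.event_id for e in kept} | {e.event_id for e in removed} \
            == {e.event_id for e in events}

    def test_substituted_player_removed_after_leaving(self, schedule, rng):
        kept, removed = filter_on_pitch([_event("E0", "P01", 4010.0, rng)], schedule)
        assert kept == [] and len(removed) == 1

    def test_on_pitch_event_kept(self, schedule, rng):
        kept, _ = filter_on_pitch([_event("E0", "P01", 3900.0, rng)], schedule)
        assert len(kept) == 1

    def test_unknown_player_is_lookup_error(self, schedule, rng):
        with pytest.raises(KeyError, match="P99"):
            filter_on_pitch([_event("E0", "P99", 200.0, rng)], schedule)

    def test_unknown_session_is_lookup_error(self, schedule, rng):
        bad = SensorEventRecord(event_id="E0", player_id="P00", session_id="S999",
                                timestamp_s=200.0, trace=rng.normal(size=(3, 100)))
        with pytest.raises(KeyError, match="S999"):
            filter_match_time([bad], schedule)

    def test_simulator_truth_filter_counts(self, small_session):
        cfg, events, _, schedule, truth = small_session
        kept, removed = filter_match_time(events, schedule)
        assert len(removed) == (truth.category == "out_of_match").sum()
        _, removed_pitch = filter_on_pitch(kept, schedule)
        assert len(removed_pitch) == (truth.category == "off_pitch").sum()


def naive_min_dt_assignment(events, videos, window=2.0):
    """Independent oracle: repeatedly scan all free pairs for the global
    minimum |dt| (ties: earlier sensor timestamp, then event id)."""
    free_events = {e.event_id: e for e in events}
    free_videos = dict(enumerate(videos))
    out = {}
    while True:
        best = None
        for eid, e in free_events.items():
            for vi, v in free_videos.items():
                if e.player_id != v.player_id or e.session_id != v.session_id:
                    continue
                dt = e.timestamp_s - v.timestamp_s
                if abs(dt) > window:
                    continue
                key = (abs(dt), e.timestamp_s, eid, vi)
                if best is None or key < best[0]:
                    best = (key, eid, vi, dt)
        if best is None:
            return out
        _, eid, vi, dt = best
        out[eid] = (videos[vi].video_id, dt)
        del free_events[eid]
        del free_videos[vi]


class TestMatching:
    def test_inside_window_assigned(self, rng):
        events = [_event("E0", "P00", 101.9, rng)]
        videos = [_video("V0", "P00", 100.0)]
        assignments, unmatched = match_events(events, videos)
        assert assignments["E0"][0] == "V0"
        assert assignments["E0"][1] == pytest.approx(1.9)
        assert unmatched == []

    def test_outside_window_unmatched(self, rng):
        events = [_event("E0", "P00", 102.5, rng)]
        videos = [_video("V0", "P00", 100.0)]
        assignments, unmatched = match_events(events, videos)
        assert assignments == {} and unmatched == videos

    def test_closest_competitor_wins(self, rng):
        events = [_event("E0", "P00", 100.3, rng), _event("E1", "P00", 99.0, rng)]
        videos = [_video("V0", "P00", 100.0)]
        assignments, _ = match_events(events, videos)
        assert set(assignments) == {"E0"}

    def test_other_player_never_matches(self, rng):
        events = [_event("E0", "P01", 100.1, rng)]
        videos = [_video("V0", "P00", 100.0)]
        assignments, unmatched = match_events(events, videos)
        assert assignments == {} and len(unmatched) == 1

    def test_negative_window_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            match_events([], [], window_s=-1.0)

    def test_agrees_with_naive_oracle_on_dense_clusters(self, rng):
        """Sorted greedy equals a repeated-global-minimum scan on crowded
        windows, and the result is maximal (no free in-window pair remains)."""
        for seed in range(20):
            local = np.random.default_rng(seed)
            events = [_event(f"E{i}", f"P{local.integers(2)}",
                             100.0 + float(local.uniform(-4, 4)), rng)
                      for i in range(6)]
            videos = [_video(f"V{j}", f"P{local.integers(2)}",
                             100.0 + float(local.uniform(-2, 2)))
                      for j in range(3)]
            assignments, unmatched = match_events(events, videos)
            oracle = naive_min_dt_assignment(events, videos)
            assert assignments == oracle
            matched_events = set(assignments)
            for v in unmatched:
                for e in events:
                    if e.event_id in matched_events or e.player_id != v.player_id:
                        continue
                    assert abs(e.timestamp_s - v.timestamp_s) > 2.0

    def test_permutation_invariance(self, rng):
        events = [_event(f"E{i}", "P00", 100.0 + 0.7 * i, rng) for i in range(4)]
        videos = [_video(f"V{j}", "P00", 100.5 + 1.1 * j) for j in range(3)]
        a1, _ = match_events(events, videos)
        a2, _ = match_events(events[::-1], videos[::-1])
        assert a1 == a2

    def test_window_zero_only_exact_hits(self, rng):
        events = [_event("E0", "P00", 100.0, rng), _event("E1", "P00", 100.4, rng)]
        videos = [_video("V0", "P00", 100.0)]
        a, _ = match_events(events, videos, window_s=0.0)
        assert set(a) == {"E0"}


class TestBuildGroundTruth:
    def test_reference_count_identity(self, rng):
        """retained - matched = NH, on a small analogue of the study's counts."""
        report = LabelingReport(raw_events=30, removed_out_of_match=5,
                                removed_off_pitch=3, retained=22, vh=4, nh=18,
                                unmatched_video_headers=1)
        assert report.nh == report.retained - report.vh

    def test_count_identities_enforced(self):
        with pytest.raises(ValueError, match="retained"):
            LabelingReport(raw_events=10, removed_out_of_match=0,
                           removed_off_pitch=0, retained=10, vh=3, nh=6,
                           unmatched_video_headers=0)

    def test_zero_video_headers_all_nh(self, schedule, rng):
        events = [_event(f"E{i}", "P00", 200.0 + 10 * i, rng) for i in range(5)]
        labeled, report = build_ground_truth(events, [], schedule)
        assert all(le.label == "NH" for le in labeled)
        assert report.vh == 0 and report.nh == 5

    def test_simulator_truth_agreement_is_total(self, small_session, labeled_small):
        """Labels equal the truth table under the simulator's separation rules."""
        _, _, _, _, truth = small_session
        labeled, report = labeled_small
        truth_labels = dict(zip(truth.event_id, truth.label))
        assert len(labeled) == report.retained
        assert all(le.label == truth_labels[le.event.event_id] for le in labeled)
        # VH events matched to the intended video header, not merely any header
        truth_vid = dict(zip(truth.event_id, truth.matched_video_id))
        for le in labeled:
            if le.label == "VH":
                assert le.matched_video_id == truth_vid[le.event.event_id]

    def test_report_counts_mirror_truth_categories(self, small_session, labeled_small):
        _, events, _, _, truth = small_session
        _, report = labeled_small
        counts = truth.category.value_counts()
        assert report.raw_events == len(events)
        assert report.removed_out_of_match == counts.get("out_of_match", 0)
        assert report.removed_off_pitch == counts.get("off_pitch", 0)
        assert report.vh == counts.get("header", 0)
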