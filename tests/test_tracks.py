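"""Migration metrics: exactness fixtures, invariances, encounter logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nksearch import (
    Track,
    classify_encounters,
    filter_immobile,
    persistence,
    read_tracks_csv,
    step_sizes,
    track_metrics,
    velocity,
    write_tracks_csv,
)
from nksearch.tracks import attracted_fraction


def _track(points, dt=30.0, tid="t0"):
    pts = np.asarray(points, float)
    return Track(tid, np.arange(len(pts)) * dt, pts)


class TestVelocity:
    def test_straight_line_constant_speed(self):
        # 10 um in 60 s -> 10 um/min
        tr = _track([[0, 0], [5, 0], [10, 0]], dt=30.0)
        assert velocity(tr) == pytest.approx(10.0)

    def test_stationary_track_zero_velocity(self):
        tr = _track([[1, 1], [1, 1], [1, 1]])
        assert velocity(tr) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            velocity(Track("x", [0.0], np.zeros((1, 2))))


class TestPersistence:
    def test_straight_line_is_one(self):
        assert persistence(_track([[0, 0], [3, 4], [6, 8]])) == 1.0

    def test_closed_loop_is_zero(self):
        square = [[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]
        assert persistence(_track(square)) == 0.0

    def test_immobile_track_rejected(self):
        with pytest.raises(ValueError, match="immobile"):
            persistence(_track([[2, 2], [2, 2]]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(rng.integers(2, 30), 2)), axis=0)
        tr = Track("r", np.arange(len(pts)) * 20.0, pts)
        if tr.path_length > 0:
            assert 0.0 <= persistence(tr) <= 1.0


class TestRigidMotionInvariance:
    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_velocity_steps_persistence_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(scale=3.0, size=(12, 2)), axis=0)
        t = np.cumsum(rng.uniform(16.8, 38.2, size=12))
        tr = Track("a", t, pts)
        th = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = rng.uniform(-100, 100, size=2)
        tr2 = Track("b", t, pts @ rot.T + shift)
        assert velocity(tr2) == pytest.approx(velocity(tr), rel=1e-9)
        np.testing.assert_allclose(step_sizes(tr2), step_sizes(tr), rtol=1e-9)
        assert persistence(tr2) == pytest.approx(persistence(tr), rel=1e-9)
        # persistence is also invariant under uniform time rescaling
        tr3 = Track("c", 3.0 * t, pts)
        assert persistence(tr3) == persistence(tr)


class TestFilterImmobile:
    def test_all_stationary_dropped(self):
        tracks = [_track([[0, 0], [0.1, 0], [0, 0]], tid=f"s{i}")
                  for i in range(3)]
        assert filter_immobile(tracks) == []

    def test_known_mobile_count_survives(self):
        mobile = [_track([[0, 0], [20, 0]], tid=f"m{i}") for i in range(4)]
        still = [_track([[0, 0], [1, 0]], tid=f"s{i}") for i in range(3)]
        kept = filter_immobile(mobile + still, displacement_threshold=10.0)
        assert [t.track_id for t in kept] == [t.track_id for t in mobile]

    def test_zero_threshold_keeps_everything_moving(self):
        tracks = [_track([[0, 0], [0.5, 0]], tid="a")]
        assert filter_immobile(tracks, displacement_threshold=0.0) == tracks


class TestEncounters:
    BY = [((0.0, 0.0), 7.5)]  # bystander of radius 7.5 um at the origin

    def test_far_track_has_no_encounters(self):
        tr = _track([[30, 40], [35, 40], [40, 40]])
        assert classify_encounters(tr, self.BY) == []

    def test_hand_built_attracted_event(self):
        """Radial 7-frame track; crossings fall exactly on frames, so the
        phase durations equal the frame-time differences by construction."""
        # surface distances per frame: 15, 10, 7.5, 5, 5, 7.5, 10 -> 12
        d = np.array([15.0, 10.0, 7.5, 5.0, 5.0, 7.5, 10.0, 12.0])
        pts = np.column_stack([d + 7.5, np.zeros(d.size)])
        tr = Track("h", np.arange(d.size) * 30.0, pts)
        events = classify_encounters(tr, self.BY, approach_radius=10.0,
                                     contact_distance=7.5 + 5.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.outcome == "attracted"
        assert ev.approach_s == pytest.approx(60.0)   # frames 1 -> 3
        assert ev.touch_s == pytest.approx(30.0)      # frames 3 -> 4
        assert ev.leave_s == pytest.approx(60.0)      # frames 4 -> 6
        assert ev.total_s == pytest.approx(150.0)

    def test_passing_by_event(self):
        d = np.array([15.0, 9.0, 8.0, 9.5, 14.0])
        pts = np.column_stack([d + 7.5, np.zeros(d.size)])
        tr = Track("p", np.arange(d.size) * 25.0, pts)
        events = classify_encounters(tr, self.BY)
        assert len(events) == 1 and events[0].outcome == "passing_by"
        assert events[0].touch_s == 0.0

    def test_segmentation_idempotent(self):
        d = np.array([15.0, 8.0, 4.0, 4.0, 8.0, 15.0, 9.0, 15.0])
        pts = np.column_stack([d + 7.5, np.zeros(d.size)])
        tr = Track("i", np.arange(d.size) * 20.0, pts)
        a = classify_encounters(tr, self.BY)
        b = classify_encounters(tr, self.BY)
        assert a == b and len(a) == 2

    def test_dimension_mismatch_rejected(self):
        tr = Track("z", [0.0, 30.0], np.zeros((2, 3)))
        with pytest.raises(ValueError, match="3D"):
            classify_encounters(tr, self.BY)

    def test_attracted_fraction_inclusion_rule(self):
        from nksearch import EncounterEvent

        many = [EncounterEvent("a", i, "attracted" if i < 6 else "passing_by",
                               1.0, 1.0, 1.0) for i in range(8)]
        few = [EncounterEvent("b", i, "attracted", 1, 1, 1) for i in range(3)]
        out = attracted_fraction(many + few, min_encounters=8)
        assert out == {"a": 6 / 8}


class TestTrackCsv:
    def test_long_roundtrip_bit_exact(self, tmp_path, rng):
        pts = rng.normal(scale=50.0, size=(7, 2)) + 200.0
        t = np.cumsum(rng.uniform(16.8, 38.2, size=7))
        tracks = [Track("trk1", t, pts)]
        path = tmp_path / "tracks.csv"
        write_tracks_csv(tracks, path)
        back = read_tracks_csv(path)
        assert back[0].track_id == "trk1"
        np.testing.assert_array_equal(back[0].t, t)
        np.testing.assert_array_equal(back[0].xy, pts)
        m1, m2 = track_metrics(tracks[0]), track_metrics(back[0])
        assert m1.velocity_um_min == m2.velocity_um_min
        assert m1.persistence == m2.persistence

    def test_3d_roundtrip(self, tmp_path):
        pts = np.arange(12.0).reshape(4, 3)
        tracks = [Track("t3", np.arange(4) * 30.0, pts)]
        path = tmp_path / "t3.csv"
        write_tracks_csv(tracks, path)
        back = read_tracks_csv(path)
        assert back[0].dim == 3
        np.testing.assert_array_equal(back[0].xy, pts)

    def test_wide_dialect(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "t_seconds,x_a,y_a,x_b,y_b\n"
            "0,0.0,0.0,5.0,5.0\n"
            "30,1.0,0.0,,\n"
            "60,2.0,0.0,7.0,5.0\n"
        )
        tracks = read_tracks_csv(path, dialect="wide")
        assert [t.track_id for t in tracks] == ["a", "b"]
        assert tracks[0].n_samples == 3 and tracks[1].n_samples == 2


def test_invalid_tracks_rejected():
    with pytest.raises(ValueError):
        Track("bad", [0.0, 0.0], np.zeros((2, 2)))       # non-increasing t
    with pytest.raises(ValueError):
        Track("bad", [0.0, 1.0], np.full((2, 2), np.nan))
    with pytest.raises(ValueError):
        Track("bad", [0.0, 1.0], np.zeros((2, 4)))       # 4D
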