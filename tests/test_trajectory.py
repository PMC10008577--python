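"""Pose-track I/O, cleaning, kinematics, HMM segmentation, turning detection."""

import dataclasses
import math

import numpy as np
import pytest

from pawbias import (
    Arena,
    DataError,
    TrajectoryGenConfig,
    TurningEvent,
    UntrackableVideoError,
    ValidationError,
    angular_differences,
    approach_turning_bias,
    clean_trajectory,
    compute_speed,
    detect_turnings,
    gen_trajectory,
    heading_series,
    object_proximity,
    read_pose_tracks,
    segment_states,
    turning_bias,
    wrap_degrees,
    write_pose_tracks,
)
from pawbias.trajectory import SpeedProfile, make_trajectory


def brute_force_turns(diffs, arm=45.0, stop=2.0):
    """Independent run-scanning oracle for the turning definition.

    Walks candidate runs explicitly: a run accumulates same-sign
    differences (zeros are neutral); exceeding ``arm`` in magnitude arms
    it, after which every difference accrues until the first |d| < stop
    closes the event; an unarmed run dies at a sign flip and the scan
    restarts there; an armed run surviving to the end is emitted.
    """
    out = []
    n = len(diffs)
    i = 0
    while i < n:
        if diffs[i] == 0.0:
            i += 1
            continue
        positive = diffs[i] > 0
        total = 0.0
        armed = False
        j = i
        closed = False
        while j < n:
            d = diffs[j]
            if not armed:
                if d == 0.0:
                    j += 1
                    continue
                if (d > 0) != positive:
                    break  # run dies; rescan from here
                total += d
                j += 1
                if abs(total) > arm:
                    armed = True
            else:
                if abs(d) < stop:
                    out.append((i, j, total))
                    j += 1
                    closed = True
                    break
                total += d
                j += 1
        else:
            if armed:
                out.append((i, n - 1, total))
        if closed or armed or j > i:
            i = j
        else:
            i += 1
    return out


def straight_line_traj(n=30, step=3.0, frame_rate=30.0, arena=None):
    body = np.column_stack([np.arange(n) * step, np.zeros(n)])
    head = body + [10.0, 0.0]
    return make_trajectory({"body": body, "head": head}, frame_rate=frame_rate, arena=arena)


class TestPoseIO:
    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        body = rng.uniform(0, 500, (10, 2))
        head = body + rng.uniform(-5, 5, (10, 2))
        traj = make_trajectory({"body": body, "head": head})
        path = tmp_path / "pose.csv"
        write_pose_tracks(traj, path)
        back = read_pose_tracks(path)
        assert back.n_frames == 10
        np.testing.assert_allclose(back.xy("body"), body, atol=1e-9)
        np.testing.assert_allclose(back.xy("head"), head, atol=1e-9)

    def test_generator_round_trip(self, tmp_path):
        traj, _ = gen_trajectory(
            TrajectoryGenConfig(duration_s=5.0, object_epoch_s=2.0, seed=3)
        )
        path = tmp_path / "gen.csv"
        write_pose_tracks(traj, path)
        back = read_pose_tracks(path)
        np.testing.assert_allclose(back.xy("body"), traj.xy("body"), atol=1e-9)
        np.testing.assert_allclose(
            back.likelihood("head"), traj.likelihood("head"), atol=1e-12
        )

    def test_missing_bodypart_lists_available(self, tmp_path):
        traj = straight_line_traj()
        path = tmp_path / "pose.csv"
        write_pose_tracks(traj, path)
        with pytest.raises(ValidationError, match="nose.*body"):
            read_pose_tracks(path, required_bodyparts=("nose",))

    def test_missing_likelihood_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "scorer,s,s,s,s\n"
            "bodyparts,body,body,head,head\n"
            "coords,x,y,x,y\n"
            "0,1.0,2.0,3.0,4.0\n"
            "1,1.5,2.0,3.5,4.0\n"
        )
        with pytest.raises(ValidationError, match="likelihood"):
            read_pose_tracks(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "flat.csv"
        path.write_text("x,y\n1,2\n3,4\n")
        with pytest.raises(ValidationError):
            read_pose_tracks(path)


class TestCleaning:
    def test_constant_position_preserved(self):
        n = 20
        body = np.full((n, 2), [100.0, 200.0])
        traj = make_trajectory({"body": body, "head": body + [10, 0]})
        out = clean_trajectory(traj)
        np.testing.assert_allclose(out.xy("body"), body, atol=1e-8)

    def test_dropout_filled_on_line(self):
        n = 21
        body = np.column_stack([np.arange(n) * 2.0, np.arange(n) * 1.0])
        lik = np.ones(n)
        lik[10] = 0.0
        corrupted = body.copy()
        corrupted[10] = [9999.0, -9999.0]
        traj = make_trajectory(
            {"body": corrupted, "head": corrupted + [5, 0]},
            likelihoods={"body": lik, "head": lik},
        )
        out = clean_trajectory(traj, smoothing=0.0)
        np.testing.assert_allclose(out.xy("body")[10], body[10], atol=1e-6)
        assert (out.likelihood("body") >= 0.9).all()

    def test_smoothing_reduces_noise(self, rng):
        n = 300
        t = np.arange(n)
        true = np.column_stack([t * 1.0, 50 * np.sin(t / 20)])
        noisy = true + rng.normal(0, 2.0, true.shape)
        traj = make_trajectory({"body": noisy, "head": noisy + [8, 0]})
        out = clean_trajectory(traj, smoothing=4.0)
        rms_raw = np.sqrt(((noisy - true) ** 2).mean())
        rms_clean = np.sqrt(((out.xy("body") - true) ** 2).mean())
        assert rms_clean < rms_raw

    def test_mostly_bad_bodypart_flagged_untrackable(self, rng):
        n = 40
        body = rng.uniform(0, 100, (n, 2))
        lik = np.full(n, 0.2)
        lik[:10] = 1.0
        traj = make_trajectory(
            {"body": body, "head": body}, likelihoods={"body": lik, "head": np.ones(n)}
        )
        with pytest.raises(UntrackableVideoError):
            clean_trajectory(traj)

    def test_too_few_frames_rejected(self):
        traj = straight_line_traj(n=5)
        with pytest.raises(ValidationError):
            clean_trajectory(traj)


class TestSpeed:
    def test_stationary_subject(self):
        traj = straight_line_traj(step=0.0)
        assert compute_speed(traj).mean == 0.0

    def test_uniform_motion(self):
        traj = straight_line_traj(step=3.0)
        np.testing.assert_allclose(compute_speed(traj).speed, 3.0, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        body = rng.uniform(0, 100, (50, 2))
        traj = make_trajectory({"body": body, "head": body + [5, 0]})
        base = compute_speed(traj).speed
        for _ in range(5):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            shift = rng.uniform(-500, 500, 2)
            moved = make_trajectory(
                {"body": body @ rot.T + shift, "head": (body + [5, 0]) @ rot.T + shift}
            )
            np.testing.assert_allclose(compute_speed(moved).speed, base, atol=1e-9)

    def test_unknown_bodypart(self):
        with pytest.raises(ValidationError):
            compute_speed(straight_line_traj(), bodypart="tail")


class TestProximity:
    def test_parked_on_object(self):
        n = 30
        body = np.full((n, 2), [50.0, 60.0])
        arena = Arena(object_xy=(50.0, 60.0), object_epoch=(10, 30))
        traj = make_trajectory({"body": body, "head": body + [10, 0]}, arena=arena)
        res = object_proximity(traj)
        assert res.proportion_near == 1.0
        assert res.mean_distance == pytest.approx(0.0)
        assert res.n_frames == 20

    def test_always_far(self):
        traj = straight_line_traj(
            n=30, arena=Arena(object_xy=(10000.0, 10000.0), object_epoch=(0, 30))
        )
        assert object_proximity(traj, near_threshold=5.0).proportion_near == 0.0

    def test_circular_path_mean_distance(self):
        n, r = 200, 120.0
        theta = np.linspace(0, 4 * np.pi, n)
        body = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        arena = Arena(object_xy=(0.0, 0.0), object_epoch=(0, n))
        traj = make_trajectory({"body": body, "head": body * 1.05}, arena=arena)
        res = object_proximity(traj, near_threshold=10.0)
        assert res.mean_distance == pytest.approx(r, rel=1e-6)

    def test_epoch_outside_recording_rejected(self):
        traj = straight_line_traj(
            n=30, arena=Arena(object_xy=(0.0, 0.0), object_epoch=(10, 50))
        )
        with pytest.raises(ValidationError, match="epoch"):
            object_proximity(traj)


@pytest.fixture(scope="module")
def clean_gen():
    cfg = TrajectoryGenConfig(
        duration_s=70.0, object_epoch_s=10.0,
        tracking_noise_sd=0.0, dropout_prob=0.0, seed=21,
    )
    return gen_trajectory(cfg)


class TestSegmentation:

    def test_occupancy_sums_to_one(self, clean_gen):
        traj, _ = clean_gen
        seg = segment_states(compute_speed(traj), seed=0, n_restarts=2)
        assert sum(seg.occupancy.values()) == pytest.approx(1.0)
        assert len(seg.labels) == traj.n_frames - 1

    def test_state_ordering_by_mean(self, clean_gen):
        traj, _ = clean_gen
        seg = segment_states(compute_speed(traj), seed=0, n_restarts=2)
        assert seg.means[0] < seg.means[1] < seg.means[2]
        assert np.allclose(seg.transition_matrix.sum(axis=1), 1.0)

    def test_label_switching_invariance(self, clean_gen):
        """Different EM seeds give identical occupancies after mean-ordering."""
        traj, _ = clean_gen
        profile = compute_speed(traj)
        occupancies = [
            tuple(
                round(v, 6)
                for v in segment_states(profile, seed=s, n_restarts=1).occupancy.values()
            )
            for s in range(10)
        ]
        assert len(set(occupancies)) == 1

    def test_degenerate_single_speed_rejected(self):
        profile = SpeedProfile(speed=np.full(500, 2.0), frame_rate=30.0)
        with pytest.raises(DataError):
            segment_states(profile)

    def test_short_profile_rejected(self):
        profile = SpeedProfile(speed=np.arange(50, dtype=float), frame_rate=30.0)
        with pytest.raises(ValidationError):
            segment_states(profile)


class TestHeading:
    def test_constant_eastward_heading(self):
        traj = straight_line_traj()
        angles = heading_series(traj)
        np.testing.assert_allclose(angles, 0.0, atol=1e-12)
        np.testing.assert_allclose(angular_differences(angles), 0.0, atol=1e-12)

    def test_rigid_rotation_constant_rate(self):
        n = 50
        theta = np.radians(np.arange(n) * 5.0)
        body = np.zeros((n, 2))
        head = np.column_stack([np.cos(theta), np.sin(theta)]) * 20
        traj = make_trajectory({"body": body, "head": head})
        diffs = angular_differences(heading_series(traj))
        np.testing.assert_allclose(diffs, 5.0, atol=1e-9)

    def test_seam_wrap(self):
        assert wrap_degrees(-358.0) == pytest.approx(2.0)
        assert angular_differences([179.0, -179.0])[0] == pytest.approx(2.0)
        assert angular_differences([-179.0, 179.0])[0] == pytest.approx(-2.0)

    def test_coincident_frames_carry_forward(self):
        body = np.zeros((12, 2))
        head = np.tile([10.0, 0.0], (12, 1))
        head[5] = [0.0, 0.0]  # coincident with body
        traj = make_trajectory({"body": body, "head": head})
        angles = heading_series(traj)
        np.testing.assert_allclose(angles, 0.0, atol=1e-12)


class TestTurningDetection:
    def test_single_turn_counted_once_past_90(self):
        diffs = [10.0] * 10 + [0.0]
        events = detect_turnings(diffs)
        assert len(events) == 1
        ev = events[0]
        assert ev.cumulative_angle == pytest.approx(100.0)
        assert ev.direction == "left"
        assert (ev.start_frame, ev.end_frame) == (0, 10)

    def test_below_threshold_no_event(self):
        assert detect_turnings([4.0] * 10 + [0.0]) == []

    def test_boundary_is_strict(self):
        # exactly 45 never arms; 45.1 does
        assert detect_turnings([9.0] * 5 + [0.0]) == []
        events = detect_turnings([9.02] * 5 + [0.0])
        assert len(events) == 1

    def test_sign_change_resets_unarmed(self):
        diffs = [20.0, 20.0, -20.0, -20.0, -20.0, 0.0]
        events = detect_turnings(diffs)
        assert len(events) == 1
        assert events[0].direction == "right"
        assert events[0].cumulative_angle == pytest.approx(-60.0)

    def test_armed_event_closed_at_series_end(self):
        events = detect_turnings([10.0] * 6)
        assert len(events) == 1
        assert events[0].end_frame == 5

    def test_short_series_empty(self):
        assert detect_turnings([]) == []
        assert detect_turnings([170.0]) == []

    def test_mirror_swaps_directions(self, rng):
        diffs = rng.normal(0, 12, 500)
        fwd = detect_turnings(diffs)
        mirrored = detect_turnings(-diffs)
        assert len(fwd) == len(mirrored)
        for a, b in zip(fwd, mirrored):
            assert a.start_frame == b.start_frame
            assert a.end_frame == b.end_frame
            assert a.cumulative_angle == pytest.approx(-b.cumulative_angle)
            assert {a.direction, b.direction} in ({"left", "right"}, {a.direction})

    def test_matches_brute_force_oracle(self):
        """Exact agreement (count + boundaries) on 100 random seeded series."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 400))
            diffs = rng.normal(0, rng.uniform(2, 20), n)
            # sprinkle exact zeros and sub-stop values
            mask = rng.random(n) < 0.15
            diffs[mask] = rng.uniform(-1.5, 1.5, mask.sum())
            events = detect_turnings(diffs)
            expected = brute_force_turns(diffs)
            got = [(e.start_frame, e.end_frame, e.cumulative_angle) for e in events]
            assert len(got) == len(expected), seed
            for (gs, ge, ga), (es, ee, ea) in zip(got, expected):
                assert (gs, ge) == (es, ee), seed
                assert ga == pytest.approx(ea, abs=1e-9)


class TestTurningBias:
    def _event(self, start, end, angle):
        return TurningEvent(start, end, angle, "left" if angle > 0 else "right")

    def test_balanced_events(self):
        events = [self._event(i, i + 5, 90.0) for i in range(0, 50, 10)] + [
            self._event(i, i + 5, -90.0) for i in range(50, 100, 10)
        ]
        assert turning_bias(events) == 0.5

    def test_no_events_is_missing(self):
        assert math.isnan(turning_bias([]))

    def test_approach_bias_missing_without_epoch_events(self):
        traj = straight_line_traj(
            n=30, arena=Arena(object_xy=(1000.0, 0.0), object_epoch=(20, 30))
        )
        assert math.isnan(approach_turning_bias([self._event(2, 5, 90.0)], traj))

    def test_approach_bias_all_left(self):
        # body moves straight toward the object: distance strictly decreasing
        traj = straight_line_traj(
            n=30, arena=Arena(object_xy=(1000.0, 0.0), object_epoch=(0, 30))
        )
        events = [self._event(3, 6, 100.0), self._event(10, 14, 80.0)]
        assert approach_turning_bias(events, traj) == 1.0

    def test_equals_global_bias_when_always_approaching(self):
        traj = straight_line_traj(
            n=40, arena=Arena(object_xy=(1000.0, 0.0), object_epoch=(0, 40))
        )
        events = [
            self._event(1, 4, 90.0),
            self._event(8, 12, -70.0),
            self._event(20, 25, 120.0),
        ]
        assert approach_turning_bias(events, traj) == turning_bias(events)

    def test_recovers_injected_bias(self):
        """70:30 left:right injection recovered within +-0.05 at ~200 events."""
        directions = []
        for seed in range(4):
            cfg = TrajectoryGenConfig(
                duration_s=300.0, turn_rate=(0.02, 0.02, 0.02),
                left_turn_prob=0.7, tracking_noise_sd=0.0, dropout_prob=0.0,
                seed=100 + seed,
            )
            _, truth = gen_trajectory(cfg)
            directions += [e.direction for e in truth.events]
        assert len(directions) >= 200
        bias = sum(d == "left" for d in directions) / len(directions)
        assert bias == pytest.approx(0.7, abs=0.05)
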