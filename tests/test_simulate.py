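"""Synthetic-data generator tests: walkers, locomotion, gaze, pupil, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch

from swgaze.geometry import Ray, intersect_gaze_rays
from swgaze.io import TrialLogParseError, read_trial_log, write_trial_log
from swgaze.scene import enumerate_conditions
from swgaze.simulate import (
    GazeEventParams,
    ParticipantPolicy,
    PupilParams,
    simulate_gaze,
    simulate_participant,
    simulate_pupil,
    simulate_trial,
    simulate_walkers,
)


class TestWalkers:
    def test_finite_difference_speed_is_exact(self, layout, condition):
        tracks = simulate_walkers(layout, condition, duration=3.0)
        for tr in tracks[:5]:
            v = np.diff(tr.x) / np.diff(tr.t)
            assert np.allclose(np.abs(v), 1.3, atol=1e-9)

    def test_row_spacing_exact_at_every_shared_frame(self, layout, condition):
        tracks = simulate_walkers(layout, condition, duration=3.0)
        for row in (1, 2):
            xs = np.array([tr.x for tr in tracks if tr.row == row])
            for j in range(0, xs.shape[1], 40):
                gaps = np.diff(np.sort(xs[:, j]))
                assert np.allclose(gaps, 2.5, atol=1e-9)

    def test_rows_move_in_opposite_directions(self, layout, condition):
        tracks = simulate_walkers(layout, condition, duration=2.0)
        d1 = {tr.direction for tr in tracks if tr.row == 1}
        d2 = {tr.direction for tr in tracks if tr.row == 2}
        assert len(d1) == 1 and len(d2) == 1 and d1 != d2

    def test_z_fixed_per_row(self, layout, condition):
        tracks = simulate_walkers(layout, condition, duration=1.0)
        assert {tr.z for tr in tracks if tr.row == 1} == {layout.row1_z}
        assert {tr.z for tr in tracks if tr.row == 2} == {layout.row2_z}

    @pytest.mark.parametrize("kwargs", [{"speed_mps": 0.0}, {"duration": -1.0}])
    def test_invalid_parameters_rejected(self, layout, condition, kwargs):
        with pytest.raises(ValueError):
            simulate_walkers(layout, condition, **{"duration": 3.0, **kwargs})


class TestParticipant:
    def test_ballistic_case_monotone_z_flat_speed(self, layout, condition):
        policy = ParticipantPolicy(dip_depth=0.0, hook_probability=0.0, lateral_jitter_m=0.0)
        res = simulate_participant(policy, layout, condition, seed=1)
        z = res.head_pos[:, 2]
        assert np.all(np.diff(z) >= 0)
        moving = z > 0.2
        speed = np.hypot(
            np.gradient(res.head_pos[:, 0], res.t), np.gradient(z, res.t)
        )
        inner = moving & (z < 5.5)
        assert np.std(speed[inner]) < 0.08 * policy.base_speed_mps

    def test_velocity_dip_depth_matches_speed_law(self, layout, condition):
        policy = ParticipantPolicy(dip_depth=0.5, hook_probability=0.0)
        res = simulate_participant(policy, layout, condition, seed=2)
        z = res.head_pos[:, 2]
        speed = np.hypot(
            np.gradient(res.head_pos[:, 0], res.t), np.gradient(z, res.t)
        )
        near_dip = np.abs(z - policy.dip_center_z) < 0.15
        assert np.mean(speed[near_dip]) == pytest.approx(
            0.5 * policy.base_speed_mps, rel=0.1
        )

    def test_forced_hook_crosses_bench_zone_on_wrong_side(self, layout, condition):
        policy = ParticipantPolicy(hook_probability=1.0)
        res = simulate_participant(policy, layout, condition, seed=3)
        assert res.path_class == "hooked"
        z = res.head_pos[:, 2]
        i = int(np.argmin(np.abs(z - 3.05)))
        x_mid = res.head_pos[i, 0]
        target_sign = -1.0 if condition.gate_side == "left" else 1.0
        assert np.sign(x_mid) == -target_sign

    def test_trajectory_starts_at_origin_ends_at_target_gate(self, layout, condition):
        res = simulate_participant(ParticipantPolicy(hook_probability=0.0), layout, condition, seed=4)
        assert np.allclose(res.head_pos[0, [0, 2]], [0.0, 0.0], atol=1e-9)
        gx = -1.25 if condition.gate_side == "left" else 1.25
        assert res.head_pos[-1, 0] == pytest.approx(gx, abs=0.2)
        assert res.head_pos[-1, 2] == pytest.approx(layout.room_length_z, abs=0.05)

    def test_never_enters_static_colliders(self, layout, condition):
        for seed in range(6):
            res = simulate_participant(ParticipantPolicy(), layout, condition, seed=seed)
            for obj in layout.static_obstacles():
                lo, hi = obj.bounds()
                inside = (
                    (res.head_pos[:, 0] > lo[0]) & (res.head_pos[:, 0] < hi[0])
                    & (res.head_pos[:, 2] > lo[2]) & (res.head_pos[:, 2] < hi[2])
                )
                assert not inside.any(), f"entered {obj.id} (seed {seed})"

    def test_infeasible_clearance_flags_failure_not_exception(self, layout, condition):
        res = simulate_participant(
            ParticipantPolicy(clearance_m=1.3), layout, condition, seed=0
        )
        assert res.failed and "clearance" in res.failure_reason


class TestWalkerClearance:
    def test_min_distance_to_walkers_respects_clearance(self, layout, condition):
        for seed in range(4):
            log = simulate_trial(layout, condition, seed=seed, with_gaze=False)
            head = log.frames[["head_x", "head_z"]].to_numpy()
            t = log.t()
            dmin = np.inf
            for tr in log.walker_tracks:
                x = np.interp(t, tr.t, tr.x)
                d = np.hypot(head[:, 0] - x, head[:, 1] - tr.z)
                dmin = min(dmin, float(d.min()))
            assert dmin >= 0.3


class TestGaze:
    def test_single_fixation_zero_noise_vergence_recovers_sign(self, layout, condition):
        fs = 80.0
        n = 40
        t = np.arange(n) / fs
        head = np.tile([0.0, 1.6, 0.0], (n, 1))
        tracks = simulate_walkers(layout, condition, 0.5)
        schedule = {
            p: [("gate_indicator", 1.0)]
            for p in (
                "initial_preparation",
                "approaching_first_row",
                "approaching_second_row",
                "approaching_gate",
            )
        }
        params = GazeEventParams(noise_deg=0.0, fixation_mean_s=10.0, fixation_sd_s=0.001)
        g = simulate_gaze(t, head, layout, tracks, condition, seed=0, schedule=schedule, params=params)
        sign_pos = np.asarray(layout.object_by_id("gate_indicator").position)
        for i in (0, 10, 30):
            gp = intersect_gaze_rays(
                Ray(g["eyeL_origin"][i], g["eyeL_dir"][i]),
                Ray(g["eyeR_origin"][i], g["eyeR_dir"][i]),
            )
            # Within 1 mm of the sign (the generator jitters the anchor on
            # the sign's surface by a few cm, identical across frames).
            assert np.linalg.norm(gp.point - g["gaze_point"][i]) < 1e-3
            assert np.linalg.norm(gp.point - sign_pos) < 0.15

    def test_pursuit_gaze_point_velocity_tracks_walker(self, layout, condition):
        fs = 80.0
        n = 400
        t = np.arange(n) / fs
        head = np.tile([0.0, 1.6, 0.0], (n, 1))
        tracks = simulate_walkers(layout, condition, 5.0)
        schedule = {
            p: [("walker_row2", 1.0)]
            for p in (
                "initial_preparation",
                "approaching_first_row",
                "approaching_second_row",
                "approaching_gate",
            )
        }
        params = GazeEventParams(noise_deg=0.0, pursuit_mean_s=10.0, pursuit_sd_s=0.001)
        g = simulate_gaze(t, head, layout, tracks, condition, seed=0, schedule=schedule, params=params)
        run = g["event_label"] == "pursuit"
        vx = np.gradient(g["gaze_point"][:, 0], t)
        assert abs(np.median(np.abs(vx[run]))) == pytest.approx(1.3, rel=0.05)

    def test_seeded_stream_is_reproducible(self, layout, condition):
        fs = 80.0
        n = 200
        t = np.arange(n) / fs
        head = np.tile([0.0, 1.6, 0.0], (n, 1))
        tracks = simulate_walkers(layout, condition, 2.5)
        a = simulate_gaze(t, head, layout, tracks, condition, seed=5)
        b = simulate_gaze(t, head, layout, tracks, condition, seed=5)
        assert np.array_equal(a["eyeL_dir"], b["eyeL_dir"])
        assert np.array_equal(a["event_label"], b["event_label"])

    def test_empty_phase_pool_rejected(self, layout, condition):
        t = np.arange(10) / 80.0
        head = np.tile([0.0, 1.6, 0.0], (10, 1))
        with pytest.raises(ValueError, match="empty target pool"):
            simulate_gaze(
                t, head, layout, simulate_walkers(layout, condition, 0.2),
                condition, seed=0, schedule={"initial_preparation": []},
            )

    def test_event_label_proportions_match_schedule(self, layout, condition):
        # With all-static targets every non-transition frame is a fixation;
        # saccade/PSO frames are the bridging events.
        fs = 80.0
        n = 10_000
        t = np.arange(n) / fs
        head = np.tile([0.0, 1.6, 0.0], (n, 1))
        tracks = simulate_walkers(layout, condition, n / fs)
        g = simulate_gaze(t, head, layout, tracks, condition, seed=7)
        labels, counts = np.unique(g["event_label"], return_counts=True)
        by = dict(zip(labels, counts))
        assert set(by) == {"fixation", "saccade", "pso", "pursuit"}
        # Fixation+pursuit dominate; saccades bridge events briefly.
        assert (by["fixation"] + by["pursuit"]) / n > 0.6
        assert by["saccade"] / n < 0.3


class TestPupil:
    def test_zero_load_zero_noise_constant_baseline(self):
        t = np.arange(800) / 80.0
        p = simulate_pupil(
            t, 0.0, baseline_mm=4.0, seed=0,
            params=PupilParams(lf_amp_mm=0.0, noise_sd_mm=0.0),
        )
        assert np.allclose(p, 4.0, atol=1e-12)

    def test_doubling_load_doubles_high_band_power(self):
        fs = 80.0
        t = np.arange(int(120 * fs)) / fs
        params = PupilParams(noise_sd_mm=0.0, lf_amp_mm=0.0)
        powers = []
        for load in (1.0, 2.0):
            p = simulate_pupil(t, load, seed=0, params=params)
            freqs, psd = welch(p - p.mean(), fs=fs, nperseg=4096)
            # With the slow oscillation disabled, everything above 0.5 Hz
            # is the load-driven component (duty-cycle gating spreads the
            # carrier into sidebands, so integrate the whole band).
            band = freqs > 0.5
            powers.append(np.trapezoid(psd[band], freqs[band]))
        assert powers[1] == pytest.approx(2.0 * powers[0], rel=0.15)

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            simulate_pupil(np.arange(10) / 80.0, -1.0)

    def test_strictly_positive_and_reproducible(self):
        t = np.arange(1600) / 80.0
        a = simulate_pupil(t, 1.5, seed=3)
        b = simulate_pupil(t, 1.5, seed=3)
        assert np.array_equal(a, b)
        assert np.all(a > 0)


class TestTrialLogIO:
    def test_round_trip_identity(self, trial_log, tmp_path):
        path = write_trial_log(trial_log, tmp_path / "trial")
        back = read_trial_log(path)
        pd.testing.assert_frame_equal(
            back.frames, trial_log.frames, rtol=0.0, atol=1e-9
        )
        assert back.condition == trial_log.condition
        assert back.layout.to_dict() == trial_log.layout.to_dict()
        assert back.truth == trial_log.truth
        assert len(back.walker_tracks) == len(trial_log.walker_tracks)
        for a, b in zip(back.walker_tracks, trial_log.walker_tracks):
            assert a.agent_id == b.agent_id
            assert np.allclose(a.x, b.x, atol=1e-9)

    def test_truncated_frame_table_raises_named_parse_error(self, trial_log, tmp_path):
        path = write_trial_log(trial_log, tmp_path / "trial")
        frames_csv = path / "frames.csv"
        lines = frames_csv.read_text().splitlines()
        lines[5] = lines[5].split(",")[0]  # drop all but one field on line 5
        frames_csv.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrialLogParseError, match="frames.csv"):
            read_trial_log(path)

    def test_log_without_truth_reads_as_real_data(self, trial_log, tmp_path):
        path = write_trial_log(trial_log, tmp_path / "trial")
        import json

        header = json.loads((path / "header.json").read_text())
        header["truth"] = None
        (path / "header.json").write_text(json.dumps(header))
        back = read_trial_log(path)
        assert back.truth is None and not back.has_truth

    def test_schema_version_mismatch_rejected(self, trial_log, tmp_path):
        path = write_trial_log(trial_log, tmp_path / "trial")
        import json

        header = json.loads((path / "header.json").read_text())
        header["schema_version"] = 99
        (path / "header.json").write_text(json.dumps(header))
        with pytest.raises(TrialLogParseError, match="schema version"):
            read_trial_log(path)


class TestTrialDeterminism:
    def test_same_seed_same_frames(self, layout, condition):
        a = simulate_trial(layout, condition, seed=9)
        b = simulate_trial(layout, condition, seed=9)
        pd.testing.assert_frame_equal(a.frames, b.frames)

    def test_truth_labels_cover_all_conditions(self, layout):
        for cond in enumerate_conditions(2)[:2]:
            log = simulate_trial(layout, cond, seed=1, with_gaze=False)
            assert log.truth["path_class"] in ("direct", "hooked")
            assert set(log.truth["crossing_times"]) == {"1", "2"}
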