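"""Attention metrics: allocation, GTE, K, gaps, paths, alignment, LHIPA."""

import math

import numpy as np
import pandas as pd
import pytest

from swgaze.metrics import (
    ATTENTION_LABELS,
    default_attention_map,
    distance_from_midline,
    gap_crossing,
    gaze_allocation,
    gaze_density_grid,
    gaze_movement_alignment,
    gte,
    k_coefficient,
    label_attention,
    lhipa,
    speed_profile,
)
from swgaze.simulate import PupilParams, simulate_pupil, simulate_walkers
from swgaze.trials import TrialPhase


class TestAttentionLabels:
    def test_row2_walker_is_global_before_first_row(self):
        assert label_attention("walker_row2", "approaching_first_row") == "global"

    def test_gate_indicator_is_task_related_in_preparation(self):
        assert label_attention("gate_indicator", "initial_preparation") == "task_related"

    def test_unattributed_gaze_is_miscellaneous(self):
        for phase in (
            "initial_preparation",
            "approaching_first_row",
            "approaching_second_row",
            "approaching_gate",
        ):
            assert label_attention("none", phase) == "miscellaneous"
            assert label_attention(None, phase) == "miscellaneous"

    def test_timer_resolves_to_task_related_everywhere(self):
        amap = default_attention_map()
        for phase in (
            "initial_preparation",
            "approaching_first_row",
            "approaching_second_row",
            "approaching_gate",
        ):
            assert amap.label(phase, "timer") == "task_related"

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            label_attention("timer", "warmup")


class TestGazeAllocation:
    def test_single_target_phase_has_unit_proportion(self):
        t = np.arange(160) / 80.0
        labels = np.array(["task_related"] * 160, dtype=object)
        phases = [TrialPhase("initial_preparation", 0.0, 2.0)]
        table = gaze_allocation(t, labels, phases)
        assert table["task_related"].iloc[0] == 1.0

    def test_proportions_sum_to_one_per_segment(self):
        rng = np.random.default_rng(0)
        t = np.arange(800) / 80.0
        labels = rng.choice(ATTENTION_LABELS, size=800).astype(object)
        phases = [
            TrialPhase("initial_preparation", 0.0, 2.0),
            TrialPhase("approaching_first_row", 2.0, 5.0),
            TrialPhase("approaching_second_row", 5.0, 10.0),
        ]
        table = gaze_allocation(t, labels, phases)
        sums = table[list(ATTENTION_LABELS)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_known_split_recovered_within_multinomial_error(self):
        rng = np.random.default_rng(1)
        n = 20_000
        t = np.arange(n) / 80.0
        probs = dict(zip(ATTENTION_LABELS, (0.4, 0.3, 0.2, 0.1)))
        labels = rng.choice(list(probs), size=n, p=list(probs.values())).astype(object)
        table = gaze_allocation(t, labels, [TrialPhase("approaching_second_row", 0.0, n / 80.0)])
        for lbl, p in probs.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(table[lbl].iloc[0] - p) < 4 * se

    def test_empty_segment_omitted(self):
        t = np.arange(80) / 80.0
        labels = np.array(["local"] * 80, dtype=object)
        phases = [
            TrialPhase("initial_preparation", 0.0, 1.0),
            TrialPhase("approaching_gate", 5.0, 6.0),  # no frames
        ]
        table = gaze_allocation(t, labels, phases)
        assert table["segment"].tolist() == ["initial_preparation"]


class TestGte:
    def test_single_state_window_is_missing(self):
        res = gte(np.zeros(200, dtype=int), window=80)
        assert np.all(np.isnan(res.values))

    def test_deterministic_alternation_has_zero_entropy(self):
        states = np.tile([0, 1], 200)
        res = gte(states, window=80)
        assert np.allclose(res.values, 0.0, atol=1e-12)

    def test_uniform_two_state_chain_approaches_one(self):
        # Hand check: for an i.i.d. uniform 2-state chain the empirical
        # transition matrix approaches [[.5,.5],[.5,.5]], whose conditional
        # entropy is exactly 1 bit = the normalizing constant.
        rng = np.random.default_rng(2)
        states = rng.integers(0, 2, size=4000)
        res = gte(states, window=2000)
        assert np.nanmean(res.values) == pytest.approx(1.0, abs=0.01)

    def test_hand_computed_empirical_window(self):
        # Window 0,0,1,1,0: transitions 0->0, 0->1, 1->1, 1->0.
        # p(0)=1/2, p(1)=1/2 (by source counts); each row is (1/2, 1/2),
        # so H(next|cur) = 1 bit and GTE = 1 after normalizing by log2(2).
        states = np.array([0, 0, 1, 1, 0])
        res = gte(states, window=5)
        assert res.values[0] == pytest.approx(1.0)

    def test_values_stay_in_unit_interval(self):
        rng = np.random.default_rng(3)
        states = rng.integers(0, 216, size=1500)
        res = gte(states, window=80)
        vals = res.values[~np.isnan(res.values)]
        assert np.all((vals >= 0) & (vals <= 1.0 + 1e-12))

    def test_missing_samples_skipped(self):
        states = np.tile([0, 1], 100)
        states[::7] = -1
        res = gte(states, window=80)
        assert np.all(np.isfinite(res.values))

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            gte(np.zeros(10, dtype=int), window=1)


class TestKCoefficient:
    def test_two_event_hand_example_sign(self):
        # Long fixation with a small saccade -> focal (K > 0); the short
        # fixation with the large saccade is its mirror image (K < 0).
        pairs = [(0.3, 2.0, 0.1), (0.1, 10.0, 0.5)]
        res = k_coefficient(pairs)
        d = np.array([0.3, 0.1])
        a = np.array([2.0, 10.0])
        expected = (d - d.mean()) / d.std() - (a - a.mean()) / a.std()
        assert np.allclose(res.k_values, expected)
        assert res.k_values[0] > 0 and res.k_values[1] < 0

    def test_grand_mean_is_zero(self):
        rng = np.random.default_rng(4)
        pairs = [
            (float(rng.lognormal(-1.2, 0.5)), float(rng.lognormal(1.5, 0.7)), float(i))
            for i in range(50)
        ]
        res = k_coefficient(pairs)
        assert res.k_values.mean() == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        pairs = [
            (float(rng.uniform(0.1, 0.5)), float(rng.uniform(1, 15)), float(i))
            for i in range(30)
        ]
        scaled = [(1000.0 * d, a, m) for d, a, m in pairs]  # durations in ms
        assert np.allclose(
            k_coefficient(pairs).k_values, k_coefficient(scaled).k_values
        )

    def test_zero_variance_flags_degenerate(self):
        res = k_coefficient([(0.3, 5.0, 0.0), (0.3, 5.0, 1.0)])
        assert res.degenerate and len(res.k_values) == 0

    def test_single_pair_degenerate(self):
        assert k_coefficient([(0.3, 5.0, 0.0)]).degenerate

    def test_phase_means_split_by_fixation_midpoint(self):
        pairs = [(0.3, 2.0, 0.5), (0.1, 9.0, 2.5), (0.2, 5.0, 2.8)]
        res = k_coefficient(pairs)
        phases = [
            TrialPhase("initial_preparation", 0.0, 2.0),
            TrialPhase("approaching_first_row", 2.0, 4.0),
        ]
        table = res.phase_means(phases)
        assert table["n_events"].tolist() == [1, 2]


class TestGapCrossing:
    def test_mid_gap_crossing_is_symmetric(self, layout, condition):
        tracks = simulate_walkers(layout, condition, duration=4.0)
        # Build a trajectory crossing row 1 exactly midway between two
        # walkers at a chosen instant.
        t = np.arange(320) / 80.0
        t_cross = 2.0
        row1 = [tr for tr in tracks if tr.row == 1]
        xs = np.sort([tr.x_at(t_cross) for tr in row1])
        inside = xs[(xs > -2.0) & (xs < 2.0)]
        x_mid = (inside[0] + xs[np.searchsorted(xs, inside[0]) + 1]) / 2.0
        z = np.where(t < t_cross, 1.0, 1.5)
        xz = np.column_stack([np.full_like(t, x_mid), z])
        got = gap_crossing(t, xz, tracks, layout)[1]
        assert got.d_rear == pytest.approx(1.25, abs=1e-9)
        assert got.d_front == pytest.approx(1.25, abs=1e-9)
        assert got.gap_fraction == pytest.approx(0.5, abs=1e-9)

    def test_row_never_crossed_is_missing(self, layout, condition):
        tracks = simulate_walkers(layout, condition, duration=2.0)
        t = np.arange(160) / 80.0
        xz = np.column_stack([np.zeros_like(t), np.full_like(t, 1.0)])
        out = gap_crossing(t, xz, tracks, layout)
        assert out[1] is None and out[2] is None


class TestPathAndSpeed:
    def test_constant_offset_distance_from_midline(self):
        z = np.linspace(0, 6, 400)
        xz = np.column_stack([np.full_like(z, 0.8), z])
        assert distance_from_midline(xz) == pytest.approx(0.8)

    def test_left_right_symmetry(self):
        z = np.linspace(0, 6, 400)
        left = np.column_stack([np.full_like(z, -0.7), z])
        right = np.column_stack([np.full_like(z, 0.7), z])
        assert distance_from_midline(left) == distance_from_midline(right)

    def test_piecewise_path_hand_average(self):
        # Half the in-zone frames at 0.6 m, half at 1.0 m -> mean 0.8 m.
        z = np.concatenate([np.linspace(2.0, 3.049, 100), np.linspace(3.05, 4.1, 100)])
        x = np.concatenate([np.full(100, 0.6), np.full(100, 1.0)])
        assert distance_from_midline(np.column_stack([x, z])) == pytest.approx(0.8)

    def test_flat_profile_for_constant_velocity(self):
        t = np.arange(400) / 80.0
        xz = np.column_stack([np.zeros_like(t), 1.2 * t])
        prof = speed_profile(t, xz)
        filled = prof.dropna(subset=["mean_speed"])
        assert np.allclose(filled["mean_speed"], 1.2, atol=1e-6)

    def test_empty_bins_are_missing_not_zero(self):
        t = np.arange(100) / 80.0
        xz = np.column_stack([np.zeros_like(t), np.full_like(t, 0.5)])
        prof = speed_profile(t, xz)
        beyond = prof[prof["z_lo"] >= 1.0]
        assert beyond["mean_speed"].isna().all()

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            speed_profile(np.array([0.0]), np.array([[0.0, 0.0]]))


class TestAlignment:
    @staticmethod
    def _moving_frames(n=200):
        t = np.arange(n) / 80.0
        xz = np.column_stack([np.zeros(n), 1.3 * t])  # heading +z
        return t, xz

    def test_gaze_along_heading_is_zero(self):
        t, xz = self._moving_frames()
        g = np.tile([0.0, 0.0, 1.0], (len(t), 1))
        table = gaze_movement_alignment(t, xz, g)
        assert np.allclose(table["alignment_deg"][5:-5], 0.0, atol=1e-6)

    def test_backward_look_is_180(self):
        t, xz = self._moving_frames()
        g = np.tile([0.0, 0.0, -1.0], (len(t), 1))
        table = gaze_movement_alignment(t, xz, g)
        assert np.allclose(np.abs(table["alignment_deg"][5:-5]), 180.0, atol=1e-6)

    def test_rightward_gaze_is_plus_90(self):
        t, xz = self._moving_frames()
        g = np.tile([1.0, 0.0, 0.0], (len(t), 1))
        table = gaze_movement_alignment(t, xz, g)
        assert np.allclose(table["alignment_deg"][5:-5], 90.0, atol=1e-6)

    def test_slow_frames_flagged_stationary_but_reported(self):
        n = 100
        t = np.arange(n) / 80.0
        xz = np.zeros((n, 2))
        g = np.tile([0.0, 0.0, 1.0], (n, 1))
        table = gaze_movement_alignment(t, xz, g)
        assert table["stationary"].all()
        assert len(table) == n


class TestLhipa:
    FS = 80.0

    def test_constant_series_flagged_degenerate(self):
        res = lhipa(np.full(2400, 4.0), self.FS)
        assert res.degenerate

    def test_monotone_decreasing_in_high_frequency_power(self):
        t = np.arange(int(60 * self.FS)) / self.FS
        values = []
        for load in (0.5, 1.5, 2.5):
            pupil = simulate_pupil(
                t, load, seed=6, params=PupilParams(noise_sd_mm=0.02)
            )
            values.append(lhipa(pupil, self.FS).value)
        assert values[0] > values[1] > values[2]

    def test_seeded_stream_gives_identical_index(self):
        t = np.arange(int(30 * self.FS)) / self.FS
        pupil = simulate_pupil(t, 1.0, seed=7)
        assert lhipa(pupil, self.FS).value == lhipa(pupil.copy(), self.FS).value

    def test_short_gaps_interpolated_long_gaps_rejected(self):
        t = np.arange(int(30 * self.FS)) / self.FS
        pupil = simulate_pupil(t, 1.0, seed=8)
        ok = pupil.copy()
        ok[100:110] = np.nan  # 0.125 s gap
        assert np.isfinite(lhipa(ok, self.FS).value)
        bad = pupil.copy()
        bad[100:150] = np.nan  # 0.625 s gap
        with pytest.raises(ValueError, match="gap"):
            lhipa(bad, self.FS)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            lhipa(np.random.default_rng(0).normal(4, 0.1, 100), self.FS)


class TestDensityGrid:
    def test_normalized_to_unit_mass(self, layout):
        rng = np.random.default_rng(9)
        pts = rng.uniform([-2, 0], [2, 6], size=(500, 2))
        density, _, _ = gaze_density_grid(pts, layout)
        assert density.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_point_gives_kernel_bump_at_location(self, layout):
        density, xe, ze = gaze_density_grid(np.array([[1.0, 3.0]]), layout)
        ix, iz = np.unravel_index(np.argmax(density), density.shape)
        assert xe[ix] <= 1.0 <= xe[ix + 1]
        assert ze[iz] <= 3.0 <= ze[iz + 1]

    def test_two_equal_clusters_share_mass(self, layout):
        rng = np.random.default_rng(10)
        a = rng.normal([-1.5, 2.0], 0.05, size=(400, 2))
        b = rng.normal([1.5, 4.0], 0.05, size=(400, 2))
        density, xe, ze = gaze_density_grid(np.vstack([a, b]), layout)
        left = density[: len(xe) // 2].sum()
        right = density[len(xe) // 2 :].sum()
        assert left == pytest.approx(right, rel=0.05)

    def test_nonpositive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            gaze_density_grid(np.zeros((1, 2)), bin_size=0.0)
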