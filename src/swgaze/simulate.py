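"""Synthetic study data: walkers, participant locomotion, gaze, and pupil.

The study's raw frame streams are not publicly deposited, so this module
simulates them with ground truth attached.  The generator reproduces the
study conditions: two walker rows at z = 1.4 m and 4.7 m moving at 1.3 m/s
with 2.5 m spacing, a gate cue revealed 2 s into each trial, a 5 x 6 m room,
and participant paths that are direct, show a velocity dip between the rows,
or hook toward the wrong gate before switching sides.  Gaze is composed of
fixations, saccades, post-saccadic oscillations and smooth pursuit directed
at phase-appropriate targets, emitted as binocular rays converging on the
gazed point; pupil diameter carries a load-scaled high-frequency component
for pupillometric analysis.

Everything is driven by a fixed 80 Hz frame clock and a single integer seed
per trial, so streams are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .scene import (
    WALKER_COLLIDER,
    ObjectSpec,
    SceneLayout,
    TrialCondition,
    gate_x,
)
from .trials import frame_phase_indices, PHASE_LABELS

__all__ = [
    "FRAME_RATE_HZ",
    "CUE_TIME_S",
    "EYE_HEIGHT_M",
    "IPD_M",
    "WalkerTrack",
    "ParticipantPolicy",
    "ParticipantResult",
    "GazeEventParams",
    "PupilParams",
    "TrialLog",
    "simulate_walkers",
    "simulate_participant",
    "simulate_gaze",
    "simulate_pupil",
    "simulate_trial",
    "default_gaze_schedule",
]

FRAME_RATE_HZ = 80.0
CUE_TIME_S = 2.0
EYE_HEIGHT_M = 1.6
IPD_M = 0.063

WALKER_SPEED_MPS = 1.3
WALKER_SPACING_M = 2.5


# ---------------------------------------------------------------------------
# Walkers
# ---------------------------------------------------------------------------


@dataclass
class WalkerTrack:
    """One walker: constant-z, constant-speed motion along x."""

    agent_id: str
    row: int
    direction: str  # "left_to_right" | "right_to_left"
    t: np.ndarray
    x: np.ndarray
    z: float
    speed_mps: float

    @property
    def facing_sign(self) -> float:
        return 1.0 if self.direction == "left_to_right" else -1.0

    def x_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.x))

    def object_at(self, t: float) -> ObjectSpec:
        kind = "walker_row1" if self.row == 1 else "walker_row2"
        return ObjectSpec(
            id=self.agent_id,
            kind=kind,
            position=(self.x_at(t), 0.9, self.z),
            collider=WALKER_COLLIDER,
            facing=(self.facing_sign, 0.0),
        )


def _row_direction(condition: TrialCondition, row: int) -> str:
    # "row1_from_left" means row 1 enters from the left door, i.e. walks +x.
    row1_ltr = condition.row_directions == "row1_from_left"
    ltr = row1_ltr if row == 1 else not row1_ltr
    return "left_to_right" if ltr else "right_to_left"


def simulate_walkers(
    layout: SceneLayout,
    condition: TrialCondition,
    duration: float,
    spacing_m: float = WALKER_SPACING_M,
    speed_mps: float = WALKER_SPEED_MPS,
    fs: float = FRAME_RATE_HZ,
    phase_offsets: dict[int, float] | None = None,
) -> list[WalkerTrack]:
    """Simulate both walker rows for a trial.

    Each row is a single file of agents at fixed z, equally spaced along x
    and all moving at the same constant speed, entering and exiting through
    the side doors.  Enough agents are spawned upstream that the room stays
    populated for the whole trial; every agent moves strictly linearly, so
    logged kinematics are exact.  ``phase_offsets`` shifts a row's file
    along x (mod spacing); the trial generator uses it to realize the
    configured gap-crossing geometry.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if spacing_m <= 0 or speed_mps <= 0:
        raise ValueError("spacing and speed must be positive")
    phase_offsets = phase_offsets or {}
    n_frames = int(round(duration * fs)) + 1
    t = np.arange(n_frames) / fs
    margin = 1.5 * spacing_m
    half_span = layout.half_width + margin
    tracks: list[WalkerTrack] = []
    for row, row_z in ((1, layout.row1_z), (2, layout.row2_z)):
        direction = _row_direction(condition, row)
        sign = 1.0 if direction == "left_to_right" else -1.0
        offset = float(phase_offsets.get(row, 0.0)) % spacing_m
        # Cover [-half_span, half_span] at every t in [0, duration]: the file
        # extends upstream by the distance travelled during the trial.
        travel = speed_mps * duration
        x_first = -half_span - (travel if sign > 0 else 0.0)
        x_last = half_span + (travel if sign < 0 else 0.0)
        # Snap the file start to a multiple of the spacing so a row's
        # positions are congruent to offset + sign*speed*t (mod spacing).
        x_first = math.floor(x_first / spacing_m) * spacing_m
        n_agents = int(math.ceil((x_last - x_first) / spacing_m)) + 1
        for k in range(n_agents):
            x0 = x_first + offset + k * spacing_m
            tracks.append(
                WalkerTrack(
                    agent_id=f"walker_r{row}_{k:02d}",
                    row=row,
                    direction=direction,
                    t=t,
                    x=x0 + sign * speed_mps * t,
                    z=row_z,
                    speed_mps=speed_mps,
                )
            )
    return tracks


def walker_states_at(tracks: list[WalkerTrack], t: float) -> list[ObjectSpec]:
    return [tr.object_at(t) for tr in tracks]


# ---------------------------------------------------------------------------
# Participant locomotion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantPolicy:
    """Parametric locomotion policy.

    ``dip_depth`` is the fractional speed reduction at ``dip_center_z``
    (the strategic slow-down between the rows); ``hook_probability`` is the
    chance of a hooked path; ``gap_offset_bias`` shifts the row-crossing
    point within the inter-walker gap (0 = mid-gap, negative = toward the
    rear-facing, just-passed agent); ``reaction_delay_s`` is the pause after
    the gate cue before locomotion starts.
    """

    base_speed_mps: float = 1.3
    dip_depth: float = 0.4
    dip_center_z: float = 3.05
    dip_width_z: float = 0.8
    hook_probability: float = 0.06
    gap_offset_bias: float = 0.0
    gap_offset_sd: float = 0.08
    reaction_delay_s: float = 0.3
    lateral_offset_m: float = 1.25
    lateral_jitter_m: float = 0.08
    clearance_m: float = 0.3

    def __post_init__(self) -> None:
        if self.base_speed_mps <= 0:
            raise ValueError("base_speed_mps must be positive")
        for name in ("dip_depth", "hook_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ParticipantResult:
    t: np.ndarray
    head_pos: np.ndarray  # (n, 3)
    path_class: str  # "direct" | "hooked"
    crossing_times: dict[int, float]
    gap_fractions: dict[int, float]
    failed: bool = False
    failure_reason: str = ""


def _speed_law(policy: ParticipantPolicy):
    def v(z: float | np.ndarray) -> float | np.ndarray:
        dip = policy.dip_depth * np.exp(
            -((z - policy.dip_center_z) ** 2) / (2.0 * policy.dip_width_z**2)
        )
        return policy.base_speed_mps * (1.0 - dip)

    return v


def _lateral_path(
    policy: ParticipantPolicy,
    layout: SceneLayout,
    condition: TrialCondition,
    hooked: bool,
    rng: np.random.Generator,
):
    """x as a monotone-z PCHIP spline from start to the target gate."""
    s = -1.0 if condition.gate_side == "left" else 1.0
    gx = gate_x(layout, condition.gate_side)
    off = policy.lateral_offset_m + rng.normal(0.0, policy.lateral_jitter_m)
    off = float(np.clip(off, 1.15, layout.half_width - 0.6))
    L = layout.room_length_z
    if not hooked:
        zs = [0.0, 1.0, 2.2, 3.9, layout.row2_z, L]
        xs = [0.0, 0.2 * s * off, s * off, s * off, 0.8 * s * off + 0.2 * gx, gx]
    else:
        # Toward the wrong gate through the bench zone, switching sides late.
        zs = [0.0, 1.0, 2.6, 4.1, 4.9, L]
        xs = [0.0, -0.2 * s * off, -s * off, -0.5 * s * off, 0.35 * s * off, gx]
    return PchipInterpolator(np.asarray(zs), np.asarray(xs))


def simulate_participant(
    policy: ParticipantPolicy,
    layout: SceneLayout,
    condition: TrialCondition,
    seed: int,
    fs: float = FRAME_RATE_HZ,
    cue_time: float = CUE_TIME_S,
    max_duration: float = 20.0,
) -> ParticipantResult:
    """Generate one head-position trajectory with ground-truth path class.

    The participant waits at the start until the gate cue plus a reaction
    delay, then follows a lateral spline x(z) around the bench block toward
    the target gate, moving at path speed v(z) = base * (1 - dip), where the
    dip is a Gaussian bump of depth ``dip_depth`` centred at
    ``dip_center_z``.  If the configured clearance is geometrically
    infeasible within the walker gap, the trial is returned flagged as
    failed rather than raising.
    """
    rng = np.random.default_rng(seed)
    hooked = bool(rng.random() < policy.hook_probability)
    x_of_z = _lateral_path(policy, layout, condition, hooked, rng)
    dx_dz = x_of_z.derivative()
    v_of_z = _speed_law(policy)

    if policy.clearance_m >= WALKER_SPACING_M / 2.0:
        # No crossing point in the gap can satisfy the clearance.
        n = int(round(max_duration * fs)) + 1
        t = np.arange(n) / fs
        head = np.tile([0.0, EYE_HEIGHT_M, 0.0], (n, 1))
        return ParticipantResult(
            t, head, "direct", {}, {}, failed=True,
            failure_reason="clearance exceeds half the walker spacing",
        )

    t_go = cue_time + policy.reaction_delay_s
    # Integrate dz/dt = v(z) / sqrt(1 + x'(z)^2) on a fine clock, then sample
    # at frame times.
    dt = 1.0 / (fs * 10.0)
    z_vals = [0.0]
    t_vals = [t_go]
    z = 1e-6
    tt = t_go
    L = layout.room_length_z
    while z < L and tt < max_duration:
        slope = float(dx_dz(min(z, L)))
        dz = float(v_of_z(z)) / math.sqrt(1.0 + slope * slope) * dt
        z = min(z + dz, L)
        tt += dt
        z_vals.append(z)
        t_vals.append(tt)
    t_end = t_vals[-1]
    n_frames = int(math.ceil(t_end * fs)) + 1
    t = np.arange(n_frames) / fs
    z_frames = np.interp(t, [0.0] + t_vals, [0.0] + z_vals)
    x_frames = np.asarray(x_of_z(z_frames), dtype=float)
    head = np.column_stack(
        [x_frames, np.full_like(x_frames, EYE_HEIGHT_M), z_frames]
    )
    crossing_times: dict[int, float] = {}
    for row, row_z in ((1, layout.row1_z), (2, layout.row2_z)):
        idx = np.argmax(z_frames >= row_z)
        if z_frames[idx] >= row_z:
            crossing_times[row] = float(t[idx])
    # Target position within the inter-walker gap at each crossing.
    f_lo = policy.clearance_m / WALKER_SPACING_M
    gap_fractions = {
        row: float(
            np.clip(
                0.5 + policy.gap_offset_bias + rng.normal(0.0, policy.gap_offset_sd),
                f_lo,
                1.0 - f_lo,
            )
        )
        for row in crossing_times
    }
    return ParticipantResult(
        t=t,
        head_pos=head,
        path_class="hooked" if hooked else "direct",
        crossing_times=crossing_times,
        gap_fractions=gap_fractions,
    )


def align_walker_offsets(
    participant: ParticipantResult,
    layout: SceneLayout,
    condition: TrialCondition,
    spacing_m: float = WALKER_SPACING_M,
    speed_mps: float = WALKER_SPEED_MPS,
) -> dict[int, float]:
    """Row phase offsets realizing the participant's target gap fractions.

    The generator chooses where each walker file sits (mod spacing) so that
    at the moment the participant crosses a row line, the rear-facing agent
    (the one that just passed, walking away) is ``fraction x spacing``
    downstream and the front-facing agent ``(1 - fraction) x spacing``
    upstream.
    """
    offsets: dict[int, float] = {}
    for row, t_cross in participant.crossing_times.items():
        f = participant.gap_fractions[row]
        direction = _row_direction(condition, row)
        sign = 1.0 if direction == "left_to_right" else -1.0
        i = int(np.argmin(np.abs(participant.t - t_cross)))
        x_p = float(participant.head_pos[i, 0])
        # Want some agent at x_p + sign * f * spacing at t_cross.  Agents sit
        # at x_first + offset + k*spacing + sign*speed*t; x_first is a
        # multiple-independent shift, so solve mod spacing.
        offsets[row] = (x_p + sign * f * spacing_m - sign * speed_mps * t_cross) % spacing_m
    return offsets


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GazeEventParams:
    """Eye-movement generative parameters.

    Fixation durations are lognormal; saccade duration follows the
    main-sequence linear law (intercept + slope * amplitude); PSOs are
    damped oscillations appended to saccade offset; angular noise is an
    AR(1) wobble around the target direction, mimicking tracker jitter plus
    fixational drift.
    """

    fixation_mean_s: float = 0.30
    fixation_sd_s: float = 0.15
    pursuit_mean_s: float = 0.45
    pursuit_sd_s: float = 0.15
    pursuit_gain: float = 0.98
    saccade_duration_intercept_s: float = 0.021
    saccade_duration_slope_s_per_deg: float = 0.0022
    pso_probability: float = 0.7
    pso_amplitude_deg: float = 1.0
    pso_frequency_hz: float = 18.0
    pso_decay_s: float = 0.022
    pso_duration_s: float = 0.05
    noise_deg: float = 0.5
    noise_ar1: float = 0.995  # drift-dominated: 0.5 deg positional accuracy
    #                           with ~0.05 deg/frame sample-to-sample
    #                           precision, matching consumer HMD trackers
    ipd_m: float = IPD_M


# Default phase -> target-pool schedule.  Entries are (target, weight) where
# target is an object id, "walker_row1"/"walker_row2" (nearest visible walker
# of that row, pursued), or "misc" (a random point on the walls/ceiling).
def default_gaze_schedule(condition: TrialCondition) -> dict[str, list[tuple[str, float]]]:
    target_gate, foil_gate = (
        ("gate_left", "gate_right")
        if condition.gate_side == "left"
        else ("gate_right", "gate_left")
    )
    return {
        "initial_preparation": [
            ("gate_indicator", 0.65),
            ("timer", 0.15),
            ("walker_row1", 0.10),
            ("misc", 0.10),
        ],
        "approaching_first_row": [
            ("walker_row1", 0.45),
            ("gate_indicator", 0.15),
            ("walker_row2", 0.15),
            ("timer", 0.05),
            ("misc", 0.20),
        ],
        "approaching_second_row": [
            ("walker_row2", 0.45),
            ("walker_row1", 0.10),
            (target_gate, 0.10),
            (foil_gate, 0.05),
            ("timer", 0.05),
            ("misc", 0.25),
        ],
        "approaching_gate": [
            (target_gate, 0.65),
            ("timer", 0.20),
            ("misc", 0.15),
        ],
    }


def _rotate_toward(d: np.ndarray, target: np.ndarray, frac: float) -> np.ndarray:
    """Spherical interpolation between unit vectors by fraction ``frac``."""
    cosang = float(np.clip(d @ target, -1.0, 1.0))
    ang = math.acos(cosang)
    if ang < 1e-9:
        return target
    axis = np.cross(d, target)
    axis /= np.linalg.norm(axis)
    return _rodrigues(d, axis, frac * ang)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * (axis @ v) * (1.0 - math.cos(angle))
    )


def _perp_axis(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=3)
    a -= (a @ d) * d
    n = np.linalg.norm(a)
    return a / n if n > 0 else np.array([0.0, 1.0, 0.0])


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


class _TargetPoint:
    """Resolves a schedule entry to a (possibly moving) 3D point."""

    def __init__(
        self,
        name: str,
        layout: SceneLayout,
        tracks: list[WalkerTrack],
        head_x: float,
        t_now: float,
        rng: np.random.Generator,
    ):
        self.moving: WalkerTrack | None = None
        if name in ("walker_row1", "walker_row2"):
            row = 1 if name.endswith("1") else 2
            hw = layout.half_width
            candidates = [
                tr for tr in tracks if tr.row == row and abs(tr.x_at(t_now)) < hw
            ]
            if not candidates:
                candidates = [tr for tr in tracks if tr.row == row]
            tr = min(candidates, key=lambda tr: abs(tr.x_at(t_now) - head_x))
            self.moving = tr
            self.id = tr.agent_id
            self._y = 1.5 + rng.normal(0.0, 0.1)
        elif name == "misc":
            self.id = "none"
            hw = layout.half_width
            self._fixed = np.array(
                [
                    rng.uniform(-hw, hw),
                    rng.uniform(2.2, 2.5),
                    rng.uniform(0.5, layout.room_length_z),
                ]
            )
        else:
            obj = layout.object_by_id(name)
            self.id = name
            c = np.asarray(obj.position, dtype=float)
            jitter = rng.normal(0.0, 0.03, size=3)
            self._fixed = c + jitter

    def at(self, t: float) -> np.ndarray:
        if self.moving is not None:
            return np.array([self.moving.x_at(t), self._y, self.moving.z])
        return self._fixed


def simulate_gaze(
    t: np.ndarray,
    head_pos: np.ndarray,
    layout: SceneLayout,
    tracks: list[WalkerTrack],
    condition: TrialCondition,
    seed: int,
    schedule: dict[str, list[tuple[str, float]]] | None = None,
    params: GazeEventParams = GazeEventParams(),
    cue_time: float = CUE_TIME_S,
) -> dict[str, np.ndarray]:
    """Generate binocular gaze rays with per-frame ground-truth labels.

    Events alternate: a saccade toward a newly scheduled target (minimum-
    jerk angular profile, main-sequence duration), optionally a damped
    post-saccadic oscillation, then a fixation (static target) or smooth
    pursuit (walker target, gain ``pursuit_gain``).  Both eye rays originate
    half an inter-pupillary distance left/right of the head and converge on
    the current gaze point; AR(1) angular noise is applied per eye.

    Returns arrays: eyeL/R origins and directions, truth event label per
    frame, truth target id per frame.
    """
    schedule = schedule or default_gaze_schedule(condition)
    for phase in PHASE_LABELS:
        if phase not in schedule or not schedule[phase]:
            raise ValueError(f"gaze schedule has an empty target pool for {phase!r}")
    rng = np.random.default_rng(seed)
    n = len(t)
    fs = 1.0 / float(np.median(np.diff(t)))
    phase_idx = frame_phase_indices(t, head_pos[:, 2], layout, cue_time)

    gaze_dir = np.zeros((n, 3))
    gaze_dist = np.zeros(n)
    labels = np.empty(n, dtype=object)
    target_ids = np.empty(n, dtype=object)

    cyc_origin = head_pos.copy()

    def aim(i: int, point: np.ndarray) -> tuple[np.ndarray, float]:
        vec = point - cyc_origin[i]
        dist = float(np.linalg.norm(vec))
        return vec / dist, dist

    # Initial target.
    phase = PHASE_LABELS[phase_idx[0]]
    names, weights = zip(*schedule[phase])
    w = np.asarray(weights, float)
    target = _TargetPoint(
        str(rng.choice(names, p=w / w.sum())), layout, tracks, head_pos[0, 0], t[0], rng
    )
    d0, _ = aim(0, target.at(t[0]))
    i = 0
    while i < n:
        is_pursuit = target.moving is not None
        if is_pursuit:
            dur = max(0.08, rng.lognormal(
                _ln_mu(params.pursuit_mean_s, params.pursuit_sd_s),
                _ln_sigma(params.pursuit_mean_s, params.pursuit_sd_s),
            ))
        else:
            dur = max(0.06, rng.lognormal(
                _ln_mu(params.fixation_mean_s, params.fixation_sd_s),
                _ln_sigma(params.fixation_mean_s, params.fixation_sd_s),
            ))
        n_ev = max(2, int(round(dur * fs)))
        end = min(n, i + n_ev)
        # Truncate at phase boundaries: the next event retargets from the
        # new phase's pool, keeping gaze phase-appropriate.
        crossed = np.nonzero(phase_idx[i:end] != phase_idx[i])[0]
        if len(crossed):
            end = i + max(int(crossed[0]), 1)
        anchor = target.at(t[i])
        for j in range(i, end):
            if is_pursuit and params.pursuit_gain != 1.0:
                raw = target.at(t[j])
                point = anchor + params.pursuit_gain * (raw - anchor)
            else:
                point = target.at(t[j])
            gaze_dir[j], gaze_dist[j] = aim(j, point)
            labels[j] = "pursuit" if is_pursuit else "fixation"
            target_ids[j] = target.id
        i = end
        if i >= n:
            break
        # Pick the next target and saccade to it.
        phase = PHASE_LABELS[phase_idx[i]]
        names, weights = zip(*schedule[phase])
        w = np.asarray(weights, float)
        target = _TargetPoint(
            str(rng.choice(names, p=w / w.sum())), layout, tracks, head_pos[i, 0], t[i], rng
        )
        d_from = gaze_dir[i - 1]
        d_to, dist_to = aim(i, target.at(t[i]))
        amp = math.degrees(math.acos(float(np.clip(d_from @ d_to, -1, 1))))
        sac_dur = (
            params.saccade_duration_intercept_s
            + params.saccade_duration_slope_s_per_deg * amp
        )
        n_sac = max(2, int(round(sac_dur * fs)))
        end = min(n, i + n_sac)
        for j in range(i, end):
            u = (j - i + 1) / n_sac
            gaze_dir[j] = _rotate_toward(d_from, d_to, float(_minimum_jerk(np.array([u]))[0]))
            gaze_dist[j] = dist_to
            labels[j] = "saccade"
            target_ids[j] = target.id
        i = end
        if i >= n:
            break
        if amp > 2.0 and rng.random() < params.pso_probability:
            n_pso = max(2, int(round(params.pso_duration_s * fs)))
            end = min(n, i + n_pso)
            axis = _perp_axis(d_to, rng)
            for j in range(i, end):
                tau = (j - i + 1) / fs
                ang = math.radians(
                    params.pso_amplitude_deg
                    * math.exp(-tau / params.pso_decay_s)
                    * math.sin(2 * math.pi * params.pso_frequency_hz * tau)
                )
                d_base, gaze_dist[j] = aim(j, target.at(t[j]))
                gaze_dir[j] = _rodrigues(d_base, axis, ang)
                labels[j] = "pso"
                target_ids[j] = target.id
            i = end

    # Binocular rays: eyes offset laterally, both converging on the gaze
    # point; independent AR(1) angular noise per eye.
    half_ipd = params.ipd_m / 2.0
    eyeL_o = head_pos + np.array([-half_ipd, 0.0, 0.0])
    eyeR_o = head_pos + np.array([half_ipd, 0.0, 0.0])
    gaze_point = cyc_origin + gaze_dir * gaze_dist[:, None]
    eyeL_d = _normalize(gaze_point - eyeL_o)
    eyeR_d = _normalize(gaze_point - eyeR_o)
    if params.noise_deg > 0:
        for dirs in (eyeL_d, eyeR_d):
            _apply_ar1_noise(dirs, params.noise_deg, params.noise_ar1, rng)
    return {
        "eyeL_origin": eyeL_o,
        "eyeL_dir": eyeL_d,
        "eyeR_origin": eyeR_o,
        "eyeR_dir": eyeR_d,
        "event_label": labels,
        "target_id": target_ids,
        "gaze_point": gaze_point,
    }


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _apply_ar1_noise(
    dirs: np.ndarray, sd_deg: float, rho: float, rng: np.random.Generator
) -> None:
    """Rotate each direction by a temporally correlated random angle (in place)."""
    n = len(dirs)
    sd = math.radians(sd_deg)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    e1 = np.zeros(n)
    e2 = np.zeros(n)
    e1[0] = rng.normal(0.0, sd)
    e2[0] = rng.normal(0.0, sd)
    for k in range(1, n):
        e1[k] = rho * e1[k - 1] + rng.normal(0.0, innov_sd)
        e2[k] = rho * e2[k - 1] + rng.normal(0.0, innov_sd)
    up = np.array([0.0, 1.0, 0.0])
    for k in range(n):
        d = dirs[k]
        a1 = np.cross(up, d)
        a1 /= np.linalg.norm(a1)
        a2 = np.cross(d, a1)
        dirs[k] = _rodrigues(_rodrigues(d, a1, e1[k]), a2, e2[k])


def _ln_mu(mean: float, sd: float) -> float:
    return math.log(mean**2 / math.sqrt(mean**2 + sd**2))


def _ln_sigma(mean: float, sd: float) -> float:
    return math.sqrt(math.log(1.0 + sd**2 / mean**2))


# ---------------------------------------------------------------------------
# Pupil
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PupilParams:
    """Pupil-diameter generative parameters (millimetres, Hz)."""

    lf_freq_hz: float = 0.9
    lf_amp_mm: float = 0.15
    hf_freq_hz: float = 3.5
    hf_amp_mm: float = 0.12
    burst_rate_hz_per_load: float = 0.5  # high-frequency bursts per second per unit load
    burst_duration_s: float = 0.35
    noise_sd_mm: float = 0.02


def simulate_pupil(
    t: np.ndarray,
    load: float | np.ndarray,
    baseline_mm: float = 4.0,
    seed: int = 0,
    params: PupilParams = PupilParams(),
) -> np.ndarray:
    """Pupil-diameter series with a load-scaled high-frequency component.

    signal = baseline + low-frequency oscillation + high-frequency burst
    train + white noise.  Bursts are Hann-windowed oscillations emitted at
    a rate proportional to the instantaneous cognitive load (placed
    deterministically via the integrated burst intensity), so the
    high-frequency band power scales linearly with load and the number of
    distinct oscillatory events grows with it.  The series is strictly
    positive.
    """
    if baseline_mm <= 0:
        raise ValueError("baseline_mm must be positive")
    t = np.asarray(t, dtype=float)
    load_arr = np.broadcast_to(np.asarray(load, dtype=float), t.shape).astype(float)
    if np.any(load_arr < 0):
        raise ValueError("cognitive load must be non-negative")
    rng = np.random.default_rng(seed)
    lf = params.lf_amp_mm * np.sin(2 * np.pi * params.lf_freq_hz * t)
    # Burst centres: crossings of the integrated intensity at k + 1/2.
    rate = params.burst_rate_hz_per_load * load_arr
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))])
    n_bursts = int(np.floor(cum[-1] + 0.5))
    hf = np.zeros_like(t)
    half = params.burst_duration_s / 2.0
    for k in range(n_bursts):
        c = float(np.interp(k + 0.5, cum, t))
        w = np.abs(t - c) <= half
        envelope = 0.5 * (1.0 + np.cos(np.pi * (t[w] - c) / half))
        hf[w] += (
            params.hf_amp_mm
            * envelope
            * np.sin(2 * np.pi * params.hf_freq_hz * (t[w] - c))
        )
    noise = rng.normal(0.0, params.noise_sd_mm, size=t.shape) if params.noise_sd_mm > 0 else 0.0
    return np.maximum(baseline_mm + lf + hf + noise, 0.1)


# Per-phase cognitive-load levels used by the trial generator: load rises
# through the navigational phases and relaxes in the final approach.
DEFAULT_LOAD_BY_PHASE = {
    "initial_preparation": 0.8,
    "approaching_first_row": 1.4,
    "approaching_second_row": 1.7,
    "approaching_gate": 0.5,
}


# ---------------------------------------------------------------------------
# Full-trial assembly
# ---------------------------------------------------------------------------


@dataclass
class TrialLog:
    """One trial's complete frame stream with (synthetic-only) ground truth.

    ``frames`` is a DataFrame with columns t, head_x/y/z, eyeL_ox..dz,
    eyeR_ox..dz, pupil_mm, valid and (when truth is present) event_label and
    target_id.
    """

    trial_id: str
    condition: TrialCondition
    layout: SceneLayout
    frames: "pd.DataFrame"  # noqa: F821 - imported in io.py
    walker_tracks: list[WalkerTrack]
    seed: int | None = None
    cue_time: float = CUE_TIME_S
    truth: dict | None = None  # path_class, crossing_times, gap_fractions

    @property
    def has_truth(self) -> bool:
        return self.truth is not None

    def head_xz(self) -> np.ndarray:
        return self.frames[["head_x", "head_z"]].to_numpy()

    def t(self) -> np.ndarray:
        return self.frames["t"].to_numpy()


def simulate_trial(
    layout: SceneLayout,
    condition: TrialCondition,
    seed: int,
    policy: ParticipantPolicy = ParticipantPolicy(),
    gaze_params: GazeEventParams = GazeEventParams(),
    pupil_params: PupilParams = PupilParams(),
    schedule: dict[str, list[tuple[str, float]]] | None = None,
    load_by_phase: dict[str, float] = DEFAULT_LOAD_BY_PHASE,
    fs: float = FRAME_RATE_HZ,
    trial_id: str = "trial",
    with_gaze: bool = True,
) -> TrialLog:
    """Simulate one complete trial: locomotion, walkers, gaze, pupil.

    The participant trajectory is generated first; walker-file phase
    offsets are then chosen so the row crossings realize the policy's gap
    geometry; gaze and pupil streams are generated on the shared frame
    clock.  Setting ``with_gaze=False`` skips the eye streams for cheap
    trajectory-only cohorts.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    part = simulate_participant(
        policy, layout, condition, seed=int(rng.integers(2**31)), fs=fs
    )
    duration = float(part.t[-1])
    offsets = align_walker_offsets(part, layout, condition)
    tracks = simulate_walkers(
        layout, condition, duration, fs=fs, phase_offsets=offsets
    )
    frames = pd.DataFrame({"t": part.t})
    frames["head_x"] = part.head_pos[:, 0]
    frames["head_y"] = part.head_pos[:, 1]
    frames["head_z"] = part.head_pos[:, 2]
    truth: dict = {
        "path_class": part.path_class,
        "crossing_times": {str(k): v for k, v in part.crossing_times.items()},
        "gap_fractions": {str(k): v for k, v in part.gap_fractions.items()},
        "failed": part.failed,
    }
    if with_gaze:
        gaze = simulate_gaze(
            part.t,
            part.head_pos,
            layout,
            tracks,
            condition,
            seed=int(rng.integers(2**31)),
            schedule=schedule,
            params=gaze_params,
        )
        for eye in ("eyeL", "eyeR"):
            o = gaze[f"{eye}_origin"]
            d = gaze[f"{eye}_dir"]
            for k, ax in enumerate("xyz"):
                frames[f"{eye}_o{ax}"] = o[:, k]
                frames[f"{eye}_d{ax}"] = d[:, k]
        frames["event_label"] = gaze["event_label"]
        frames["target_id"] = gaze["target_id"]
        phase_idx = frame_phase_indices(part.t, part.head_pos[:, 2], layout)
        load = np.array([load_by_phase[PHASE_LABELS[k]] for k in phase_idx])
        frames["pupil_mm"] = simulate_pupil(
            part.t, load, seed=int(rng.integers(2**31)), params=pupil_params
        )
        frames["valid"] = True
    return TrialLog(
        trial_id=trial_id,
        condition=condition,
        layout=layout,
        frames=frames,
        walker_tracks=tracks,
        seed=seed,
        truth=truth,
    )
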