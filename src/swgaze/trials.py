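"""Trial-level bookkeeping: phases, success scoring, filtering, path shape.

Each trial is divided into four phases driven by elapsed time and the
participant's depth (z) in the room:

* ``initial_preparation`` — before the gate cue (t < 2 s) and before row 1;
* ``approaching_first_row`` — cue shown, still before row 1 (z < 1.4 m);
* ``approaching_second_row`` — between the rows (1.4 <= z < 4.7 m);
* ``approaching_gate`` — past row 2 (z >= 4.7 m).

Phase labels are monotone within a trial: brief backward dips in z do not
re-open an earlier phase.  Each phase splits into four equal-duration
quarters (start/early/middle/late), giving 16 mini-phases per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .scene import SceneLayout, TrialCondition, gate_x

__all__ = [
    "PHASE_LABELS",
    "MINI_PHASE_QUARTERS",
    "TrialPhase",
    "TrialOutcome",
    "frame_phase_indices",
    "segment_phases",
    "mini_phases",
    "detect_gate_arrival",
    "assess_success",
    "filter_trials",
    "detect_hooked",
]

PHASE_LABELS = (
    "initial_preparation",
    "approaching_first_row",
    "approaching_second_row",
    "approaching_gate",
)
MINI_PHASE_QUARTERS = ("start", "early", "middle", "late")

ARRIVAL_BOX_DEPTH = 0.3  # m; arrival region extends this far in front of the gate
PASS_THROUGH_GRACE = 0.25  # s; shorter foil-box visits en route to target don't count
DEFAULT_GATE_WIDTH = 0.9  # m


@dataclass(frozen=True)
class TrialPhase:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("phase must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class TrialOutcome:
    trial_id: str
    duration_s: float
    success: bool
    reached_gate: str  # "target" | "foil" | "none"
    path_class: str = "direct"  # "direct" | "hooked"
    excluded: bool = False
    exclusion_reason: str = "none"  # "overlong" | "wrong_gate" | "none"

    def __post_init__(self) -> None:
        if self.success and self.reached_gate != "target":
            raise ValueError("a successful trial must have reached the target gate")


def frame_phase_indices(
    t: np.ndarray, z: np.ndarray, layout: SceneLayout, cue_time: float = 2.0
) -> np.ndarray:
    """Per-frame phase index (0..3) under the monotone-label rule."""
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    raw = np.zeros(len(t), dtype=int)
    raw[(t >= cue_time) & (z < layout.row1_z)] = 1
    raw[(z >= layout.row1_z) & (z < layout.row2_z)] = 2
    raw[z >= layout.row2_z] = 3
    # A closed phase never re-opens (e.g. z dipping back below a row line).
    return np.maximum.accumulate(raw)


def segment_phases(
    t: np.ndarray,
    z: np.ndarray,
    layout: SceneLayout,
    cue_time: float = 2.0,
) -> list[TrialPhase]:
    """Contiguous phase intervals covering [t0, t_end] of the trial.

    A trial that ends before reaching a later phase yields a partial list
    (with a warning); intervals are half-open with the final phase closed at
    the last timestamp.
    """
    idx = frame_phase_indices(t, z, layout, cue_time)
    phases: list[TrialPhase] = []
    start = 0
    for i in range(1, len(idx) + 1):
        if i == len(idx) or idx[i] != idx[start]:
            t_end = t[i] if i < len(idx) else t[-1]
            if t_end > t[start]:
                phases.append(TrialPhase(PHASE_LABELS[idx[start]], float(t[start]), float(t_end)))
            start = i
    if len(phases) < 4:
        warnings.warn(
            f"trial ended with only {len(phases)} of 4 phases "
            f"(last: {phases[-1].label if phases else 'none'})",
            stacklevel=2,
        )
    return phases


def mini_phases(phases: list[TrialPhase]) -> list[tuple[str, str, float, float]]:
    """Split each of the 4 phases into equal quarters -> 16 labeled segments.

    Returns (phase label, quarter label, t_start, t_end) tuples.
    """
    present = [p.label for p in phases]
    missing = [lbl for lbl in PHASE_LABELS if lbl not in present]
    if missing:
        raise ValueError(f"cannot build mini-phases; missing phase(s): {missing}")
    out: list[tuple[str, str, float, float]] = []
    for p in phases:
        edges = np.linspace(p.t_start, p.t_end, 5)
        for q, (a, b) in zip(MINI_PHASE_QUARTERS, zip(edges[:-1], edges[1:])):
            out.append((p.label, q, float(a), float(b)))
    return out


def _gate_box(layout: SceneLayout, side: str, width: float) -> tuple[float, float, float, float]:
    gx = gate_x(layout, side)
    return (
        gx - width / 2,
        gx + width / 2,
        layout.room_length_z - ARRIVAL_BOX_DEPTH,
        layout.room_length_z,
    )


def detect_gate_arrival(
    t: np.ndarray,
    xz: np.ndarray,
    layout: SceneLayout,
    condition: TrialCondition,
    gate_width: float = DEFAULT_GATE_WIDTH,
) -> tuple[str, float | None]:
    """First gate whose arrival box the head enters, with the entry time.

    The arrival box is gate-width wide and 0.3 m deep at the far wall.  A
    visit to the foil box shorter than 0.25 s followed by target-box entry
    within the same trial counts as a pass-through, not an arrival.
    """
    t = np.asarray(t, dtype=float)
    xz = np.asarray(xz, dtype=float)
    if len(t) == 0:
        raise ValueError("empty trajectory")
    target_side = condition.gate_side
    foil_side = "right" if target_side == "left" else "left"
    entries: dict[str, np.ndarray] = {}
    for name, side in (("target", target_side), ("foil", foil_side)):
        x_lo, x_hi, z_lo, z_hi = _gate_box(layout, side, gate_width)
        inside = (
            (xz[:, 0] >= x_lo)
            & (xz[:, 0] <= x_hi)
            & (xz[:, 1] >= z_lo)
            & (xz[:, 1] <= z_hi)
        )
        entries[name] = inside
    first_target = np.argmax(entries["target"]) if entries["target"].any() else None
    first_foil = np.argmax(entries["foil"]) if entries["foil"].any() else None
    if first_foil is not None and (first_target is None or first_foil < first_target):
        # Pass-through grace: brief foil visit followed by target arrival.
        inside = entries["foil"]
        end = first_foil
        while end < len(t) and inside[end]:
            end += 1
        visit = t[min(end, len(t) - 1)] - t[first_foil]
        if first_target is not None and visit < PASS_THROUGH_GRACE:
            return "target", float(t[first_target])
        return "foil", float(t[first_foil])
    if first_target is not None:
        return "target", float(t[first_target])
    return "none", None


def assess_success(
    reached_gate: str,
    arrival_time: float | None,
    deadline_s: float,
    grace_s: float = 1.0,
) -> bool:
    """Success = reached the target gate within deadline plus a 1 s grace."""
    if deadline_s <= 0:
        raise ValueError("deadline must be positive")
    return (
        reached_gate == "target"
        and arrival_time is not None
        and arrival_time <= deadline_s + grace_s
    )


@dataclass
class ExclusionLedger:
    total: int = 0
    overlong: int = 0
    wrong_gate: int = 0
    kept: int = 0
    details: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        frac = lambda n: (n / self.total) if self.total else 0.0
        return {
            "total": self.total,
            "kept": self.kept,
            "excluded": {
                "overlong": {"count": self.overlong, "fraction": frac(self.overlong)},
                "wrong_gate": {"count": self.wrong_gate, "fraction": frac(self.wrong_gate)},
            },
            "details": self.details,
        }


def filter_trials(
    outcomes: list[TrialOutcome],
    max_duration_s: float = 16.0,
) -> tuple[list[TrialOutcome], list[TrialOutcome], ExclusionLedger]:
    """Two-stage trial filter.

    Stage 1 removes over-long trials (duration > 16 s, assumed technical
    failures) before any statistics.  Stage 2 additionally removes
    wrong-gate trials; those remain available for success/duration
    statistics but are excluded from gaze analyses.  Returns
    (stage-1 survivors, stage-2 survivors, ledger).
    """
    ledger = ExclusionLedger(total=len(outcomes))
    stage1: list[TrialOutcome] = []
    for o in outcomes:
        if o.duration_s > max_duration_s:
            o.excluded = True
            o.exclusion_reason = "overlong"
            ledger.overlong += 1
            ledger.details.append({"trial_id": o.trial_id, "reason": "overlong"})
        else:
            stage1.append(o)
    stage2: list[TrialOutcome] = []
    for o in stage1:
        if o.reached_gate == "foil":
            o.excluded = True
            o.exclusion_reason = "wrong_gate"
            ledger.wrong_gate += 1
            ledger.details.append({"trial_id": o.trial_id, "reason": "wrong_gate"})
        else:
            stage2.append(o)
    ledger.kept = len(stage2)
    return stage1, stage2, ledger


def detect_hooked(
    xz: np.ndarray,
    layout: SceneLayout,
    condition: TrialCondition,
    bench_zone: tuple[float, float] = (2.0, 4.1),
) -> bool:
    """Hooked-path rule: wrong-side bench passage plus a late midline cross.

    A trial is hooked when the mean lateral position while traversing the
    bench zone lies on the opposite side of the target gate AND the path
    crosses the midline (x = 0) at some depth beyond the bench zone.  Paths
    hugging the midline exactly count as direct.
    """
    xz = np.asarray(xz, dtype=float)
    if xz[:, 1].max() < layout.row2_z:
        raise ValueError("trajectory must reach the second row for path-shape analysis")
    z_lo, z_hi = bench_zone
    in_zone = (xz[:, 1] >= z_lo) & (xz[:, 1] <= z_hi)
    if not in_zone.any():
        return False
    target_sign = -1.0 if condition.gate_side == "left" else 1.0
    mean_x = float(np.mean(xz[in_zone, 0]))
    if mean_x == 0.0 or np.sign(mean_x) == target_sign:
        return False
    late = xz[:, 1] > z_hi
    x_late = xz[late, 0]
    crosses = np.any(np.sign(x_late[:-1]) * np.sign(x_late[1:]) <= 0) if len(x_late) > 1 else False
    return bool(crosses)
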