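"""Virtual train-station geometry and the two factorial experiment designs.

The study environment is a 5 m (x) by 6 m (z) waiting room.  The participant
starts at (0, 0) and must reach one of two exit gates on the far wall
(z = 6 m) within a deadline.  Two single-file rows of walkers cross the room
perpendicular to the participant's travel direction, at z = 1.4 m (row 1)
and z = 4.7 m (row 2).  A gate-indicator sign hangs at z = 1.7 m, standers
idle at z = 3 m near the side walls, and back-to-back bench pairs occupy the
room centre, forcing an initial left/right choice.

Coordinates are right-handed with y up: x is lateral (midline at x = 0,
positive x toward the right gate, gate 2), z is depth from the start platform
to the far wall.  All positions are in metres, times in seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ObjectSpec",
    "SceneLayout",
    "TrialCondition",
    "SessionDesign",
    "build_default_scene",
    "enumerate_conditions",
    "generate_session_design",
]


class SceneConfigurationError(ValueError):
    """Unknown layout field named in an override mapping."""


class SceneValidationError(ValueError):
    """Layout values violate a geometric invariant."""


@dataclass(frozen=True)
class ObjectSpec:
    """A static or dynamic scene object with an axis-aligned box collider.

    ``position`` is the collider centre (x, y, z); ``collider`` holds full
    box extents along each axis.  ``facing`` is an optional unit horizontal
    direction for agents (walkers face their travel direction, standers face
    away from the room centre).
    """

    id: str
    kind: str  # walker_row1 | walker_row2 | sitter | stander | bench |
    #            gate_target | gate_foil | gate_indicator | timer | wall | other
    position: tuple[float, float, float]
    collider: tuple[float, float, float]
    facing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.collider) <= 0:
            raise SceneValidationError(
                f"object {self.id!r}: collider extents must be strictly positive"
            )

    @property
    def volume(self) -> float:
        ex, ey, ez = self.collider
        return ex * ey * ez

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the collider box."""
        c = np.asarray(self.position, dtype=float)
        h = np.asarray(self.collider, dtype=float) / 2.0
        return c - h, c + h


# Collider sizes (full extents, metres).  Walkers get a 0.4 x 1.8 x 0.3 box;
# the rest are plausible human/furniture footprints.
WALKER_COLLIDER = (0.4, 1.8, 0.3)
SITTER_COLLIDER = (0.5, 1.3, 0.8)  # depth includes extended legs
STANDER_COLLIDER = (0.5, 1.8, 0.5)
GATE_COLLIDER = (0.9, 2.2, 0.2)
INDICATOR_COLLIDER = (0.8, 0.4, 0.1)
TIMER_COLLIDER = (0.7, 0.4, 0.1)


@dataclass(frozen=True)
class SceneLayout:
    """Static geometry of the virtual train station."""

    room_width_x: float = 5.0
    room_length_z: float = 6.0
    start_position: tuple[float, float] = (0.0, 0.0)
    row1_z: float = 1.4
    row2_z: float = 4.7
    gate_indicator_z: float = 1.7
    standers_z: float = 3.0
    gate_positions: tuple[tuple[float, float], tuple[float, float]] = (
        (-1.25, 6.0),
        (1.25, 6.0),
    )
    bench_specs: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = (
        (((0.0), 3.05), (1.2, 2.4)),
    )
    object_registry: tuple[ObjectSpec, ...] = field(default_factory=tuple)
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not (
            self.row1_z
            < self.gate_indicator_z
            < self.standers_z
            < self.row2_z
            < self.room_length_z
        ):
            raise SceneValidationError(
                "row/landmark depth ordering violated: require "
                "row1_z < gate_indicator_z < standers_z < row2_z < room_length_z, got "
                f"{self.row1_z} < {self.gate_indicator_z} < {self.standers_z} "
                f"< {self.row2_z} < {self.room_length_z}"
            )
        ids = [o.id for o in self.object_registry]
        if len(ids) != len(set(ids)):
            raise SceneValidationError("duplicate object ids in registry")
        hw = self.room_width_x / 2.0
        for obj in self.object_registry:
            x, _, z = obj.position
            if not (-hw <= x <= hw and 0.0 <= z <= self.room_length_z):
                raise SceneValidationError(
                    f"object {obj.id!r} at {obj.position} lies outside the room"
                )

    @property
    def half_width(self) -> float:
        return self.room_width_x / 2.0

    def object_by_id(self, obj_id: str) -> ObjectSpec:
        for obj in self.object_registry:
            if obj.id == obj_id:
                return obj
        raise KeyError(obj_id)

    def static_obstacles(self) -> list[ObjectSpec]:
        """Objects the participant must not walk through (benches, sitters, standers)."""
        return [
            o
            for o in self.object_registry
            if o.kind in ("bench", "sitter", "stander")
        ]

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "units": {"length": "m", "time": "s"},
            "room_width_x": self.room_width_x,
            "room_length_z": self.room_length_z,
            "start_position": list(self.start_position),
            "row1_z": self.row1_z,
            "row2_z": self.row2_z,
            "gate_indicator_z": self.gate_indicator_z,
            "standers_z": self.standers_z,
            "gate_positions": [list(g) for g in self.gate_positions],
            "bench_specs": [
                [list(c), list(e)] for c, e in self.bench_specs
            ],
            "objects": [
                {
                    "id": o.id,
                    "kind": o.kind,
                    "position": list(o.position),
                    "collider": list(o.collider),
                    "facing": list(o.facing) if o.facing is not None else None,
                }
                for o in self.object_registry
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneLayout":
        objs = tuple(
            ObjectSpec(
                id=o["id"],
                kind=o["kind"],
                position=tuple(o["position"]),
                collider=tuple(o["collider"]),
                facing=tuple(o["facing"]) if o.get("facing") else None,
            )
            for o in d.get("objects", [])
        )
        return cls(
            room_width_x=d["room_width_x"],
            room_length_z=d["room_length_z"],
            start_position=tuple(d["start_position"]),
            row1_z=d["row1_z"],
            row2_z=d["row2_z"],
            gate_indicator_z=d["gate_indicator_z"],
            standers_z=d["standers_z"],
            gate_positions=tuple(tuple(g) for g in d["gate_positions"]),
            bench_specs=tuple(
                (tuple(c), tuple(e)) for c, e in d["bench_specs"]
            ),
            object_registry=objs,
            schema_version=d.get("schema_version", 1),
        )


_SCALAR_FIELDS = (
    "room_width_x",
    "room_length_z",
    "start_position",
    "row1_z",
    "row2_z",
    "gate_indicator_z",
    "standers_z",
    "gate_positions",
    "bench_specs",
)


def _default_registry(layout: SceneLayout) -> tuple[ObjectSpec, ...]:
    """Populate static objects consistent with the layout scalars.

    Gates are registered as gate_target/gate_foil in left/right order; a
    trial condition decides which physical gate is the target (see
    :func:`gate_ids_for_condition`).
    """
    objs: list[ObjectSpec] = []
    (gx1, gz1), (gx2, gz2) = layout.gate_positions
    objs.append(
        ObjectSpec("gate_left", "gate_target", (gx1, 1.1, gz1), GATE_COLLIDER)
    )
    objs.append(
        ObjectSpec("gate_right", "gate_foil", (gx2, 1.1, gz2), GATE_COLLIDER)
    )
    # Sign hangs from the ceiling ~1.7 m ahead of the start, eye-level plus.
    objs.append(
        ObjectSpec(
            "gate_indicator",
            "gate_indicator",
            (0.0, 2.2, layout.gate_indicator_z),
            INDICATOR_COLLIDER,
        )
    )
    # Countdown timer board on the far wall between the gates.
    objs.append(
        ObjectSpec("timer", "timer", (0.0, 2.4, layout.room_length_z), TIMER_COLLIDER)
    )
    for (cx, cz), (ex, ez) in layout.bench_specs:
        objs.append(
            ObjectSpec(
                f"bench_{cx:+.2f}_{cz:.2f}".replace("+", "p").replace("-", "m"),
                "bench",
                (cx, 0.45, cz),
                (ex, 0.9, ez),
            )
        )
    # Sitter slots flank the bench block on both lateral edges; a condition
    # selects which slots are occupied (see sitter_ids_for_condition).
    (cx, cz), (ex, ez) = layout.bench_specs[0]
    for side, sx in (("left", cx - ex / 2 - 0.25), ("right", cx + ex / 2 + 0.25)):
        for k, sz in enumerate((cz - ez / 4, cz + ez / 4)):
            objs.append(
                ObjectSpec(
                    f"sitter_{side}_{k}",
                    "sitter",
                    (sx, 0.8, sz),
                    SITTER_COLLIDER,
                    facing=(-1.0, 0.0) if side == "left" else (1.0, 0.0),
                )
            )
    # Standers idle near the side walls (map viewer / ticket buyer), backs to
    # the room.
    sx = layout.half_width - 0.35
    objs.append(
        ObjectSpec(
            "stander_left", "stander", (-sx, 0.9, layout.standers_z),
            STANDER_COLLIDER, facing=(-1.0, 0.0),
        )
    )
    objs.append(
        ObjectSpec(
            "stander_right", "stander", (sx, 0.9, layout.standers_z),
            STANDER_COLLIDER, facing=(1.0, 0.0),
        )
    )
    # Bounding walls (thin boxes on the boundary).
    L, W = layout.room_length_z, layout.room_width_x
    objs.append(ObjectSpec("wall_far", "wall", (0.0, 1.5, L), (W, 3.0, 0.1)))
    objs.append(ObjectSpec("wall_near", "wall", (0.0, 1.5, 0.0), (W, 3.0, 0.1)))
    objs.append(
        ObjectSpec("wall_left", "wall", (-W / 2, 1.5, L / 2), (0.1, 3.0, L))
    )
    objs.append(
        ObjectSpec("wall_right", "wall", (W / 2, 1.5, L / 2), (0.1, 3.0, L))
    )
    return tuple(objs)


def build_default_scene(overrides: dict | None = None) -> SceneLayout:
    """Construct the default train-station layout, optionally overriding fields.

    Parameters
    ----------
    overrides
        Mapping of layout field name to replacement value.  Only scalar
        layout fields may be overridden; unknown keys raise
        :class:`SceneConfigurationError`, values breaking the depth-ordering
        invariant raise :class:`SceneValidationError`.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(_SCALAR_FIELDS)
    if unknown:
        raise SceneConfigurationError(
            f"unknown scene override key(s): {sorted(unknown)}"
        )
    base = SceneLayout(**overrides)
    return replace(base, object_registry=_default_registry(base))


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the factorial design.

    Experiment 1 crosses gate side x walker directions x sitter position at a
    fixed 12 s deadline; experiment 2 fixes sitters to both sides and crosses
    gate side x walker directions x deadline (8, 10, 12 s).
    """

    experiment: int
    gate_side: str  # "left" | "right"
    row_directions: str  # "row1_from_left" | "row1_from_right"
    sitter_position: str  # "both" | "gate_side" | "opposite"
    deadline_s: float

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.gate_side not in ("left", "right"):
            raise ValueError(f"bad gate_side {self.gate_side!r}")
        if self.row_directions not in ("row1_from_left", "row1_from_right"):
            raise ValueError(f"bad row_directions {self.row_directions!r}")
        if self.sitter_position not in ("both", "gate_side", "opposite"):
            raise ValueError(f"bad sitter_position {self.sitter_position!r}")
        if self.experiment == 1 and self.deadline_s != 12:
            raise ValueError("experiment 1 uses a fixed 12 s deadline")
        if self.experiment == 2 and self.sitter_position != "both":
            raise ValueError("experiment 2 always has sitters on both sides")


def enumerate_conditions(experiment: int) -> list[TrialCondition]:
    """Full factorial condition grid for one experiment (12 cells each)."""
    if experiment == 1:
        return [
            TrialCondition(1, gate, rows, sitters, 12.0)
            for gate, rows, sitters in itertools.product(
                ("left", "right"),
                ("row1_from_left", "row1_from_right"),
                ("both", "gate_side", "opposite"),
            )
        ]
    if experiment == 2:
        return [
            TrialCondition(2, gate, rows, "both", deadline)
            for gate, rows, deadline in itertools.product(
                ("left", "right"),
                ("row1_from_left", "row1_from_right"),
                (8.0, 10.0, 12.0),
            )
        ]
    raise ValueError(f"unknown experiment {experiment!r}")


@dataclass(frozen=True)
class SessionDesign:
    """A seeded, fully randomized trial order for one session."""

    participant_id: str
    ordered_trials: tuple[TrialCondition, ...]
    seed: int


def generate_session_design(
    conditions: list[TrialCondition],
    reps: int,
    seed: int,
    participant_id: str = "P00",
) -> SessionDesign:
    """Repeat each condition ``reps`` times and shuffle with a seeded RNG.

    The default design (12 conditions, 7 reps) yields 84 trials per session.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not conditions:
        raise ValueError("conditions must be non-empty")
    pool = [c for c in conditions for _ in range(reps)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return SessionDesign(
        participant_id=participant_id,
        ordered_trials=tuple(pool[i] for i in order),
        seed=seed,
    )


def gate_ids_for_condition(
    layout: SceneLayout, condition: TrialCondition
) -> tuple[str, str]:
    """(target gate id, foil gate id) for a condition on this layout."""
    if condition.gate_side == "left":
        return "gate_left", "gate_right"
    return "gate_right", "gate_left"


def gate_x(layout: SceneLayout, side: str) -> float:
    (gx1, _), (gx2, _) = layout.gate_positions
    return gx1 if side == "left" else gx2


def occupied_sitter_ids(
    layout: SceneLayout, condition: TrialCondition
) -> list[str]:
    """Sitter slots occupied under a condition's bench-occupancy level."""
    sitters = [o.id for o in layout.object_registry if o.kind == "sitter"]
    if condition.sitter_position == "both":
        return sitters
    gate_side = condition.gate_side
    keep = gate_side if condition.sitter_position == "gate_side" else (
        "left" if gate_side == "right" else "right"
    )
    return [s for s in sitters if f"_{keep}_" in s]
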