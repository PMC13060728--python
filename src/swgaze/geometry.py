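"""3D gaze reconstruction and spatial discretization.

The headset logs one ray per eye (origin + unit direction).  The 3D gaze
point is reconstructed by vergence: the midpoint of the shortest segment
between the two eye rays, with the segment length kept as a quality figure.
Each gaze point is attributed to a scene object by testing collider boxes,
with a cyclopean-ray cast as fallback when the vergence point lies in open
space.  For entropy analysis gaze points are discretized into a regular
(x, z, y) grid — 6 x 12 x 3 = 216 states by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import ObjectSpec, SceneLayout

__all__ = [
    "Ray",
    "GazePoint",
    "GridSpec",
    "intersect_gaze_rays",
    "cast_to_colliders",
    "attribute_gaze",
    "discretize_gaze",
    "angular_kinematics",
    "cyclopean_ray",
]

_PARALLEL_EPS = 1e-9


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0.0:
            raise ValueError("ray direction must be non-zero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class GazePoint:
    """A reconstructed 3D gaze point.

    ``quality`` is the length of the shortest segment between the two eye
    rays (0 for exact convergence).  ``method`` is "vergence" normally and
    "collider_fallback" when the rays are (near-)parallel and no finite
    vergence point exists.
    """

    t: float
    point: np.ndarray | None
    quality: float
    method: str = "vergence"

    @property
    def valid(self) -> bool:
        return self.point is not None and np.all(np.isfinite(self.point))


def intersect_gaze_rays(left: Ray, right: Ray, t: float = 0.0) -> GazePoint:
    """Vergence intersection of the two eye rays.

    Solves for the ray parameters minimizing the inter-line distance,
    clamped to non-negative values (gaze points cannot lie behind the eyes),
    and returns the midpoint of the connecting segment.  Near-parallel rays
    (cross-product norm below 1e-9) have no usable vergence point and are
    flagged for collider fallback.
    """
    d1, d2 = left.direction, right.direction
    if np.linalg.norm(np.cross(d1, d2)) < _PARALLEL_EPS:
        return GazePoint(t=t, point=None, quality=np.inf, method="collider_fallback")
    w0 = left.origin - right.origin
    a = 1.0  # d1.d1, unit
    b = float(d1 @ d2)
    c = 1.0  # d2.d2
    d = float(d1 @ w0)
    e = float(d2 @ w0)
    denom = a * c - b * b
    s = (b * e - c * d) / denom
    u = (a * e - b * d) / denom
    if s < 0.0 or u < 0.0:
        # The constrained optimum of this convex problem lies on an edge:
        # evaluate both edge minimizers and keep the closer pair.
        def dist2(ss: float, uu: float) -> float:
            v = w0 + ss * d1 - uu * d2
            return float(v @ v)

        cand_a = (0.0, max(0.0, e / c))  # s = 0 edge
        cand_b = (max(0.0, -d / a), 0.0)  # u = 0 edge
        s, u = min((cand_a, cand_b), key=lambda p: dist2(*p))
    p1 = left.origin + s * d1
    p2 = right.origin + u * d2
    gap = float(np.linalg.norm(p1 - p2))
    return GazePoint(t=t, point=(p1 + p2) / 2.0, quality=gap, method="vergence")


def cyclopean_ray(left: Ray, right: Ray) -> Ray:
    """Average-eye ray: mean origin, renormalized mean direction."""
    return Ray(
        origin=(left.origin + right.origin) / 2.0,
        direction=left.direction + right.direction,
    )


def _ray_box_hit(
    origin: np.ndarray, direction: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> float | None:
    """Slab-test distance along the ray to an AABB, or None on a miss."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / direction
        t1 = (lo - origin) * inv
        t2 = (hi - origin) * inv
    # Zero-direction axes: inside-slab check.
    for k in range(3):
        if direction[k] == 0.0:
            if not (lo[k] <= origin[k] <= hi[k]):
                return None
            t1[k], t2[k] = -np.inf, np.inf
    tnear = float(np.max(np.minimum(t1, t2)))
    tfar = float(np.min(np.maximum(t1, t2)))
    if tnear > tfar or tfar < 0.0:
        return None
    if tnear < 0.0:
        # Ray origin lies inside the box (e.g. the observer standing on the
        # boundary wall): not a gaze target.
        return None
    return tnear


def cast_to_colliders(
    ray: Ray,
    layout: SceneLayout,
    walker_states: list[ObjectSpec] | None = None,
) -> tuple[str, np.ndarray] | None:
    """Nearest collider hit along a ray, or None if the ray escapes.

    ``walker_states`` supplies the dynamic agents as ObjectSpecs positioned
    at the frame's timestamp; static objects come from the layout registry.
    """
    best: tuple[float, str] | None = None
    for obj in list(layout.object_registry) + list(walker_states or []):
        lo, hi = obj.bounds()
        dist = _ray_box_hit(ray.origin, ray.direction, lo, hi)
        if dist is not None and (best is None or dist < best[0]):
            best = (dist, obj.id)
    if best is None:
        return None
    dist, obj_id = best
    return obj_id, ray.origin + dist * ray.direction


def _point_box_distance(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    d = np.maximum(np.maximum(lo - p, 0.0), p - hi)
    return float(np.linalg.norm(d))


def attribute_gaze(
    gaze_point: GazePoint,
    cyclopean: Ray,
    layout: SceneLayout,
    walker_states: list[ObjectSpec] | None = None,
    snap_radius: float = 0.1,
) -> str:
    """Attribute a gaze sample to a scene object id, or "none".

    Primary rule: the object whose collider contains the vergence point or
    comes within ``snap_radius`` of it; ties at equal distance go to the
    smaller collider volume (a sitter beats the bench it sits on).  When no
    collider is close enough — or the vergence point is invalid — the
    cyclopean ray is cast against all colliders instead.
    """
    objects = list(layout.object_registry) + list(walker_states or [])
    if gaze_point.valid and gaze_point.method == "vergence":
        p = np.asarray(gaze_point.point, dtype=float)
        candidates: list[tuple[float, float, str]] = []
        for obj in objects:
            lo, hi = obj.bounds()
            dist = _point_box_distance(p, lo, hi)
            if dist <= snap_radius:
                candidates.append((dist, obj.volume, obj.id))
        if candidates:
            candidates.sort()
            return candidates[0][2]
    hit = cast_to_colliders(cyclopean, layout, walker_states)
    return hit[0] if hit is not None else "none"


@dataclass(frozen=True)
class GridSpec:
    """Regular spatial grid for gaze-state discretization.

    ``bins`` is (n_x, n_z, n_y); the default 6 x 12 x 3 grid yields 216
    states.  ``extents`` are ((x_lo, x_hi), (z_lo, z_hi), (y_lo, y_hi)).
    """

    bins: tuple[int, int, int] = (6, 12, 3)
    extents: tuple[tuple[float, float], ...] = (
        (-2.5, 2.5),
        (0.0, 6.0),
        (0.0, 2.5),
    )

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.bins):
            raise ValueError("grid bin counts must all be >= 1")

    @property
    def n_states(self) -> int:
        nx, nz, ny = self.bins
        return nx * nz * ny

    @classmethod
    def for_layout(
        cls, layout: SceneLayout, bins: tuple[int, int, int] = (6, 12, 3)
    ) -> "GridSpec":
        hw = layout.half_width
        return cls(
            bins=bins,
            extents=((-hw, hw), (0.0, layout.room_length_z), (0.0, 2.5)),
        )


def discretize_gaze(points: list[GazePoint] | np.ndarray, grid: GridSpec) -> np.ndarray:
    """Map gaze points to integer grid states; invalid points map to -1.

    Out-of-extent coordinates clamp to the boundary bins, so the function is
    total on valid points.  State index = ix + n_x * (iz + n_z * iy).
    """
    if isinstance(points, np.ndarray):
        coords = np.asarray(points, dtype=float)
        valid = np.all(np.isfinite(coords), axis=1)
    else:
        coords = np.array(
            [
                p.point if p.valid else (np.nan, np.nan, np.nan)
                for p in points
            ],
            dtype=float,
        ).reshape(-1, 3)
        valid = np.array([p.valid for p in points], dtype=bool)
    nx, nz, ny = grid.bins
    (xlo, xhi), (zlo, zhi), (ylo, yhi) = grid.extents
    out = np.full(len(coords), -1, dtype=int)
    if not valid.any():
        return out
    c = coords[valid]

    def _bin(v: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
        idx = np.floor((v - lo) / (hi - lo) * n).astype(int)
        return np.clip(idx, 0, n - 1)

    ix = _bin(c[:, 0], xlo, xhi, nx)
    iz = _bin(c[:, 2], zlo, zhi, nz)
    iy = _bin(c[:, 1], ylo, yhi, ny)
    out[valid] = ix + nx * (iz + nz * iy)
    return out


def angular_kinematics(
    t: np.ndarray, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angular position, speed and acceleration of a gaze-direction series.

    Directions are (n, 3) unit vectors in world coordinates.  Position is
    returned as unwrapped (azimuth, elevation) in degrees; speed (deg/s) is
    the spherical rate combining both components via central differences
    (one-sided at the endpoints, as computed by ``np.gradient``);
    acceleration is the time-derivative of speed.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(directions, dtype=float)
    if len(t) < 3:
        raise ValueError("angular kinematics needs at least 3 frames")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    d = d / norms
    azimuth = np.unwrap(np.arctan2(d[:, 0], d[:, 2]))
    elevation = np.arcsin(np.clip(d[:, 1], -1.0, 1.0))
    az_rate = np.gradient(azimuth, t)
    el_rate = np.gradient(elevation, t)
    # Spherical speed: azimuth rate scaled by cos(elevation).
    speed = np.degrees(np.sqrt((az_rate * np.cos(elevation)) ** 2 + el_rate**2))
    accel = np.gradient(speed, t)
    angles = np.degrees(np.column_stack([azimuth, elevation]))
    return angles, speed, accel
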