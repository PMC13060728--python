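"""Headline gaze and trajectory metrics.

* attention taxonomy — every attributed gaze frame is labeled local,
  global, task_related or miscellaneous as a function of trial phase and
  the gazed object's kind (local = imminent obstacles, global = future-
  phase obstacles / look-ahead, task_related = information sources: gate
  indicator and timer);
* gaze transition entropy (GTE) — normalized conditional Shannon entropy
  of transitions between discretized gaze states over rolling windows;
* ambient/focal K-coefficient — standardized fixation duration minus
  standardized subsequent-saccade amplitude;
* gap-crossing geometry, distance from midline, speed-vs-depth profiles,
  signed gaze-movement alignment, LHIPA pupillometric load index, and
  smoothed gaze-density maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import gaussian_filter

from .scene import SceneLayout
from .simulate import WalkerTrack
from .trials import PHASE_LABELS, TrialPhase

__all__ = [
    "ATTENTION_LABELS",
    "AttentionMap",
    "default_attention_map",
    "label_attention",
    "gaze_allocation",
    "GteResult",
    "gte",
    "KResult",
    "k_coefficient",
    "GapCrossing",
    "gap_crossing",
    "distance_from_midline",
    "speed_profile",
    "gaze_movement_alignment",
    "lhipa",
    "gaze_density_grid",
]

ATTENTION_LABELS = ("local", "global", "task_related", "miscellaneous")

BENCH_ZONE = (2.0, 4.1)


# ---------------------------------------------------------------------------
# Attention taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttentionMap:
    """Total mapping (phase label, object kind) -> attention label.

    Kinds not listed for a phase fall through to "miscellaneous".  Where a
    kind would qualify for several labels (the timer is both a look-ahead
    and an information source while approaching the first row) the
    precedence task_related > local > global applies: information sources
    keep their task_related role everywhere they are listed.
    """

    mapping: dict[tuple[str, str], str]

    def label(self, phase: str, kind: str) -> str:
        if phase not in PHASE_LABELS:
            raise ValueError(f"unknown phase {phase!r}")
        return self.mapping.get((phase, kind), "miscellaneous")


def default_attention_map() -> AttentionMap:
    gates = ("gate_target", "gate_foil")
    m: dict[tuple[str, str], str] = {}

    def put(phase: str, kinds, label: str) -> None:
        for k in kinds:
            m[(phase, k)] = label

    p = "initial_preparation"
    put(p, ["walker_row1"], "local")
    put(p, ["walker_row2", *gates, "stander", "sitter", "bench"], "global")
    put(p, ["gate_indicator", "timer"], "task_related")

    p = "approaching_first_row"
    put(p, ["walker_row1", "stander", "sitter", "bench"], "local")
    put(p, ["walker_row2", *gates], "global")
    put(p, ["gate_indicator", "timer"], "task_related")

    p = "approaching_second_row"
    put(p, ["walker_row1", "walker_row2", "stander", "sitter", "bench"], "local")
    put(p, list(gates), "global")
    put(p, ["timer"], "task_related")

    p = "approaching_gate"
    put(p, list(gates), "local")
    put(p, ["timer"], "task_related")
    return AttentionMap(m)


def label_attention(
    target_kind: str | None,
    phase: str,
    attention_map: AttentionMap | None = None,
) -> str:
    """Attention label for one attributed gaze frame.

    ``target_kind`` is the gazed object's kind ("none"/None for
    unattributed gaze, which is miscellaneous by definition).
    """
    attention_map = attention_map or default_attention_map()
    if target_kind is None or target_kind == "none":
        if phase not in PHASE_LABELS:
            raise ValueError(f"unknown phase {phase!r}")
        return "miscellaneous"
    return attention_map.label(phase, target_kind)


def kind_of_target(target_id: str, layout: SceneLayout) -> str:
    """Object kind for an attribution target id (walkers resolved by name)."""
    if target_id is None or target_id == "none" or target_id != target_id:
        return "none"
    if target_id.startswith("walker_r1"):
        return "walker_row1"
    if target_id.startswith("walker_r2"):
        return "walker_row2"
    try:
        return layout.object_by_id(target_id).kind
    except KeyError:
        return "other"


def gaze_allocation(
    t: np.ndarray,
    attention_labels: np.ndarray,
    segments: list[tuple[str, float, float]] | list[TrialPhase],
) -> pd.DataFrame:
    """Per-segment proportions of the four attention labels.

    ``segments`` may be TrialPhase objects or (label, t_start, t_end)
    tuples (e.g. mini-phases).  Proportions sum to 1 in every non-empty
    segment; empty segments are omitted.
    """
    t = np.asarray(t, dtype=float)
    labels = np.asarray(attention_labels, dtype=object)
    rows = []
    for seg in segments:
        if isinstance(seg, TrialPhase):
            name, a, b = seg.label, seg.t_start, seg.t_end
        else:
            name, a, b = seg[0], seg[-2], seg[-1]
        mask = (t >= a) & (t < b)
        n = int(mask.sum())
        if n == 0:
            continue
        row = {"segment": name, "t_start": a, "t_end": b, "n_frames": n}
        for lbl in ATTENTION_LABELS:
            row[lbl] = float(np.sum(labels[mask] == lbl) / n)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaze transition entropy
# ---------------------------------------------------------------------------


@dataclass
class GteResult:
    window_frames: int
    window_centers: np.ndarray  # frame index of each window centre
    values: np.ndarray  # normalized conditional entropy, NaN where undefined


def _window_gte(states: np.ndarray) -> float:
    """Normalized H(next|current) of one window's state sequence."""
    valid = states >= 0
    s = states[valid]
    if len(s) < 3:
        return np.nan
    src, dst = s[:-1], s[1:]
    observed = np.unique(s)
    k = len(observed)
    if k < 2:
        return np.nan  # one distinct state: no transition structure
    if len(src) < 2:
        return np.nan
    remap = {int(v): i for i, v in enumerate(observed)}
    counts = np.zeros((k, k))
    for a, b in zip(src, dst):
        counts[remap[int(a)], remap[int(b)]] += 1
    row_tot = counts.sum(axis=1)
    p_i = row_tot / row_tot.sum()
    h = 0.0
    for i in range(k):
        if row_tot[i] == 0:
            continue
        p_cond = counts[i] / row_tot[i]
        nz = p_cond > 0
        h -= p_i[i] * float(np.sum(p_cond[nz] * np.log2(p_cond[nz])))
    return h / math.log2(k)


def gte(states: np.ndarray, window: int = 80, stride: int = 1) -> GteResult:
    """Rolling-window gaze transition entropy over a discretized sequence.

    Per window, first-order transition probabilities are estimated among
    the states observed in that window, the conditional Shannon entropy
    H(next | current) is computed and normalized by log2(number of distinct
    observed states) to a 0-1 scale.  Windows with fewer than two distinct
    states (or fewer than two transitions) are undefined (NaN), never 0.
    Negative state values mark missing samples and are skipped.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    states = np.asarray(states, dtype=int)
    n = len(states)
    if n < window:
        return GteResult(window, np.array([], dtype=int), np.array([]))
    starts = np.arange(0, n - window + 1, stride)
    values = np.array([_window_gte(states[s : s + window]) for s in starts])
    return GteResult(window, starts + window // 2, values)


def gte_by_phase(
    result: GteResult,
    t: np.ndarray,
    phases: list[TrialPhase],
) -> pd.DataFrame:
    """Mean GTE per phase, assigning each window by its centre timestamp."""
    t = np.asarray(t, dtype=float)
    rows = []
    for p in phases:
        centers_t = t[result.window_centers] if len(result.window_centers) else np.array([])
        mask = (centers_t >= p.t_start) & (centers_t < p.t_end)
        vals = result.values[mask]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "phase": p.label,
                "gte_mean": float(np.mean(vals)) if len(vals) else np.nan,
                "n_windows": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# K-coefficient
# ---------------------------------------------------------------------------


@dataclass
class KResult:
    k_values: np.ndarray
    midpoints: np.ndarray
    mu_d: float
    sigma_d: float
    mu_a: float
    sigma_a: float
    degenerate: bool = False

    def phase_means(self, phases: list[TrialPhase]) -> pd.DataFrame:
        rows = []
        for p in phases:
            mask = (self.midpoints >= p.t_start) & (self.midpoints < p.t_end)
            vals = self.k_values[mask]
            rows.append(
                {
                    "phase": p.label,
                    "k_mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "n_events": int(len(vals)),
                }
            )
        return pd.DataFrame(rows)


def k_coefficient(pairs: list[tuple[float, float, float]]) -> KResult:
    """Ambient/focal K for a trial's (fixation, next saccade) event pairs.

    K_i = (d_i - mu_d)/sigma_d - (a_i - mu_a)/sigma_a with the moments taken
    over the trial's own pairs, so the grand mean of K is 0 by construction.
    Positive K marks focal attention (long fixations, small saccades);
    negative K marks ambient scanning.  Fewer than 2 pairs, or zero
    variance in either component, is degenerate: no K values are emitted.
    """
    if len(pairs) < 2:
        return KResult(
            np.array([]), np.array([]), np.nan, np.nan, np.nan, np.nan, degenerate=True
        )
    arr = np.asarray(pairs, dtype=float)
    d, a, mid = arr[:, 0], arr[:, 1], arr[:, 2]
    mu_d, mu_a = float(d.mean()), float(a.mean())
    sigma_d, sigma_a = float(d.std(ddof=0)), float(a.std(ddof=0))
    if sigma_d == 0.0 or sigma_a == 0.0:
        return KResult(
            np.array([]), np.array([]), mu_d, sigma_d, mu_a, sigma_a, degenerate=True
        )
    k = (d - mu_d) / sigma_d - (a - mu_a) / sigma_a
    return KResult(k, mid, mu_d, sigma_d, mu_a, sigma_a)


# ---------------------------------------------------------------------------
# Gap crossing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapCrossing:
    """Where the participant crossed a walker row within the inter-agent gap.

    Distances are along the row's travel axis (x): ``d_rear`` to the
    rear-facing agent (the walker that just passed, showing its back),
    ``d_front`` to the front-facing oncoming walker.  ``gap_fraction`` =
    d_rear / (d_rear + d_front): 0.5 is mid-gap, small values mean passing
    right behind the leading agent.
    """

    row: int
    t_cross: float
    d_rear: float
    d_front: float

    def __post_init__(self) -> None:
        if self.d_rear < 0 or self.d_front < 0:
            raise ValueError("gap distances must be non-negative")

    @property
    def gap_fraction(self) -> float:
        return self.d_rear / (self.d_rear + self.d_front)


def gap_crossing(
    t: np.ndarray,
    head_xz: np.ndarray,
    tracks: list[WalkerTrack],
    layout: SceneLayout,
) -> dict[int, GapCrossing | None]:
    """Gap-crossing geometry for each walker row.

    The crossing instant is the first frame at or past the row's z line;
    the rear walker is the nearest one downstream of the participant along
    the row's travel direction, the front walker the nearest upstream.
    Rows never crossed, or crossed without a straddling walker pair, map to
    None.
    """
    t = np.asarray(t, dtype=float)
    head_xz = np.asarray(head_xz, dtype=float)
    out: dict[int, GapCrossing | None] = {}
    for row, row_z in ((1, layout.row1_z), (2, layout.row2_z)):
        past = head_xz[:, 1] >= row_z
        if not past.any():
            out[row] = None
            continue
        i = int(np.argmax(past))
        t_cross = float(t[i])
        x_p = float(head_xz[i, 0])
        row_tracks = [tr for tr in tracks if tr.row == row]
        if not row_tracks:
            out[row] = None
            continue
        sign = row_tracks[0].facing_sign
        rel = np.array([sign * (tr.x_at(t_cross) - x_p) for tr in row_tracks])
        down = rel[rel > 0]
        up = rel[rel < 0]
        if len(down) == 0 or len(up) == 0:
            out[row] = None
            continue
        out[row] = GapCrossing(
            row=row,
            t_cross=t_cross,
            d_rear=float(down.min()),
            d_front=float(-up.max()),
        )
    return out


# ---------------------------------------------------------------------------
# Path and speed
# ---------------------------------------------------------------------------


def distance_from_midline(
    head_xz: np.ndarray,
    bench_zone: tuple[float, float] = BENCH_ZONE,
) -> float:
    """Mean |x| over frames whose depth lies inside the bench zone."""
    head_xz = np.asarray(head_xz, dtype=float)
    z_lo, z_hi = bench_zone
    mask = (head_xz[:, 1] >= z_lo) & (head_xz[:, 1] <= z_hi)
    if not mask.any():
        return float("nan")
    return float(np.mean(np.abs(head_xz[mask, 0])))


def speed_profile(
    t: np.ndarray,
    head_xz: np.ndarray,
    z_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and interquartile range of horizontal speed per depth (z) bin.

    Frame speeds come from central differences of the horizontal position.
    Empty bins report NaN, not zero.
    """
    t = np.asarray(t, dtype=float)
    head_xz = np.asarray(head_xz, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 frames for a speed profile")
    vx = np.gradient(head_xz[:, 0], t)
    vz = np.gradient(head_xz[:, 1], t)
    speed = np.hypot(vx, vz)
    if z_edges is None:
        z_edges = np.arange(0.0, 6.0 + 0.25, 0.25)
    idx = np.digitize(head_xz[:, 1], z_edges) - 1
    rows = []
    for b in range(len(z_edges) - 1):
        vals = speed[idx == b]
        rows.append(
            {
                "z_lo": float(z_edges[b]),
                "z_hi": float(z_edges[b + 1]),
                "mean_speed": float(np.mean(vals)) if len(vals) else np.nan,
                "q25": float(np.percentile(vals, 25)) if len(vals) else np.nan,
                "q75": float(np.percentile(vals, 75)) if len(vals) else np.nan,
                "n_frames": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaze-movement alignment
# ---------------------------------------------------------------------------


def gaze_movement_alignment(
    t: np.ndarray,
    head_xz: np.ndarray,
    gaze_dirs: np.ndarray,
    speed_floor: float = 0.2,
    smooth_window_s: float = 0.25,
) -> pd.DataFrame:
    """Signed horizontal angle between gaze and movement direction.

    0 deg = gaze along the heading, positive = gaze to the right of the
    heading, negative = left, +/-180 deg = looking backward.  The movement
    direction comes from smoothed finite differences of the horizontal
    head position; frames moving slower than ``speed_floor`` (m/s) are
    flagged stationary but still reported.
    """
    t = np.asarray(t, dtype=float)
    head_xz = np.asarray(head_xz, dtype=float)
    g = np.asarray(gaze_dirs, dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_window_s * fs)))
    kernel = np.ones(w) / w

    def _smooth(v: np.ndarray) -> np.ndarray:
        padded = np.concatenate([np.full(w, v[0]), v, np.full(w, v[-1])])
        return np.convolve(padded, kernel, mode="same")[w:-w]

    xs = _smooth(head_xz[:, 0])
    zs = _smooth(head_xz[:, 1])
    mx = np.gradient(xs, t)
    mz = np.gradient(zs, t)
    speed = np.hypot(mx, mz)
    gx, gz = g[:, 0], g[:, 2]
    angle = np.degrees(np.arctan2(gx * mz - gz * mx, gx * mx + gz * mz))
    # Map -180 to +180: the backward look is reported as +180.
    angle = np.where(np.isclose(angle, -180.0), 180.0, angle)
    return pd.DataFrame(
        {
            "t": t,
            "alignment_deg": angle,
            "speed": speed,
            "stationary": speed < speed_floor,
        }
    )


# ---------------------------------------------------------------------------
# LHIPA
# ---------------------------------------------------------------------------


@dataclass
class LhipaResult:
    value: float
    low_count: int
    high_count: int
    degenerate: bool = False


def _band_levels(fs: float) -> tuple[list[int], int]:
    """(high-band detail levels, low-band level) for a sampling rate.

    Detail level j of a dyadic DWT covers [fs/2^(j+1), fs/2^j] Hz.  The
    high band collects the levels spanning roughly 1.25-5 Hz (pupil
    oscillations attributable to load); the low band sits one octave below
    (~0.6-1.25 Hz), keeping the required decomposition depth shallow
    enough for phase-length windows.
    """
    j_top = max(1, int(round(math.log2(fs / 5.0))))
    j_bot = max(j_top, int(round(math.log2(fs / 1.25))) - 1)
    return list(range(j_top, j_bot + 1)), j_bot + 1


def _modulus_maxima_count(coeffs: np.ndarray, sigma: float) -> int:
    """Count local maxima of |coeffs| surviving the universal threshold.

    ``sigma`` is the measurement-noise scale (estimated once from the
    finest detail level, as in standard wavelet denoising); the threshold
    is sigma * sqrt(2 ln N) so pure-noise maxima are suppressed while
    genuine oscillatory peaks survive.
    """
    c = np.abs(np.asarray(coeffs, dtype=float))
    n = len(c)
    if n < 3:
        return 0
    lam = sigma * math.sqrt(2.0 * math.log(n)) if sigma > 0 else 0.0
    peaks = (c[1:-1] > c[:-2]) & (c[1:-1] >= c[2:]) & (c[1:-1] > lam) & (c[1:-1] > 0)
    return int(np.sum(peaks))


def lhipa(
    pupil_mm: np.ndarray,
    fs: float,
    wavelet: str = "sym16",
    max_gap_s: float = 0.2,
) -> LhipaResult:
    """Low/High Index of Pupillary Activity over one window.

    The pupil series is decomposed with a discrete wavelet transform
    (symlet-16, periodized); modulus maxima of the detail coefficients are
    counted in a low- and a high-frequency band (the high band covers
    roughly 0.6-5 Hz at typical headset rates, the low band sits two
    octaves below) after universal thresholding, and the index is the
    low-band maxima rate divided by the high-band maxima rate.  Higher
    values indicate lower cognitive load.

    NaN gaps up to ``max_gap_s`` are linearly interpolated; longer gaps
    reject the window (ValueError).  A series with no suprathreshold
    maxima in either band is returned flagged degenerate.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    x = np.asarray(pupil_mm, dtype=float).copy()
    nan = ~np.isfinite(x)
    if nan.any():
        # Reject windows with any gap longer than max_gap_s.
        max_run = 0
        run = 0
        for flag in nan:
            run = run + 1 if flag else 0
            max_run = max(max_run, run)
        if max_run / fs > max_gap_s:
            raise ValueError(
                f"pupil gap of {max_run / fs:.3f} s exceeds {max_gap_s} s; window rejected"
            )
        idx = np.arange(len(x))
        x[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    hif_levels, lof = _band_levels(fs)
    # Require at least 3 low-band coefficients; shorter windows cannot
    # support a maxima count in the low band at all.
    min_len = 2**lof * 3
    if len(x) < min_len:
        raise ValueError(
            f"series too short for wavelet depth {lof} (need >= {min_len} samples)"
        )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # depth beyond pywt's heuristic
        # Noise scale from the finest detail level (Donoho-Johnstone MAD
        # estimate): the 20-40 Hz octave carries essentially pure
        # measurement noise at pupil-signal bandwidths.
        c1 = pywt.downcoef("d", x, wavelet, mode="periodization", level=1)
        sigma = float(np.median(np.abs(c1 - np.median(c1)))) / 0.6745
        # The periodized DWT is orthonormal, so white measurement noise has
        # the same scale at every level; coefficients are thresholded raw.
        n_h = 0
        for j in hif_levels:
            c = pywt.downcoef("d", x, wavelet, mode="periodization", level=j)
            n_h += _modulus_maxima_count(c, sigma)
        c_l = pywt.downcoef("d", x, wavelet, mode="periodization", level=lof)
    duration = len(x) / fs
    n_l = _modulus_maxima_count(c_l, sigma)
    if n_h == 0:
        return LhipaResult(float("nan"), n_l, n_h, degenerate=True)
    return LhipaResult((n_l / duration) / (n_h / duration), n_l, n_h)


def lhipa_by_phase(
    t: np.ndarray,
    pupil_mm: np.ndarray,
    phases: list[TrialPhase],
    fs: float,
) -> pd.DataFrame:
    rows = []
    t = np.asarray(t, dtype=float)
    for p in phases:
        mask = (t >= p.t_start) & (t < p.t_end)
        row = {"phase": p.label, "lhipa": np.nan, "degenerate": True}
        try:
            res = lhipa(np.asarray(pupil_mm, dtype=float)[mask], fs)
            row["lhipa"] = res.value
            row["degenerate"] = res.degenerate
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaze density
# ---------------------------------------------------------------------------


def gaze_density_grid(
    points_xz: np.ndarray,
    layout: SceneLayout | None = None,
    bin_size: float = 0.1,
    kernel_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-smoothed 2D (x, z) gaze-density map, normalized to sum 1.

    Returns (density, x_edges, z_edges).  The smoothing kernel standard
    deviation is in metres (0.3 m by default).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    pts = np.asarray(points_xz, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    hw = layout.half_width if layout is not None else 2.5
    depth = layout.room_length_z if layout is not None else 6.0
    x_edges = np.arange(-hw, hw + bin_size, bin_size)
    z_edges = np.arange(0.0, depth + bin_size, bin_size)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, z_edges])
    density = gaussian_filter(hist, sigma=kernel_sd / bin_size, mode="constant")
    total = density.sum()
    if total > 0:
        density = density / total
    return density, x_edges, z_edges
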