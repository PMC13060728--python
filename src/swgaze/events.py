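"""Eye-movement event classification.

Two classifiers operate on angular gaze kinematics:

* an I-VT velocity-threshold classifier on Savitzky-Golay-smoothed angular
  velocity, splitting frames into fixations and saccades (the online
  classifier used during data collection);
* a 4-state Gaussian hidden Markov model on (log angular speed,
  log angular acceleration magnitude) features, distinguishing fixations,
  smooth pursuit, saccades and post-saccadic oscillations.

World-referenced gaze angles are used throughout: the headset's own
orientation stream is unavailable, so eye-in-head decomposition is out of
scope.  Classified frame labels are merged into maximal-run event segments
whose fixation-duration / next-saccade-amplitude pairs feed the ambient-
focal K-coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .trials import TrialPhase

__all__ = [
    "EVENT_TYPES",
    "EventSegment",
    "HmmSpec",
    "sg_smooth_velocity",
    "ivt_classify",
    "hmm_fit_decode",
    "segment_events",
    "event_stats_by_phase",
    "fixation_saccade_pairs",
]

EVENT_TYPES = ("fixation", "pursuit", "saccade", "pso")


@dataclass(frozen=True)
class EventSegment:
    """A maximal run of one eye-movement type.

    ``duration`` is t_end - t_start; ``amplitude`` is the great-circle angle
    (degrees) between the gaze directions at run start and end — the
    saccade amplitude a_i for saccades.
    """

    type: str
    t_start: float
    t_end: float
    amplitude: float
    mean_velocity: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def sg_smooth_velocity(
    angles: np.ndarray,
    window: int = 11,
    order: int = 3,
    fs: float = 80.0,
) -> np.ndarray:
    """Savitzky-Golay derivative estimate of angular speed (deg/s).

    ``angles`` is (n,) or (n, k) unwrapped angle components in degrees; the
    local least-squares polynomial derivative is taken per component and
    combined as a Euclidean magnitude.  Window must be odd and shorter than
    the series; order must be below the window length.
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float).T).T
    n = angles.shape[0]
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window >= n:
        raise ValueError(f"window ({window}) must be shorter than the series ({n})")
    if order >= window:
        raise ValueError("polynomial order must be below the window length")
    deriv = savgol_filter(
        angles, window_length=window, polyorder=order, deriv=1, delta=1.0 / fs, axis=0
    )
    return np.linalg.norm(deriv, axis=1)


def ivt_classify(
    velocity: np.ndarray,
    threshold_deg_s: float = 100.0,
    min_fix_dur_s: float = 0.06,
    fs: float = 80.0,
) -> np.ndarray:
    """Velocity-threshold labels: frames at/above threshold are saccades.

    Fixation runs shorter than ``min_fix_dur_s`` are merged into the
    surrounding saccade, removing jitter-induced splits.
    """
    if threshold_deg_s <= 0:
        raise ValueError("velocity threshold must be positive")
    velocity = np.asarray(velocity, dtype=float)
    labels = np.where(velocity >= threshold_deg_s, "saccade", "fixation").astype(object)
    min_frames = int(round(min_fix_dur_s * fs))
    if min_frames > 1:
        i = 0
        n = len(labels)
        while i < n:
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            if (
                labels[i] == "fixation"
                and (j - i) < min_frames
                and i > 0
                and j < n  # interior run flanked by saccades
            ):
                labels[i:j] = "saccade"
            i = j
    return labels


@dataclass
class HmmSpec:
    """4-state Gaussian HMM specification on (log speed, log |accel|)."""

    n_states: int = 4
    covariance_type: str = "full"
    max_iter: int = 50
    tol: float = 1e-3
    seed: int = 0
    # Initial per-state feature means (log deg/s, log deg/s^2): fixation,
    # pursuit, pso, saccade — refined by EM.
    init_means: tuple[tuple[float, float], ...] = (
        (1.0, 3.0),
        (2.8, 4.5),
        (4.3, 8.0),
        (5.8, 8.5),
    )


def hmm_features(speed: np.ndarray, accel: np.ndarray) -> np.ndarray:
    eps = 1e-3
    return np.column_stack(
        [np.log(np.abs(speed) + eps), np.log(np.abs(accel) + eps)]
    )


def hmm_fit_decode(
    features: np.ndarray,
    spec: HmmSpec | None = None,
) -> tuple[np.ndarray, "object"]:
    """Fit a 4-state Gaussian HMM by EM and decode a most-probable path.

    States are relabeled by their fitted kinematics: lowest mean speed ->
    fixation, highest -> saccade; of the middle two, the higher mean
    acceleration -> post-saccadic oscillation, the other -> smooth pursuit.
    Returns (per-frame labels, fitted model).
    """
    from hmmlearn.hmm import GaussianHMM

    spec = spec or HmmSpec()
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(X) < 100:
        raise ValueError("need at least 100 frames to fit the HMM")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate features: zero variance in every dimension")
    model = GaussianHMM(
        n_components=spec.n_states,
        covariance_type=spec.covariance_type,
        n_iter=spec.max_iter,
        tol=spec.tol,
        random_state=spec.seed,
        init_params="sc",  # means and transitions supplied below
        min_covar=1e-3,
    )
    model.means_ = np.asarray(spec.init_means, dtype=float)
    # Sticky transitions with structural zeros enforcing the saccade->pso
    # prior: the oscillation state is only enterable from a saccade (EM
    # preserves exact zeros).  State order: fixation, pursuit, pso, saccade.
    trans = np.array(
        [
            [0.95, 0.02, 0.0, 0.03],
            [0.02, 0.95, 0.0, 0.03],
            [0.30, 0.25, 0.40, 0.05],
            [0.20, 0.15, 0.30, 0.35],
        ]
    )
    model.transmat_ = trans / trans.sum(axis=1, keepdims=True)
    model.fit(X)
    if not np.all(np.isfinite(model.monitor_.history)):
        raise RuntimeError(
            f"EM diverged (non-finite log-likelihood) at iteration "
            f"{len(model.monitor_.history)}"
        )
    states = model.predict(X)
    # Relabel by fitted kinematics.
    mean_speed = model.means_[:, 0]
    mean_accel = model.means_[:, 1]
    order = np.argsort(mean_speed)
    name_of_state = {int(order[0]): "fixation", int(order[3]): "saccade"}
    mid = [int(order[1]), int(order[2])]
    if mean_accel[mid[0]] >= mean_accel[mid[1]]:
        name_of_state[mid[0]], name_of_state[mid[1]] = "pso", "pursuit"
    else:
        name_of_state[mid[0]], name_of_state[mid[1]] = "pursuit", "pso"
    labels = np.array([name_of_state[int(s)] for s in states], dtype=object)
    return labels, model


def segment_events(
    labels: np.ndarray,
    t: np.ndarray,
    directions: np.ndarray,
) -> list[EventSegment]:
    """Collapse per-frame labels into maximal-run event segments.

    Segments tile the trial span: each run starts at its first frame's
    timestamp and ends at the next run's start (the final run extends one
    frame duration past the last timestamp).
    """
    labels = np.asarray(labels, dtype=object)
    t = np.asarray(t, dtype=float)
    d = np.asarray(directions, dtype=float)
    if not (len(labels) == len(t) == len(d)):
        raise ValueError("labels, timestamps and directions must align 1:1")
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0125
    segments: list[EventSegment] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        t_start = float(t[i])
        # The final run extends one frame duration past the last timestamp,
        # so every frame (including a single trailing one) is covered.
        t_end = float(t[j]) if j < n else float(t[-1]) + dt
        last = min(j - 1, n - 1)
        cosang = float(np.clip(d[i] @ d[last], -1.0, 1.0))
        amplitude = float(np.degrees(np.arccos(cosang)))
        segments.append(
            EventSegment(
                type=str(labels[i]),
                t_start=t_start,
                t_end=t_end,
                amplitude=amplitude,
                mean_velocity=amplitude / (t_end - t_start),
                n_frames=j - i,
            )
        )
        i = j
    return segments


def fixation_saccade_pairs(
    segments: list[EventSegment],
) -> list[tuple[float, float, float]]:
    """(fixation duration d_i, next saccade amplitude a_i, fixation midpoint).

    Only fixations immediately followed by a saccade are paired; fixations
    followed by pursuit or trial end are excluded.
    """
    pairs = []
    for a, b in zip(segments[:-1], segments[1:]):
        if a.type == "fixation" and b.type == "saccade":
            pairs.append((a.duration, b.amplitude, a.midpoint))
    return pairs


def event_stats_by_phase(
    segments: list[EventSegment],
    phases: list[TrialPhase],
) -> pd.DataFrame:
    """Per-phase, per-type event statistics.

    A segment belongs to the phase containing its midpoint.  Returns a tidy
    frame with count, mean/median duration and mean amplitude per
    (phase, event type); empty cells carry count 0 and NaN statistics.
    """
    rows = []
    for seg in segments:
        phase = next(
            (p.label for p in phases if p.contains(seg.midpoint)),
            phases[-1].label if phases and seg.midpoint >= phases[-1].t_end else None,
        )
        if phase is None:
            continue
        rows.append(
            {
                "phase": phase,
                "type": seg.type,
                "duration_s": seg.duration,
                "amplitude_deg": seg.amplitude,
            }
        )
    df = pd.DataFrame(rows, columns=["phase", "type", "duration_s", "amplitude_deg"])
    index = pd.MultiIndex.from_product(
        [[p.label for p in phases], list(EVENT_TYPES)], names=["phase", "type"]
    )
    if df.empty:
        out = pd.DataFrame(index=index)
        out["count"] = 0
        for c in ("mean_duration_s", "median_duration_s", "mean_amplitude_deg"):
            out[c] = np.nan
        return out.reset_index()
    g = df.groupby(["phase", "type"])
    out = pd.DataFrame(
        {
            "count": g.size(),
            "mean_duration_s": g["duration_s"].mean(),
            "median_duration_s": g["duration_s"].median(),
            "mean_amplitude_deg": g["amplitude_deg"].mean(),
        }
    ).reindex(index)
    out["count"] = out["count"].fillna(0).astype(int)
    return out.reset_index()
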