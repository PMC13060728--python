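"""End-to-end orchestration: simulate -> reconstruct -> classify -> metrics.

`run_simulate` writes one trial-log directory per designed trial plus a
manifest; `run_analyze` runs the full analysis chain over a log directory,
isolating failures per trial; `run_report` condenses the metric tables into
a summary document and basic plots.  Every run writes its resolved
configuration next to its outputs, and (config, seed) fully determines
every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import geometry as geo
from . import metrics as mx
from . import trials as tr
from .io import TrialLogParseError, read_trial_log, write_trial_log
from .scene import TrialCondition, build_default_scene, enumerate_conditions, generate_session_design
from .simulate import (
    FRAME_RATE_HZ,
    GazeEventParams,
    ParticipantPolicy,
    PupilParams,
    TrialLog,
    simulate_trial,
)

__all__ = ["PipelineConfig", "run_simulate", "run_analyze", "run_report", "analyze_trial"]

log = logging.getLogger("swgaze")


@dataclass
class PipelineConfig:
    experiment: int = 1
    reps: int = 7
    seed: int = 42
    participant_id: str = "P00"
    scene_overrides: dict = field(default_factory=dict)
    policy: ParticipantPolicy = field(default_factory=ParticipantPolicy)
    gaze: GazeEventParams = field(default_factory=GazeEventParams)
    pupil: PupilParams = field(default_factory=PupilParams)
    with_gaze: bool = True
    # classification: a short derivative window keeps 3-4-frame saccades
    # from bleeding into their neighbours at 80 Hz
    sg_window: int = 5
    sg_order: int = 2
    ivt_threshold_deg_s: float = 100.0
    hmm_max_iter: int = 50
    # metrics
    grid_bins: tuple[int, int, int] = (6, 12, 3)
    gte_window: int = 80
    bench_zone: tuple[float, float] = (2.0, 4.1)
    snap_radius: float = 0.1
    fs: float = FRAME_RATE_HZ
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_bins"] = list(self.grid_bins)
        d["bench_zone"] = list(self.bench_zone)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("policy", ParticipantPolicy), ("gaze", GazeEventParams), ("pupil", PupilParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "grid_bins" in d:
            d["grid_bins"] = tuple(d["grid_bins"])
        if "bench_zone" in d:
            d["bench_zone"] = tuple(d["bench_zone"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Simulate one full session and write trial logs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = build_default_scene(config.scene_overrides)
    conditions = enumerate_conditions(config.experiment)
    design = generate_session_design(
        conditions, config.reps, config.seed, config.participant_id
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(len(design.ordered_trials))
    manifest = {"participant_id": design.participant_id, "seed": config.seed, "trials": []}
    for i, condition in enumerate(design.ordered_trials):
        trial_id = f"trial_{i:03d}"
        trial_seed = int(seeds[i] % (2**31))
        tlog = simulate_trial(
            layout,
            condition,
            seed=trial_seed,
            policy=config.policy,
            gaze_params=config.gaze,
            pupil_params=config.pupil,
            fs=config.fs,
            trial_id=trial_id,
            with_gaze=config.with_gaze,
        )
        write_trial_log(tlog, out / trial_id)
        manifest["trials"].append(
            {"trial_id": trial_id, "seed": trial_seed, "condition": asdict(condition)}
        )
        log.info("simulated %s (%s)", trial_id, condition.gate_side)
    _atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=1))
    config.write_yaml(out / "config.yaml")
    return out


def attribute_frames(tlog: TrialLog, snap_radius: float = 0.1) -> pd.DataFrame:
    """Vergence reconstruction + per-frame object attribution for one trial.

    Returns a frame-aligned table (t, x, y, z, quality, method, target_id,
    cyclopean direction components).
    """
    f = tlog.frames
    t = f["t"].to_numpy()
    n = len(t)
    lo = f[["eyeL_ox", "eyeL_oy", "eyeL_oz"]].to_numpy()
    ld = f[["eyeL_dx", "eyeL_dy", "eyeL_dz"]].to_numpy()
    ro = f[["eyeR_ox", "eyeR_oy", "eyeR_oz"]].to_numpy()
    rd = f[["eyeR_dx", "eyeR_dy", "eyeR_dz"]].to_numpy()
    points = np.full((n, 3), np.nan)
    quality = np.full(n, np.inf)
    methods = np.empty(n, dtype=object)
    cyc_d = np.empty((n, 3))
    for i in range(n):
        left = geo.Ray(lo[i], ld[i])
        right = geo.Ray(ro[i], rd[i])
        gp = geo.intersect_gaze_rays(left, right, t=float(t[i]))
        if gp.valid:
            points[i] = gp.point
        quality[i] = gp.quality
        methods[i] = gp.method
        cd = ld[i] + rd[i]
        cyc_d[i] = cd / np.linalg.norm(cd)
    cyc_o = (lo + ro) / 2.0

    # Vectorized point-to-collider attribution: distance of every frame's
    # vergence point to every object box (walkers evaluated per frame).
    layout = tlog.layout
    objs = list(layout.object_registry)
    dists = np.full((len(objs) + len(tlog.walker_tracks), n), np.inf)
    vols = np.empty(len(objs) + len(tlog.walker_tracks))
    ids: list[str] = []
    for k, obj in enumerate(objs):
        lo_b, hi_b = obj.bounds()
        d = np.maximum(np.maximum(lo_b - points, 0.0), points - hi_b)
        dists[k] = np.linalg.norm(d, axis=1)
        vols[k] = obj.volume
        ids.append(obj.id)
    from .scene import WALKER_COLLIDER

    half = np.asarray(WALKER_COLLIDER) / 2.0
    for j, trk in enumerate(tlog.walker_tracks):
        k = len(objs) + j
        cx = np.interp(t, trk.t, trk.x)
        centers = np.column_stack([cx, np.full(n, 0.9), np.full(n, trk.z)])
        lo_b, hi_b = centers - half, centers + half
        d = np.maximum(np.maximum(lo_b - points, 0.0), points - hi_b)
        dists[k] = np.linalg.norm(d, axis=1)
        vols[k] = float(np.prod(np.asarray(WALKER_COLLIDER)))
        ids.append(trk.agent_id)
    # Smaller-volume object wins distance ties: stable argmin over objects
    # pre-sorted by volume.
    order = np.argsort(vols, kind="stable")
    dists_sorted = dists[order]
    with np.errstate(invalid="ignore"):
        best = np.nanargmin(dists_sorted, axis=0)
    best_dist = dists_sorted[best, np.arange(n)]
    target = np.empty(n, dtype=object)
    id_arr = [ids[i] for i in order]
    for i in range(n):
        if np.isfinite(best_dist[i]) and best_dist[i] <= snap_radius:
            target[i] = id_arr[best[i]]
        else:
            # Fallback: cast the cyclopean ray against the colliders.
            from .simulate import walker_states_at

            ray = geo.Ray(cyc_o[i], cyc_d[i])
            hit = geo.cast_to_colliders(
                ray, layout, walker_states_at(tlog.walker_tracks, float(t[i]))
            )
            target[i] = hit[0] if hit else "none"
    return pd.DataFrame(
        {
            "t": t,
            "x": points[:, 0],
            "y": points[:, 1],
            "z": points[:, 2],
            "quality": quality,
            "method": methods,
            "target_id": target,
            "cyc_dx": cyc_d[:, 0],
            "cyc_dy": cyc_d[:, 1],
            "cyc_dz": cyc_d[:, 2],
        }
    )


def analyze_trial(tlog: TrialLog, config: PipelineConfig) -> dict:
    """Run the full metric chain on one trial; returns tables keyed by name."""
    f = tlog.frames
    t = f["t"].to_numpy()
    head_xz = tlog.head_xz()
    layout = tlog.layout

    phases = tr.segment_phases(t, head_xz[:, 1], layout, tlog.cue_time)
    reached, arrival = tr.detect_gate_arrival(t, head_xz, layout, tlog.condition)
    duration = arrival if arrival is not None else float(t[-1])
    hooked = (
        tr.detect_hooked(head_xz, layout, tlog.condition, config.bench_zone)
        if head_xz[:, 1].max() >= layout.row2_z
        else False
    )
    outcome = tr.TrialOutcome(
        trial_id=tlog.trial_id,
        duration_s=float(duration),
        success=tr.assess_success(reached, arrival, tlog.condition.deadline_s),
        reached_gate=reached,
        path_class="hooked" if hooked else "direct",
    )
    result: dict = {"outcome": outcome, "phases": phases}
    result["speed_profile"] = mx.speed_profile(t, head_xz)
    result["midline_distance"] = mx.distance_from_midline(head_xz, config.bench_zone)
    result["gap_crossings"] = mx.gap_crossing(t, head_xz, tlog.walker_tracks, layout)

    if "eyeL_ox" not in f.columns:
        return result

    gaze_table = attribute_frames(tlog, config.snap_radius)
    result["gaze_table"] = gaze_table
    cyc_d = gaze_table[["cyc_dx", "cyc_dy", "cyc_dz"]].to_numpy()

    # Attention allocation over phases and mini-phases.
    amap = mx.default_attention_map()
    phase_idx = tr.frame_phase_indices(t, head_xz[:, 1], layout, tlog.cue_time)
    kinds = [mx.kind_of_target(tid, layout) for tid in gaze_table["target_id"]]
    att = np.array(
        [
            mx.label_attention(k, tr.PHASE_LABELS[pi], amap)
            for k, pi in zip(kinds, phase_idx)
        ],
        dtype=object,
    )
    result["attention_labels"] = att
    result["allocation_phases"] = mx.gaze_allocation(t, att, phases)
    try:
        result["allocation_mini"] = mx.gaze_allocation(t, att, tr.mini_phases(phases))
    except ValueError:
        result["allocation_mini"] = None

    # Event classification on world-referenced angular kinematics.
    angles, speed, accel = geo.angular_kinematics(t, cyc_d)
    sg_speed = ev.sg_smooth_velocity(angles, config.sg_window, config.sg_order, config.fs)
    sg_accel = np.gradient(sg_speed, t)
    labels, model = ev.hmm_fit_decode(
        ev.hmm_features(sg_speed, sg_accel),
        ev.HmmSpec(max_iter=config.hmm_max_iter, seed=config.seed),
    )
    segments = ev.segment_events(labels, t, cyc_d)
    result["segments"] = segments
    result["event_stats"] = ev.event_stats_by_phase(segments, phases)
    result["ivt_labels"] = ev.ivt_classify(sg_speed, config.ivt_threshold_deg_s, fs=config.fs)

    kres = mx.k_coefficient(ev.fixation_saccade_pairs(segments))
    result["k"] = kres
    result["k_by_phase"] = kres.phase_means(phases) if not kres.degenerate else None

    grid = geo.GridSpec.for_layout(layout, config.grid_bins)
    pts = gaze_table[["x", "y", "z"]].to_numpy()
    states = geo.discretize_gaze(pts, grid)
    gres = mx.gte(states, config.gte_window)
    result["gte"] = gres
    result["gte_by_phase"] = mx.gte_by_phase(gres, t, phases)

    result["alignment"] = mx.gaze_movement_alignment(t, head_xz, cyc_d)
    if "pupil_mm" in f.columns:
        result["lhipa_by_phase"] = mx.lhipa_by_phase(
            t, f["pupil_mm"].to_numpy(), phases, config.fs
        )
    return result


def _metrics_rows(trial_id: str, condition: TrialCondition, res: dict) -> list[dict]:
    rows = []

    def add(phase: str, metric: str, value) -> None:
        rows.append(
            {
                "trial_id": trial_id,
                "gate_side": condition.gate_side,
                "deadline_s": condition.deadline_s,
                "sitter_position": condition.sitter_position,
                "phase": phase,
                "metric": metric,
                "value": value,
            }
        )

    add("trial", "duration_s", res["outcome"].duration_s)
    add("trial", "success", float(res["outcome"].success))
    add("trial", "hooked", float(res["outcome"].path_class == "hooked"))
    add("trial", "midline_distance_m", res["midline_distance"])
    for row, gc in res["gap_crossings"].items():
        if gc is not None:
            add("trial", f"gap_fraction_row{row}", gc.gap_fraction)
            add("trial", f"gap_d_rear_row{row}", gc.d_rear)
            add("trial", f"gap_d_front_row{row}", gc.d_front)
    for tbl, metric in (("gte_by_phase", "gte_mean"), ("k_by_phase", "k_mean")):
        df = res.get(tbl)
        if df is not None:
            for _, r in df.iterrows():
                add(r["phase"], metric, r[metric])
    if res.get("lhipa_by_phase") is not None:
        for _, r in res["lhipa_by_phase"].iterrows():
            add(r["phase"], "lhipa", r["lhipa"])
    alloc = res.get("allocation_phases")
    if alloc is not None:
        for _, r in alloc.iterrows():
            for lbl in mx.ATTENTION_LABELS:
                add(r["segment"], f"alloc_{lbl}", r[lbl])
    return rows


def run_analyze(log_dir: str | Path, config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Analyze every trial log in a directory; write tidy metric tables."""
    log_dir = Path(log_dir)
    out = Path(out_dir) if out_dir is not None else log_dir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    trial_dirs = sorted(p for p in log_dir.iterdir() if (p / "header.json").exists())
    if not trial_dirs:
        raise FileNotFoundError(f"no readable trial logs under {log_dir}")
    metric_rows: list[dict] = []
    event_rows: list[dict] = []
    outcomes: list[tr.TrialOutcome] = []
    errors: list[dict] = []
    for tdir in trial_dirs:
        try:
            tlog = read_trial_log(tdir)
            res = analyze_trial(tlog, config)
        except (TrialLogParseError, ValueError, RuntimeError) as exc:
            errors.append({"trial": tdir.name, "error": str(exc)})
            log.warning("skipping %s: %s", tdir.name, exc)
            continue
        outcomes.append(res["outcome"])
        metric_rows.extend(_metrics_rows(tlog.trial_id, tlog.condition, res))
        for seg in res.get("segments", []):
            event_rows.append(
                {
                    "trial_id": tlog.trial_id,
                    "type": seg.type,
                    "t_start": seg.t_start,
                    "t_end": seg.t_end,
                    "duration_s": seg.duration,
                    "amplitude_deg": seg.amplitude,
                }
            )
    stage1, stage2, ledger = tr.filter_trials(outcomes)
    kept_ids = {o.trial_id for o in stage2}
    metrics_df = pd.DataFrame(metric_rows)
    if not metrics_df.empty:
        metrics_df["kept_for_gaze"] = metrics_df["trial_id"].isin(kept_ids)
    outcome_df = pd.DataFrame([dataclasses.asdict(o) for o in outcomes])
    tmp = out / "metrics.csv.tmp"
    metrics_df.to_csv(tmp, index=False)
    tmp.replace(out / "metrics.csv")
    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    outcome_df.to_csv(out / "outcomes.csv", index=False)
    _atomic_write_text(out / "exclusions.json", json.dumps(ledger.as_dict(), indent=1))
    _atomic_write_text(out / "errors.json", json.dumps(errors, indent=1))
    config.write_yaml(out / "config.yaml")
    return out


def run_report(analysis_dir: str | Path, out_dir: str | Path | None = None, plots: bool = True) -> Path:
    """Summarize an analysis directory into summary.json (+ optional plots)."""
    analysis_dir = Path(analysis_dir)
    out = Path(out_dir) if out_dir is not None else analysis_dir
    out.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(analysis_dir / "metrics.csv")
    outcomes = pd.read_csv(analysis_dir / "outcomes.csv")
    summary: dict = {}
    if outcomes.empty:
        summary["note"] = "no data"
    else:
        summary["n_trials"] = int(len(outcomes))
        summary["success_rate"] = float(outcomes["success"].mean())
        summary["mean_duration_s"] = float(outcomes["duration_s"].mean())
        summary["hooked_fraction"] = float((outcomes["path_class"] == "hooked").mean())
        by_phase = {}
        if not metrics.empty:
            for metric in ("gte_mean", "k_mean", "lhipa"):
                sub = metrics[metrics["metric"] == metric]
                if not sub.empty:
                    by_phase[metric] = (
                        sub.groupby("phase")["value"].mean().dropna().to_dict()
                    )
            alloc = metrics[metrics["metric"].str.startswith("alloc_")]
            if not alloc.empty:
                by_phase["allocation"] = {
                    phase: grp.groupby("metric")["value"].mean().to_dict()
                    for phase, grp in alloc.groupby("phase")
                }
        summary["by_phase"] = by_phase
    _atomic_write_text(out / "summary.json", json.dumps(summary, indent=1, sort_keys=True))
    if plots and not metrics.empty:
        _write_plots(metrics, outcomes, out)
    return out


def _write_plots(metrics: pd.DataFrame, outcomes: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, fname in (
        ("gte_mean", "gte_by_phase.png"),
        ("k_mean", "k_by_phase.png"),
        ("lhipa", "lhipa_by_phase.png"),
    ):
        sub = metrics[metrics["metric"] == metric]
        if sub.empty:
            continue
        means = sub.groupby("phase")["value"].mean().reindex(tr.PHASE_LABELS).dropna()
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(range(len(means)), means.values)
        ax.set_xticks(range(len(means)))
        ax.set_xticklabels(means.index, rotation=30, ha="right", fontsize=7)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=100)
        plt.close(fig)
    gap = metrics[metrics["metric"].str.startswith("gap_fraction")]
    if not gap.empty:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.hist(gap["value"].dropna(), bins=20, range=(0, 1))
        ax.set_xlabel("gap fraction (rear / total)")
        fig.tight_layout()
        fig.savefig(out / "gap_fractions.png", dpi=100)
        plt.close(fig)
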