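"""On-disk trial-log format: one directory per trial.

* ``header.json`` — schema version, condition, full scene layout, seed,
  cue time, and the synthetic ground-truth block (absent in real-data mode).
* ``frames.csv`` — the ~80 Hz frame table (t, head_x/y/z, eyeL_ox..dz,
  eyeR_ox..dz, pupil_mm, valid, and truth columns event_label/target_id
  when present).
* ``walkers.csv`` — long-format walker track table (agent_id, row,
  direction, z, speed_mps, t, x).

Floats are written at full repr precision, so a write/read round trip
agrees to machine precision (well inside the 1e-9 contract).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scene import SceneLayout, TrialCondition
from .simulate import TrialLog, WalkerTrack

__all__ = ["write_trial_log", "read_trial_log", "TrialLogParseError"]

SCHEMA_VERSION = 1

_FRAME_COLUMNS = ["t", "head_x", "head_y", "head_z"]
_EYE_COLUMNS = [
    f"{eye}_{p}{ax}" for eye in ("eyeL", "eyeR") for p in ("o", "d") for ax in "xyz"
]


class TrialLogParseError(ValueError):
    """A trial log on disk is malformed or has an incompatible schema."""


def write_trial_log(log: TrialLog, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": log.trial_id,
        "seed": log.seed,
        "cue_time": log.cue_time,
        "condition": asdict(log.condition),
        "layout": log.layout.to_dict(),
        "truth": log.truth,
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    log.frames.to_csv(path / "frames.csv", index=False)
    rows = []
    for tr in log.walker_tracks:
        rows.append(
            pd.DataFrame(
                {
                    "agent_id": tr.agent_id,
                    "row": tr.row,
                    "direction": tr.direction,
                    "z": tr.z,
                    "speed_mps": tr.speed_mps,
                    "t": tr.t,
                    "x": tr.x,
                }
            )
        )
    walkers = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["agent_id", "row", "direction", "z", "speed_mps", "t", "x"]
    )
    walkers.to_csv(path / "walkers.csv", index=False)
    return path


def read_trial_log(path: str | Path) -> TrialLog:
    path = Path(path)
    header_path = path / "header.json"
    if not header_path.exists():
        raise TrialLogParseError(f"{header_path}: missing header.json")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise TrialLogParseError(f"{header_path}: invalid JSON ({exc})") from exc
    version = header.get("schema_version")
    if version != SCHEMA_VERSION:
        raise TrialLogParseError(
            f"{header_path}: schema version {version!r} "
            f"(this reader supports {SCHEMA_VERSION})"
        )
    condition = TrialCondition(**header["condition"])
    layout = SceneLayout.from_dict(header["layout"])
    frames = _read_frames(path / "frames.csv")
    tracks = _read_walkers(path / "walkers.csv")
    return TrialLog(
        trial_id=header.get("trial_id", path.name),
        condition=condition,
        layout=layout,
        frames=frames,
        walker_tracks=tracks,
        seed=header.get("seed"),
        cue_time=header.get("cue_time", 2.0),
        truth=header.get("truth"),
    )


def _read_frames(csv_path: Path) -> pd.DataFrame:
    if not csv_path.exists():
        raise TrialLogParseError(f"{csv_path}: missing frame table")
    try:
        frames = pd.read_csv(csv_path)
    except Exception as exc:  # malformed CSV
        raise TrialLogParseError(f"{csv_path}: unreadable frame table ({exc})") from exc
    missing = [c for c in _FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise TrialLogParseError(f"{csv_path}: missing column(s) {missing}")
    bad = frames[_FRAME_COLUMNS].isna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise TrialLogParseError(
            f"{csv_path}: non-numeric or missing value first seen at data line {row + 2}"
        )
    if not np.all(np.diff(frames["t"].to_numpy()) > 0):
        raise TrialLogParseError(f"{csv_path}: timestamps not strictly increasing")
    return frames


def _read_walkers(csv_path: Path) -> list[WalkerTrack]:
    if not csv_path.exists():
        raise TrialLogParseError(f"{csv_path}: missing walker table")
    try:
        table = pd.read_csv(csv_path)
    except Exception as exc:
        raise TrialLogParseError(f"{csv_path}: unreadable walker table ({exc})") from exc
    tracks: list[WalkerTrack] = []
    if table.empty:
        return tracks
    for agent_id, grp in table.groupby("agent_id", sort=False):
        tracks.append(
            WalkerTrack(
                agent_id=str(agent_id),
                row=int(grp["row"].iloc[0]),
                direction=str(grp["direction"].iloc[0]),
                t=grp["t"].to_numpy(dtype=float),
                x=grp["x"].to_numpy(dtype=float),
                z=float(grp["z"].iloc[0]),
                speed_mps=float(grp["speed_mps"].iloc[0]),
            )
        )
    return tracks
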