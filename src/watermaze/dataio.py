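"""Tabular I/O for trajectory logs, trial tables, and neuropsychological z-scores.

All spatial quantities use one fixed frame: arena-centred Cartesian metres,
x east, y north; yaw/bearing in degrees, measured counter-clockwise from +y
(north), wrapped to [0, 360).  Files are plain UTF-8 CSV with a header row
and '.' decimal separator.

File schemas
------------
trajectories.csv : trial_id, t_s, x_m, y_m, yaw_deg
trials.csv       : subject_id, group, trial_index, phase, block, target_id,
                   target_x, target_y, start_id, start_x, start_y,
                   start_type, response_x, response_y, response_time_ms,
                   total_time_ms, moved_mountain_id, moved_angle_deg
zscores.csv      : subject_id, domain, test, z
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("young", "old")
PHASES = ("acquisition", "acquisition_probe", "visible", "delayed_probe", "moved_mountain")
START_TYPES = ("same", "different", "moved")
TARGET_IDS = ("T1", "T2", "T3")
ZSCORE_DOMAINS = ("memory", "attention_executive", "language", "visuospatial")

TRIAL_COLUMNS = [
    "subject_id", "group", "trial_index", "phase", "block", "target_id",
    "target_x", "target_y", "start_id", "start_x", "start_y", "start_type",
    "response_x", "response_y", "response_time_ms", "total_time_ms",
    "moved_mountain_id", "moved_angle_deg",
]
TRAJECTORY_COLUMNS = ["trial_id", "t_s", "x_m", "y_m", "yaw_deg"]
ZSCORE_COLUMNS = ["subject_id", "domain", "test", "z"]


class SchemaError(ValueError):
    """A file's header does not match the documented schema."""


class RowError(ValueError):
    """A data row is malformed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class Trajectory:
    """Ordered head-position samples for one trial (~10 Hz).

    ``t`` is seconds since trial start (strictly increasing), ``xy`` an
    (n, 2) array of positions in metres, ``yaw`` headings in degrees in
    [0, 360) or NaN where the rotation stream is missing.
    """

    trial_id: str
    t: np.ndarray
    xy: np.ndarray
    yaw: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        yaw = np.asarray(self.yaw, dtype=float)
        if len(t) != len(xy) or len(t) != len(yaw):
            raise ValueError("t, xy, yaw must have equal length")
        if len(t) and t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "yaw", yaw)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_yaw(self) -> bool:
        return len(self.yaw) > 0 and not np.any(np.isnan(self.yaw))


@dataclass(frozen=True)
class TrialRecord:
    """Metadata and response for a single trial of one subject."""

    subject_id: str
    group: str
    trial_index: int          # 1-based within subject
    phase: str
    block: int
    target_id: str
    target_pos: tuple[float, float]
    start_id: int             # 1..8
    start_pos: tuple[float, float]
    start_type: str
    response_pos: Optional[tuple[float, float]] = None
    response_time_ms: Optional[float] = None
    total_time_ms: Optional[float] = None
    mountain_move: Optional[tuple[str, float]] = None  # (mountain id, signed deg)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.start_type not in START_TYPES:
            raise ValueError(f"unknown start_type {self.start_type!r}")
        if (self.phase == "moved_mountain") != (self.mountain_move is not None):
            raise ValueError("mountain_move must be present iff phase is moved_mountain")
        if (self.start_type == "moved") != (self.phase == "moved_mountain"):
            raise ValueError("start_type 'moved' must coincide with phase moved_mountain")

    @property
    def trial_id(self) -> str:
        """Composite key linking this record to its trajectory."""
        return f"{self.subject_id}:{self.trial_index}"


@dataclass
class Dataset:
    """A full experiment: subjects, trial records, and trajectories keyed by trial_id."""

    subjects: list[tuple[str, str]]
    trials: list[TrialRecord]
    trajectories: dict[str, Trajectory] = field(default_factory=dict)


def _require_columns(df: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_trial_table(path) -> list[TrialRecord]:
    """Parse trials.csv into validated :class:`TrialRecord` rows."""
    df = pd.read_csv(path, dtype={"subject_id": str, "moved_mountain_id": str})
    _require_columns(df, TRIAL_COLUMNS, "trial table")
    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            mm_id = row.moved_mountain_id
            mm_id = None if (mm_id is None or (isinstance(mm_id, float) and math.isnan(mm_id))) else str(mm_id)
            mm_angle = _opt_float(row.moved_angle_deg)
            move = (mm_id, mm_angle) if mm_id is not None else None
            rx, ry = _opt_float(row.response_x), _opt_float(row.response_y)
            rec = TrialRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                trial_index=int(row.trial_index),
                phase=str(row.phase),
                block=int(row.block),
                target_id=str(row.target_id),
                target_pos=(float(row.target_x), float(row.target_y)),
                start_id=int(row.start_id),
                start_pos=(float(row.start_x), float(row.start_y)),
                start_type=str(row.start_type),
                response_pos=None if rx is None or ry is None else (rx, ry),
                response_time_ms=_opt_float(row.response_time_ms),
                total_time_ms=_opt_float(row.total_time_ms),
                mountain_move=move,
            )
        except (ValueError, TypeError) as exc:
            raise RowError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_trial_table(records: Iterable[TrialRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "group": r.group,
            "trial_index": r.trial_index, "phase": r.phase, "block": r.block,
            "target_id": r.target_id,
            "target_x": r.target_pos[0], "target_y": r.target_pos[1],
            "start_id": r.start_id,
            "start_x": r.start_pos[0], "start_y": r.start_pos[1],
            "start_type": r.start_type,
            "response_x": None if r.response_pos is None else r.response_pos[0],
            "response_y": None if r.response_pos is None else r.response_pos[1],
            "response_time_ms": r.response_time_ms,
            "total_time_ms": r.total_time_ms,
            "moved_mountain_id": None if r.mountain_move is None else r.mountain_move[0],
            "moved_angle_deg": None if r.mountain_move is None else r.mountain_move[1],
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_trajectories(path) -> dict[str, Trajectory]:
    """Parse trajectories.csv into per-trial :class:`Trajectory` objects.

    Rows are sorted by (trial_id, t); duplicate timestamps within a trial are
    collapsed keeping the first occurrence, so output timestamps are strictly
    increasing.
    """
    df = pd.read_csv(path, dtype={"trial_id": str})
    _require_columns(df, TRAJECTORY_COLUMNS, "trajectory table")
    for col in ("t_s", "x_m", "y_m"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise RowError(int(bad.idxmax()) + 2, f"non-numeric value in column {col}")
        df[col] = pd.to_numeric(df[col])
    df["yaw_deg"] = pd.to_numeric(df["yaw_deg"], errors="coerce")
    df = df.sort_values(["trial_id", "t_s"], kind="mergesort")
    df = df.drop_duplicates(subset=["trial_id", "t_s"], keep="first")
    out: dict[str, Trajectory] = {}
    for trial_id, grp in df.groupby("trial_id", sort=False):
        out[str(trial_id)] = Trajectory(
            trial_id=str(trial_id),
            t=grp["t_s"].to_numpy(),
            xy=grp[["x_m", "y_m"]].to_numpy(),
            yaw=grp["yaw_deg"].to_numpy(),
        )
    return out


def write_trajectories(trajectories: Mapping[str, Trajectory], path) -> None:
    frames = []
    for trial_id in trajectories:
        tr = trajectories[trial_id]
        frames.append(pd.DataFrame({
            "trial_id": trial_id, "t_s": tr.t,
            "x_m": tr.xy[:, 0], "y_m": tr.xy[:, 1], "yaw_deg": tr.yaw,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=TRAJECTORY_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def read_zscore_table(path) -> pd.DataFrame:
    """Read zscores.csv (long format: subject_id, domain, test, z)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "domain": str, "test": str})
    _require_columns(df, ZSCORE_COLUMNS, "z-score table")
    bad = ~df["domain"].isin(ZSCORE_DOMAINS)
    if bad.any():
        raise RowError(int(bad.idxmax()) + 2, f"unknown domain {df['domain'][bad].iloc[0]!r}")
    df["z"] = pd.to_numeric(df["z"])
    return df


def write_zscore_table(df: pd.DataFrame, path) -> None:
    df[ZSCORE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def validate_dataset(ds: Dataset) -> list[str]:
    """Check dataset-level invariants; returns human-readable findings (empty = valid)."""
    findings: list[str] = []
    known = {sid for sid, _ in ds.subjects}
    seen: set[tuple[str, int]] = set()
    for rec in ds.trials:
        if rec.subject_id not in known:
            findings.append(f"trial {rec.trial_id}: unknown subject {rec.subject_id!r}")
        key = (rec.subject_id, rec.trial_index)
        if key in seen:
            findings.append(f"trial {rec.trial_id}: duplicate trial_index for subject")
        seen.add(key)
        if rec.phase != "visible" and rec.response_pos is None:
            findings.append(f"trial {rec.trial_id}: non-visible trial lacks response_pos")
    for trial_id, traj in ds.trajectories.items():
        if len(traj) > 1 and not np.all(np.diff(traj.t) > 0):
            findings.append(f"trajectory {trial_id}: timestamps not strictly increasing")
    ids = {r.trial_id for r in ds.trials}
    for trial_id in ds.trajectories:
        if trial_id not in ids:
            findings.append(f"trajectory {trial_id}: no matching trial record")
    return findings
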