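"""Per-trial navigation precision metrics and condition summaries.

Distance error is the Euclidean (bird-flight) distance between the response
and the target.  Path length sums distances between consecutive trajectory
samples; excess path is total minus the optimal straight start→target line.
Rotation totals accumulate unsigned yaw increments (wrapped to (−180, 180])
across the trial, matching cumulative head-rotation totals in the
thousands of degrees; excess rotation subtracts the single initial turn
needed to face the target (a configurable zero baseline is also provided,
since "excess" has no canonical definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .dataio import Dataset, Trajectory, TrialRecord
from .geometry import bearing, wrap_angle


@dataclass(frozen=True)
class TrialMetrics:
    distance_error: float          # m
    total_path: float              # m
    optimal_path: float            # m
    excess_path: float             # m
    total_rotation: Optional[float]    # deg; None when yaw stream missing
    excess_rotation: Optional[float]   # deg; None when yaw stream missing
    response_time: Optional[float]     # ms
    total_time: Optional[float]        # ms


def distance_error(response, target) -> float:
    """Euclidean distance between response and target, metres."""
    return float(np.linalg.norm(np.asarray(response, float) - np.asarray(target, float)))


def path_length(xy) -> float:
    """Sum of distances between consecutive samples of a polyline."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def total_rotation(yaw) -> float:
    """Unsigned cumulative yaw change in degrees (increments wrapped first)."""
    yaw = np.asarray(yaw, dtype=float)
    if len(yaw) < 2:
        return 0.0
    return float(np.sum(np.abs(wrap_angle(np.diff(yaw)))))


def compute_trial_metrics(traj: Trajectory, rec: TrialRecord,
                          rotation_window: str = "trial",
                          rotation_baseline: str = "initial_turn") -> TrialMetrics:
    """Derive all per-trial measures from a trajectory and its trial record.

    ``rotation_window`` is 'trial' (whole trajectory) or 'response'
    (samples up to the response time only).  ``rotation_baseline`` is
    'initial_turn' (optimal rotation = the single turn from the initial
    heading to face the target) or 'zero'.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    response = rec.response_pos
    if response is None:
        # visible trials end at the contact point
        response = tuple(traj.xy[-1])
    derr = distance_error(response, rec.target_pos)
    tot = path_length(traj.xy)
    opt = distance_error(rec.start_pos, rec.target_pos)
    if rotation_window == "response" and rec.response_time_ms is not None:
        mask = traj.t <= rec.response_time_ms / 1000.0 + 1e-9
        yaw = traj.yaw[mask]
    elif rotation_window in ("trial", "response"):
        yaw = traj.yaw
    else:
        raise ValueError(f"unknown rotation window {rotation_window!r}")
    if len(yaw) and not np.any(np.isnan(yaw)):
        rot = total_rotation(yaw)
        if rotation_baseline == "initial_turn":
            to_target = np.asarray(rec.target_pos, float) - np.asarray(rec.start_pos, float)
            opt_rot = (abs(float(wrap_angle(bearing(to_target) - yaw[0])))
                       if np.linalg.norm(to_target) > 0 else 0.0)
        elif rotation_baseline == "zero":
            opt_rot = 0.0
        else:
            raise ValueError(f"unknown rotation baseline {rotation_baseline!r}")
        exc_rot = rot - opt_rot
    else:
        rot = exc_rot = None  # yaw stream missing: flagged, not imputed
    return TrialMetrics(
        distance_error=derr, total_path=tot, optimal_path=opt,
        excess_path=tot - opt, total_rotation=rot, excess_rotation=exc_rot,
        response_time=rec.response_time_ms, total_time=rec.total_time_ms,
    )


def median_containment_radius(errors) -> float:
    """Radius containing half the responses around a centralised target.

    With every target translated to the origin, each response lies at its
    distance error from the centre; the radius enclosing half of all
    responses is the median distance error.
    """
    errors = np.asarray(list(errors), dtype=float)
    if len(errors) == 0:
        raise ValueError("median containment radius of an empty list is undefined")
    return float(np.median(errors))


@dataclass(frozen=True)
class ConditionSummary:
    group: str
    condition: str
    n: int
    mean: float
    sd: float
    median: float
    se: float


def metrics_table(ds: Dataset, rotation_window: str = "trial",
                  rotation_baseline: str = "initial_turn") -> pd.DataFrame:
    """One row per trial: trial-record keys joined with TrialMetrics fields."""
    rows = []
    for rec in ds.trials:
        traj = ds.trajectories.get(rec.trial_id)
        if traj is None or len(traj) == 0:
            if rec.response_pos is None:
                continue
            m = TrialMetrics(distance_error(rec.response_pos, rec.target_pos),
                             np.nan, distance_error(rec.start_pos, rec.target_pos),
                             np.nan, None, None, rec.response_time_ms, rec.total_time_ms)
        else:
            m = compute_trial_metrics(traj, rec, rotation_window, rotation_baseline)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "trial_index": rec.trial_index, "phase": rec.phase,
            "block": rec.block, "target_id": rec.target_id,
            "start_id": rec.start_id, "start_type": rec.start_type,
            "distance_error": m.distance_error, "total_path": m.total_path,
            "optimal_path": m.optimal_path, "excess_path": m.excess_path,
            "total_rotation": np.nan if m.total_rotation is None else m.total_rotation,
            "excess_rotation": np.nan if m.excess_rotation is None else m.excess_rotation,
            "response_time": np.nan if m.response_time is None else m.response_time,
            "total_time": np.nan if m.total_time is None else m.total_time,
        })
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame, value: str = "distance_error",
              condition: str = "start_type") -> list[ConditionSummary]:
    """Cell summaries with the subject as the random unit.

    Trials are first averaged within subject × (group, condition); the cell
    mean/SD/median/SE are then taken across subject means, SE = SD/√n.
    Cells with a single subject report SD = SE = 0 by convention.
    """
    subj = (df.groupby(["group", condition, "subject_id"], sort=True)[value]
              .mean().reset_index())
    out: list[ConditionSummary] = []
    for (group, cond), cell in subj.groupby(["group", condition], sort=True):
        vals = cell[value].to_numpy()
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out.append(ConditionSummary(
            group=str(group), condition=str(cond), n=n,
            mean=float(np.mean(vals)), sd=sd,
            median=float(np.median(vals)),
            se=sd / np.sqrt(n) if n > 1 else 0.0,
        ))
    return out
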