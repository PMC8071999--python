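"""Moved-landmark geometry and the cue-weighting index.

In the moved-mountain probes one of four distal mountains is rotated ±20°
about the target.  A navigator relying purely on the three static mountains
should respond at the target's true location; a navigator beaconing off the
single moved mountain should respond where the target "would be" had it
moved with that mountain.  The per-trial weighting index

    W = EMM / (EMM + E3M)

uses EMM = distance from the response to the implied moved target and
E3M = distance from the response to the static target: W = 1 means complete
reliance on the static (three-mountain) array, W = 0 complete reliance on
the moved mountain, 0.5 equal weighting.

``fit_agent_params`` inverts the simulator's linear-mixture response model
and is the estimator of record for recovering a generative weight: the mean
of per-trial W is NOT an unbiased estimator of the generative w under
response noise (it is pulled toward 0.5), a property documented and tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import bearing, dist, rotate_about, wrap_angle


@dataclass(frozen=True)
class MountainMove:
    """A distal mountain rotated about the target by a signed angle (CCW +)."""

    mountain_id: str
    angle_deg: float
    original_pos: tuple[float, float]
    moved_pos: tuple[float, float]

    def __post_init__(self):
        if self.angle_deg == 0:
            raise ValueError("mountain move angle must be nonzero")


@dataclass(frozen=True)
class WeightingResult:
    emm: float   # response distance to the implied moved target, m
    e3m: float   # response distance to the static target, m
    w: float     # EMM/(EMM+E3M), in [0, 1]


def move_mountain(env, mountain_id: str, target, angle_deg: float) -> MountainMove:
    """Rotate a mountain of ``env`` by ``angle_deg`` about ``target``."""
    if angle_deg == 0:
        raise ValueError("mountain move angle must be nonzero")
    for m in env.mountains:
        if m.id == mountain_id:
            moved = rotate_about(m.pos, target, angle_deg)
            return MountainMove(mountain_id, float(angle_deg),
                                tuple(map(float, m.pos)), tuple(map(float, moved)))
    raise KeyError(f"unknown mountain {mountain_id!r}")


def implied_moved_target(target, move: MountainMove, arena_centre=(0.0, 0.0),
                         mode: str = "bearing_shift") -> np.ndarray:
    """Where the target "would be" had it moved with the rotated mountain.

    Default mode ``bearing_shift``: the mountain's bearing change as seen
    from the arena centre, Δφ, is applied to the target as a rotation about
    the centre.  For a distal mountain rotated about a target near the
    centre, Δφ is within a fraction of a degree of the nominal move angle,
    so the implied target stays at the target's radius inside the arena.

    Mode ``translation`` applies the literal displacement of the mountain to
    the target (preserving the mountain→target vector).  For a 20° rotation
    of a cue hundreds of metres away this places the implied target far
    outside the navigable space; it is provided for comparison only.
    """
    target = np.asarray(target, dtype=float)
    centre = np.asarray(arena_centre, dtype=float)
    if mode == "translation":
        shift = np.asarray(move.moved_pos) - np.asarray(move.original_pos)
        return target + shift
    if mode != "bearing_shift":
        raise ValueError(f"unknown implied-target mode {mode!r}")
    if np.allclose(target, centre):
        return centre.copy()  # fixed point of the rotation
    dphi = wrap_angle(bearing(np.asarray(move.moved_pos) - centre)
                      - bearing(np.asarray(move.original_pos) - centre))
    return rotate_about(target, centre, dphi)


def weighting_index(response, target, implied_target) -> WeightingResult:
    """Per-trial cue-weighting index W = EMM/(EMM+E3M)."""
    if np.allclose(np.asarray(target, float), np.asarray(implied_target, float)):
        raise ValueError("weighting index undefined: target equals implied target")
    emm = dist(response, implied_target)
    e3m = dist(response, target)
    w = emm / (emm + e3m)
    return WeightingResult(emm=emm, e3m=e3m, w=w)


def fit_agent_params(trials: Sequence[tuple]) -> tuple[float, float]:
    """Least-squares recovery of (w, sigma) from moved-trial responses.

    Each element of ``trials`` is ``(response, target, implied_target)``.
    Under the generative model ``response = w·T_static + (1−w)·T_moved + ε``
    with isotropic noise, the least-squares estimate pools over trials:

        ŵ = Σᵢ ⟨rᵢ − Tmᵢ, Tsᵢ − Tmᵢ⟩ / Σᵢ |Tsᵢ − Tmᵢ|² , clipped to [0, 1]

    σ̂ is the RMS residual distance divided by √2 (per-coordinate scale).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 moved trials to fit agent parameters")
    num = 0.0
    den = 0.0
    for response, target, implied in trials:
        d = np.asarray(target, float) - np.asarray(implied, float)
        if np.allclose(d, 0):
            raise ValueError("degenerate geometry: target equals implied target")
        num += float(np.dot(np.asarray(response, float) - np.asarray(implied, float), d))
        den += float(np.dot(d, d))
    w_hat = min(1.0, max(0.0, num / den))
    sq = 0.0
    for response, target, implied in trials:
        pred = w_hat * np.asarray(target, float) + (1 - w_hat) * np.asarray(implied, float)
        sq += float(np.sum((np.asarray(response, float) - pred) ** 2))
    sigma_hat = float(np.sqrt(sq / len(trials)) / np.sqrt(2.0))
    return w_hat, sigma_hat


def trial_weightings(records, env, arena_centre=(0.0, 0.0),
                     mode: str = "bearing_shift") -> list[dict]:
    """Weighting index rows for every moved-mountain trial record.

    Returns one dict per trial with subject/group keys, EMM, E3M, W, and the
    implied target used, suitable for assembly into weighting.csv.
    """
    rows = []
    for rec in records:
        if rec.phase != "moved_mountain" or rec.response_pos is None:
            continue
        mid, angle = rec.mountain_move
        move = move_mountain(env, mid, rec.target_pos, angle)
        implied = implied_moved_target(rec.target_pos, move, arena_centre, mode=mode)
        res = weighting_index(rec.response_pos, rec.target_pos, implied)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "trial_index": rec.trial_index,
            "emm": res.emm, "e3m": res.e3m, "w": res.w,
            "implied_x": float(implied[0]), "implied_y": float(implied[1]),
        })
    return rows
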