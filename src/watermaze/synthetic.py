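"""Synthetic navigator-agent generator.

Emulates the structure of an immersive virtual water-maze session: a ~5×5 m
navigable arena inside a 750 m world with four unevenly spaced distal
mountains, three hidden target objects, eight perimeter start locations,
and a 77-trial schedule — three acquisition blocks of 16 trials plus one
probe each, a block of 8 visible-target trials, 15 delayed probes, and 3
moved-mountain probes.

Agents respond with isotropic Gaussian noise about the target (resampled
until inside the arena), with a group-specific noise scale sigma; on
moved-mountain trials the response centres on the linear cue mixture
``w·T_static + (1−w)·T_moved``, where w is the generative twin of the
cue-weighting index.  Head trajectories are piecewise-linear walks sampled
at ~10 Hz with yaw facing the direction of motion.

What this generator does NOT model: learning curves across blocks,
perceptual or motor error, disorientation, or any trial-to-trial
correlation — responses are conditionally independent given the group
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import cueweight
from .dataio import Dataset, Trajectory, TrialRecord
from .geometry import bearing, dist, unit_from_bearing

# Z-score battery emulated for the older-adult cognitive screen:
# (domain, test, mean, sd) of age-normed z-scores for a cognitively normal
# older cohort; younger adults are drawn from the standard normal.
ZSCORE_BATTERY = (
    ("memory", "CVLT-II LDFR", 0.56, 1.01),
    ("memory", "RCFT LDFR", -0.49, 1.12),
    ("attention_executive", "Trails A", -0.02, 1.03),
    ("attention_executive", "Trails B", -0.08, 0.80),
    ("language", "BNT", 1.33, 1.02),
    ("language", "Animals", 0.06, 1.10),
    ("visuospatial", "WAIS-IV Block Design", 0.73, 0.91),
    ("visuospatial", "RCFT Copy", -0.65, 0.78),
)


@dataclass(frozen=True)
class Mountain:
    id: str
    bearing_deg: float   # CCW from north, seen from the arena centre
    distance_m: float

    @property
    def pos(self) -> np.ndarray:
        return self.distance_m * unit_from_bearing(self.bearing_deg)


@dataclass(frozen=True)
class Environment:
    """Arena geometry: navigable square, distal mountains, targets, starts."""

    arena_halfwidth: float = 2.5
    world_extent: float = 750.0
    mountains: tuple[Mountain, ...] = ()
    targets: tuple[tuple[float, float], ...] = ()
    starts: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if len(self.mountains) != 4:
            raise ValueError("environment requires exactly 4 distal mountains")
        if len(self.targets) != 3:
            raise ValueError("environment requires exactly 3 targets")
        if len(self.starts) != 8:
            raise ValueError("environment requires exactly 8 start locations")
        for m in self.mountains:
            if m.distance_m < 100.0:
                raise ValueError(f"mountain {m.id} is not distal (< 100 m from centre)")
        h = self.arena_halfwidth
        for t in self.targets:
            if not (abs(t[0]) < h and abs(t[1]) < h):
                raise ValueError(f"target {t} outside the navigable square")

    def target_pos(self, target_id: str) -> tuple[float, float]:
        return self.targets[int(target_id[1]) - 1]

    def start_pos(self, start_id: int) -> tuple[float, float]:
        return self.starts[start_id - 1]

    def contains(self, p) -> bool:
        h = self.arena_halfwidth
        return bool(abs(p[0]) <= h and abs(p[1]) <= h)


def _square_perimeter_point(bearing_deg: float, halfwidth: float) -> tuple[float, float]:
    """Intersection of the ray from the centre at a bearing with the square edge."""
    u = unit_from_bearing(bearing_deg)
    scale = halfwidth / max(abs(u[0]), abs(u[1]))
    return (float(u[0] * scale), float(u[1] * scale))


# Default pedestal locations: three well-separated points ~1.8 m from centre.
DEFAULT_TARGETS = ((1.30, 1.25), (-1.60, 0.85), (0.40, -1.80))


def build_environment(seed: int = 0, *, arena_halfwidth: float = 2.5,
                      world_extent: float = 750.0,
                      mountains: Optional[Sequence[Mountain]] = None,
                      targets: Optional[Sequence[tuple[float, float]]] = None,
                      starts: Optional[Sequence[tuple[float, float]]] = None) -> Environment:
    """Deterministically build an environment; unstated geometry is seeded.

    Mountains get four distinct random bearings with a minimum angular gap
    of 30° (unevenly spaced by construction) at distal distances of
    250–400 m.  Starts default to eight equally spaced bearings on the
    arena perimeter.  Explicit overrides must respect the invariants.
    """
    rng = np.random.default_rng(seed)
    if mountains is None:
        while True:
            bearings = np.sort(rng.uniform(0.0, 360.0, size=4))
            gaps = np.diff(np.concatenate([bearings, [bearings[0] + 360.0]]))
            if np.all(gaps >= 30.0) and len(np.unique(np.round(gaps, 6))) == 4:
                break
        distances = rng.uniform(250.0, 400.0, size=4)
        mountains = tuple(Mountain(f"M{i+1}", float(b), float(d))
                          for i, (b, d) in enumerate(zip(bearings, distances)))
    if targets is None:
        scale = arena_halfwidth / 2.5
        targets = tuple((x * scale, y * scale) for x, y in DEFAULT_TARGETS)
    if starts is None:
        starts = tuple(_square_perimeter_point(b, arena_halfwidth)
                       for b in np.arange(0.0, 360.0, 45.0))
    return Environment(arena_halfwidth=arena_halfwidth, world_extent=world_extent,
                       mountains=tuple(mountains), targets=tuple(targets),
                       starts=tuple(starts))


@dataclass(frozen=True)
class ScheduleEntry:
    phase: str
    block: int
    target_id: str
    start_id: int
    start_type: str
    mountain_move: Optional[tuple[str, float]] = None  # (mountain id, signed deg)


@dataclass(frozen=True)
class ScheduleConfig:
    """Trial counts; the defaults reproduce the 77-trial session design."""

    n_acq_blocks: int = 3
    acq_trials_per_block: int = 16
    probes_per_block: int = 1
    n_visible: int = 8
    n_delayed: int = 15
    n_moved: int = 3
    moved_angle_deg: float = 20.0
    # delayed-block positions (1-based within the block) forced to repeat an
    # acquisition target–start pairing; with the default schedule these land
    # on overall trial indices 65 and 70.  The matched never-seen positions
    # (trial indices 66, 67) get never-seen pairings reserved first.
    delayed_same_positions: tuple[int, ...] = (6, 11)
    delayed_different_positions: tuple[int, ...] = (7, 8)


# start ids used during the three acquisition blocks (4 per block) and the
# novel start used by each block's closing probe trial
_ACQ_STARTS = ((1, 3, 5, 7), (2, 4, 6, 8), (1, 4, 5, 8))
_PROBE_STARTS = (2, 3, 6)


def build_schedule(env: Environment, config: ScheduleConfig = ScheduleConfig(),
                   seed: int = 0) -> list[ScheduleEntry]:
    """Deterministic trial schedule; the seed only picks moved-mountain cues.

    ``start_type`` is assigned by a first-seen rule on (target, start)
    pairings: the first exposure to a pairing is 'different', repeats are
    'same', and moved-mountain trials are 'moved'.
    """
    rng = np.random.default_rng(seed)
    entries: list[ScheduleEntry] = []
    seen: set[tuple[str, int]] = set()

    def add(phase, block, target_id, start_id, move=None):
        if phase == "moved_mountain":
            st = "moved"
        else:
            st = "same" if (target_id, start_id) in seen else "different"
        seen.add((target_id, start_id))
        entries.append(ScheduleEntry(phase, block, target_id, start_id, st, move))

    targets = [f"T{i+1}" for i in range(3)]
    for b in range(config.n_acq_blocks):
        target = targets[b % 3]
        starts = _ACQ_STARTS[b % len(_ACQ_STARTS)]
        for i in range(config.acq_trials_per_block):
            add("acquisition", b + 1, target, starts[i % 4])
        for _ in range(config.probes_per_block):
            add("acquisition_probe", b + 1, target, _PROBE_STARTS[b % len(_PROBE_STARTS)])
    vis_block = config.n_acq_blocks + 1
    for i in range(config.n_visible):
        add("visible", vis_block, targets[i % 3], (i % 8) + 1)
    # delayed probes: targets in sequential order; novel pairings where
    # available, repeated acquisition pairings at the forced 'same' positions
    delayed_block = vis_block + 1
    novel_starts = {t: [s for s in range(1, 9) if (t, s) not in seen] for t in targets}
    same_starts = {t: [s for s in range(1, 9) if (t, s) in seen] for t in targets}
    # reserve never-seen pairings for the matched 'different' positions first
    reserved: dict[int, int] = {}
    for pos in config.delayed_different_positions:
        target = targets[(pos - 1) % 3]
        if novel_starts[target]:
            reserved[pos] = novel_starts[target].pop(0)
    for i in range(config.n_delayed):
        pos = i + 1
        target = targets[i % 3]
        if pos in reserved:
            start = reserved[pos]
        elif pos in config.delayed_same_positions and same_starts[target]:
            start = same_starts[target].pop(0)
        elif novel_starts[target]:
            start = novel_starts[target].pop(0)
        else:
            start = same_starts[target].pop(0) if same_starts[target] else (i % 8) + 1
        add("delayed_probe", delayed_block, target, start)
    moved_block = delayed_block + 1
    for i in range(config.n_moved):
        mid = env.mountains[rng.integers(len(env.mountains))].id
        sign = 1.0 if rng.random() < 0.5 else -1.0
        add("moved_mountain", moved_block, targets[i % 3], (i * 3 % 8) + 1,
            move=(mid, sign * config.moved_angle_deg))
    return entries


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of a navigator group.

    sigma — isotropic response-noise scale in metres; w — weight on the
    static-cue-implied target on moved-mountain trials; speed — walking
    speed in m/s; sample_rate — trajectory sampling rate in Hz.
    """

    sigma: float = 0.6
    w: float = 0.45
    speed: float = 0.5
    sample_rate: float = 10.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.speed <= 0:
            raise ValueError("speed must be positive")


# Default group regimes: old adults respond with ~1.5x the spatial noise of
# young adults and weight the moved cue slightly more.
DEFAULT_PARAMS = {
    "young": AgentParams(sigma=0.6, w=0.46),
    "old": AgentParams(sigma=0.9, w=0.40),
}
DEFAULT_N_SUBJECTS = {"young": 12, "old": 15}


def _truncated_gaussian_point(rng, centre, sigma, env, max_tries=1000):
    centre = np.asarray(centre, dtype=float)
    if sigma == 0:
        return centre.copy()
    for _ in range(max_tries):
        p = centre + rng.normal(0.0, sigma, size=2)
        if env.contains(p):
            return p
    return np.clip(centre, -env.arena_halfwidth, env.arena_halfwidth)


def simulate_trajectory(start, response, params: AgentParams, rng,
                        env: Optional[Environment] = None,
                        n_via: Optional[int] = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear walk start → via points → response, sampled at ~10 Hz.

    Via points (0–3, Poisson(1)-capped by default) are uniform in the arena
    and purely cosmetic for path metrics.  Returns (t, xy, yaw) arrays; the
    first sample is the start, the last within 1 cm of the response, and yaw
    faces the direction of motion.
    """
    start = np.asarray(start, dtype=float)
    response = np.asarray(response, dtype=float)
    if n_via is None:
        n_via = int(min(rng.poisson(1.0), 3))
    h = env.arena_halfwidth if env is not None else 2.5
    vias = [rng.uniform(-h, h, size=2) for _ in range(n_via)]
    waypoints = [start] + vias + [response]
    seg = [(a, b) for a, b in zip(waypoints[:-1], waypoints[1:]) if dist(a, b) > 0]
    if not seg:
        yaw0 = 0.0
        return np.array([0.0]), start.reshape(1, 2), np.array([yaw0])
    lengths = np.array([dist(a, b) for a, b in seg])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total_t = cum[-1] / params.speed
    dt = 1.0 / params.sample_rate
    ts = np.arange(0.0, total_t, dt)
    if len(ts) == 0 or total_t - ts[-1] > 1e-9:
        ts = np.append(ts, total_t)  # always land exactly on the endpoint
    pts = np.empty((len(ts), 2))
    yaws = np.empty(len(ts))
    for k, t in enumerate(ts):
        s = min(t * params.speed, cum[-1])
        i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg) - 1)
        a, b = seg[i]
        frac = (s - cum[i]) / lengths[i]
        pts[k] = np.asarray(a) + frac * (np.asarray(b) - np.asarray(a))
        yaws[k] = bearing(np.asarray(b) - np.asarray(a))
    return ts, pts, yaws


def _join_paths(parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]]):
    """Concatenate trajectory legs, offsetting times and dropping duplicate joints."""
    ts, xys, yaws = [parts[0][0]], [parts[0][1]], [parts[0][2]]
    offset = parts[0][0][-1]
    for t, xy, yaw in parts[1:]:
        ts.append(t[1:] + offset if len(t) > 1 else t + offset)
        xys.append(xy[1:] if len(t) > 1 else xy)
        yaws.append(yaw[1:] if len(t) > 1 else yaw)
        offset += t[-1]
    return np.concatenate(ts), np.vstack(xys), np.concatenate(yaws)


def simulate_responses(env: Environment, schedule: Sequence[ScheduleEntry],
                       params_by_group=DEFAULT_PARAMS,
                       n_subjects=DEFAULT_N_SUBJECTS, seed: int = 0,
                       include_trajectories: bool = True) -> Dataset:
    """Simulate a full dataset: responses, times and (optionally) trajectories.

    Responses on hidden-target trials are the target plus isotropic
    Gaussian noise of the group's sigma, resampled until inside the arena.
    On moved-mountain trials the response centres on
    ``w·T_static + (1−w)·T_moved`` with the implied moved target computed by
    the cue-weighting geometry.  Visible trials log the contact point (the
    target) as the response.  Trajectories cover the full trial: start →
    response, then response → revealed target; response_time_ms is the walk
    time to the response point, total_time_ms the full walk time.  With
    ``include_trajectories=False`` no walk is simulated and times are the
    straight-line leg durations at the group's speed.
    """
    ss = np.random.SeedSequence(seed)
    group_seeds = {g: child for g, child in zip(sorted(params_by_group), ss.spawn(len(params_by_group)))}
    subjects: list[tuple[str, str]] = []
    trials: list[TrialRecord] = []
    trajectories: dict[str, Trajectory] = {}
    prefix = {"young": "YA", "old": "OA"}
    for group in sorted(params_by_group):
        params = params_by_group[group]
        n = n_subjects[group]
        for rng in [np.random.default_rng(s) for s in group_seeds[group].spawn(n)]:
            sid = f"{prefix.get(group, group)}{len([s for s in subjects if s[1] == group]) + 1:02d}"
            subjects.append((sid, group))
            for idx, e in enumerate(schedule, start=1):
                target = np.asarray(env.target_pos(e.target_id), dtype=float)
                start = np.asarray(env.start_pos(e.start_id), dtype=float)
                if e.phase == "visible":
                    response = target.copy()
                elif e.phase == "moved_mountain":
                    mid, angle = e.mountain_move
                    move = cueweight.move_mountain(env, mid, target, angle)
                    implied = cueweight.implied_moved_target(target, move)
                    centre = params.w * target + (1 - params.w) * implied
                    response = _truncated_gaussian_point(rng, centre, params.sigma, env)
                else:
                    response = _truncated_gaussian_point(rng, target, params.sigma, env)
                if include_trajectories:
                    leg1 = simulate_trajectory(start, response, params, rng, env)
                    if dist(response, target) > 0:
                        leg2 = simulate_trajectory(response, target, params, rng, env, n_via=0)
                        t, xy, yaw = _join_paths([leg1, leg2])
                    else:
                        t, xy, yaw = leg1
                    response_time_ms = float(leg1[0][-1] * 1000.0)
                    total_time_ms = float(t[-1] * 1000.0)
                else:
                    # fast path: no walk simulation; times from straight-line legs
                    response_time_ms = float(dist(start, response) / params.speed * 1000.0)
                    total_time_ms = response_time_ms + float(
                        dist(response, target) / params.speed * 1000.0)
                rec = TrialRecord(
                    subject_id=sid, group=group, trial_index=idx, phase=e.phase,
                    block=e.block, target_id=e.target_id,
                    target_pos=tuple(map(float, target)), start_id=e.start_id,
                    start_pos=tuple(map(float, start)), start_type=e.start_type,
                    response_pos=tuple(map(float, response)),
                    response_time_ms=response_time_ms, total_time_ms=total_time_ms,
                    mountain_move=e.mountain_move,
                )
                trials.append(rec)
                if include_trajectories:
                    trajectories[rec.trial_id] = Trajectory(rec.trial_id, t, xy, yaw)
    return Dataset(subjects=subjects, trials=trials, trajectories=trajectories)


def simulate_zscores(subjects: Sequence[tuple[str, str]], seed: int = 0):
    """Synthetic neuropsychological z-score table (long format).

    Older adults are drawn per-test from the battery's cohort means/SDs;
    younger adults from the standard normal (the screen targets the older
    cohort; young scores are plumbing).
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for sid, group in subjects:
        for domain, test, mean, sd in ZSCORE_BATTERY:
            z = rng.normal(mean, sd) if group == "old" else rng.normal(0.0, 1.0)
            rows.append({"subject_id": sid, "domain": domain, "test": test, "z": float(z)})
    return pd.DataFrame(rows)
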