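"""Synthetic object-recognition sessions with known exploration ground truth.

A session is built from a bout plan: time windows during which the animal's
nose is parked just outside an object's footprint, facing its centre (or, for
climbing bouts, on top of the object with the paws-on-object flag raised).
Between bouts the animal rests in the arena corner farthest from the
objects, outside every scoring zone. The ground-truth summary applies the
same scoring rules as the behavioral scorer — per-sample counting, the
total-exploration criterion with scoring stop, latency to the first counted
sample, climbing exclusion — directly to the plan, so a noise-free session
round-trips exactly through the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..behavior import (
    ExplorationSummary,
    ObjectSpec,
    ScoringParams,
    Trajectory,
)


@dataclass(frozen=True)
class Bout:
    object_label: str
    start_s: float
    duration_s: float
    climbing: bool = False

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.duration_s <= 0:
            raise ValueError("bout start must be >= 0 and duration > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class TrajectoryConfig:
    """Arena geometry, objects, bout plan, and sampling for one session."""

    objects: list[ObjectSpec]
    bouts: list[Bout] = field(default_factory=list)
    arena_cm: float = 33.0
    session_s: float = 600.0
    sample_rate: float = 25.0
    approach_cm: float = 1.0        # nose distance from footprint boundary
    body_offset_cm: float = 2.0     # body behind the nose, along the approach
    position_noise_cm: float = 0.0  # jitter on nose/body positions
    seed: int = 0

    def __post_init__(self) -> None:
        labels = {o.label for o in self.objects}
        for b in self.bouts:
            if b.object_label not in labels:
                raise ValueError(f"bout references unknown object {b.object_label!r}")
            if b.end_s > self.session_s:
                raise ValueError("bout extends beyond the session")
        for o in self.objects:
            cx, cy = o.center
            if not (
                o.radius <= cx <= self.arena_cm - o.radius
                and o.radius <= cy <= self.arena_cm - o.radius
            ):
                raise ValueError(f"object {o.label!r} is not inside the arena")
        order = sorted(self.bouts, key=lambda b: b.start_s)
        for prev, nxt in zip(order[:-1], order[1:]):
            if nxt.start_s < prev.end_s:
                raise ValueError("bouts overlap in time")
        if self.sample_rate <= 0 or self.session_s <= 0:
            raise ValueError("sample_rate and session_s must be positive")


def default_objects(arena_cm: float = 33.0) -> list[ObjectSpec]:
    """Two objects in opposite arena quadrants, as in a two-object test."""
    return [
        ObjectSpec("A", (arena_cm * 0.3, arena_cm * 0.3), 2.0, role="familiar"),
        ObjectSpec("B", (arena_cm * 0.7, arena_cm * 0.7), 2.0, role="novel"),
    ]


def _rest_point(config: TrajectoryConfig) -> np.ndarray:
    """Arena corner (inset 3 cm) farthest from all object centres."""
    inset = 3.0
    a = config.arena_cm
    corners = np.array(
        [[inset, inset], [inset, a - inset], [a - inset, inset], [a - inset, a - inset]]
    )
    centers = np.array([o.center for o in config.objects])
    dmin = np.min(
        np.linalg.norm(corners[:, None, :] - centers[None, :, :], axis=2), axis=1
    )
    return corners[int(np.argmax(dmin))]


def generate_trajectory(
    config: TrajectoryConfig,
    params: ScoringParams | None = None,
) -> tuple[Trajectory, ExplorationSummary]:
    """Render the bout plan into a sampled trajectory plus its ground truth."""
    params = params or ScoringParams()
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate
    t = np.arange(0.0, config.session_s, dt)
    n = t.size

    obj_by_label = {o.label: o for o in config.objects}
    rest = _rest_point(config)
    nose = np.tile(rest, (n, 1)).astype(float)
    # at rest the heading points into the corner, away from the arena centre
    away = rest - np.array([config.arena_cm / 2, config.arena_cm / 2])
    away = away / np.linalg.norm(away)
    body = nose - away[None, :] * config.body_offset_cm
    climbing = np.zeros(n, dtype=bool)

    bouts = sorted(config.bouts, key=lambda b: b.start_s)
    approach_angles = {id(b): rng.uniform(0, 2 * np.pi) for b in bouts}
    for b in bouts:
        sel = (t >= b.start_s) & (t < b.end_s)
        obj = obj_by_label[b.object_label]
        center = np.asarray(obj.center)
        u = np.array([np.cos(approach_angles[id(b)]), np.sin(approach_angles[id(b)])])
        if b.climbing:
            nose[sel] = center
            body[sel] = center + u * 1.0
            climbing[sel] = True
        else:
            nose[sel] = center + u * (obj.radius + config.approach_cm)
            body[sel] = center + u * (obj.radius + config.approach_cm + config.body_offset_cm)

    if config.position_noise_cm > 0:
        nose = nose + rng.normal(0, config.position_noise_cm, nose.shape)
        body = body + rng.normal(0, config.position_noise_cm, body.shape)

    df = pd.DataFrame(
        {
            "time_s": t,
            "nose_x_cm": nose[:, 0],
            "nose_y_cm": nose[:, 1],
            "body_x_cm": body[:, 0],
            "body_y_cm": body[:, 1],
            "climbing": climbing.astype(int),
        }
    )
    traj = Trajectory(data=df, sample_rate=config.sample_rate)
    truth = _truth_summary(config, t, dt, params)
    return traj, truth


def _truth_summary(
    config: TrajectoryConfig,
    t: np.ndarray,
    dt: float,
    params: ScoringParams,
) -> ExplorationSummary:
    """Apply the scoring rules directly to the bout plan."""
    per_object = {o.label: 0.0 for o in config.objects}
    total = 0.0
    latency: float | None = None
    bouts = sorted(config.bouts, key=lambda b: b.start_s)
    stopped = False
    for ti in t:
        if stopped or ti > params.session_s:
            break
        for b in bouts:
            if b.climbing:
                continue
            if b.start_s <= ti < b.end_s:
                per_object[b.object_label] += dt
                total += dt
                if latency is None:
                    latency = float(ti - t[0])
                if total >= params.criterion_s - 1e-9:
                    stopped = True
                break
    reached = total >= params.criterion_s - 1e-9
    return ExplorationSummary(
        per_object_s=per_object,
        total_s=total,
        latency_s=latency,
        reached_criterion=reached,
        excluded=not reached,
    )


def plan_cohort_bouts(
    objects: list[ObjectSpec],
    novel_label: str,
    novel_bias: float,
    n_bouts: int,
    mean_bout_s: float,
    latency_s: float,
    session_s: float,
    seed: int,
) -> list[Bout]:
    """Bout plan for one simulated animal with a novelty preference.

    Visits alternate between the novel object and the others, but the
    *durations* carry the preference — the novel object receives a
    ``novel_bias`` share of each visit pair's time (2 * mean_bout_s), with
    ~10% log-normal jitter per bout. This emulates the actual phenomenon
    (animals dwell longer at the novel object) and gives each animal a
    novel-time share close to ``novel_bias``. The first bout starts at
    ``latency_s``; successive bouts are separated by rest gaps.
    """
    if not 0 <= novel_bias <= 1:
        raise ValueError("novel_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [o.label for o in objects]
    if novel_label not in labels:
        raise ValueError(f"novel label {novel_label!r} not among objects")
    others = [l for l in labels if l != novel_label]
    bouts: list[Bout] = []
    start = latency_s
    novel_first = bool(rng.uniform() < 0.5)
    for k in range(n_bouts):
        is_novel = (k % 2 == 0) == novel_first
        share = novel_bias if is_novel else 1.0 - novel_bias
        dur = max(0.5, 2.0 * mean_bout_s * share * float(rng.lognormal(0, 0.1)))
        if start + dur > session_s:
            break
        label = novel_label if is_novel else str(rng.choice(others))
        bouts.append(Bout(object_label=label, start_s=float(start), duration_s=float(dur)))
        start += dur + rng.uniform(2.0, 8.0)
    return bouts
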