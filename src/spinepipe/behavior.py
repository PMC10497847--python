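"""Scoring of object-recognition (NOR/NOL) sessions from trajectories.

A sample counts as exploration of an object when the nose is within the
proximity distance of the object's footprint boundary, the nose-heading
vector (nose minus body) points within the heading cone at the object's
centre, and the animal is not climbing the object. Counted time accumulates
sample by sample until the total-exploration criterion (20 s summed over
objects) is reached, after which scoring stops. Animals that do not reach
the criterion within the session are flagged excluded.

Note on the proximity rule: the protocol phrase "at least 2 cm from the
object" is implemented as *within* 2 cm of the footprint boundary — the
standard NOR proximity reading and the only one consistent with requiring
the nose to face the object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = [
    "time_s", "nose_x_cm", "nose_y_cm", "body_x_cm", "body_y_cm", "climbing",
]


@dataclass
class Trajectory:
    """Behavioral time series: nose/body positions (cm) and climbing flag."""

    data: pd.DataFrame
    sample_rate: float

    def __post_init__(self) -> None:
        missing = set(TRAJECTORY_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory missing columns: {sorted(missing)}")
        t = self.data["time_s"].to_numpy()
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        t = self.data["time_s"].to_numpy()
        return float(t[-1] - t[0]) if t.size else 0.0


@dataclass(frozen=True)
class ObjectSpec:
    label: str
    center: tuple[float, float]     # cm
    radius: float                   # footprint radius, cm
    role: Literal["familiar", "novel", "moved"] = "familiar"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("object footprint radius must be positive")


@dataclass
class ScoringParams:
    proximity_cm: float = 2.0
    heading_deg: float = 45.0
    criterion_s: float = 20.0
    session_s: float = 600.0


@dataclass
class ExplorationSummary:
    per_object_s: dict[str, float]
    total_s: float
    latency_s: float | None         # None when nothing was ever counted
    reached_criterion: bool
    excluded: bool

    def __post_init__(self) -> None:
        if self.excluded and self.reached_criterion:
            raise ValueError("excluded implies the criterion was not reached")


def score_exploration(
    traj: Trajectory,
    objects: Sequence[ObjectSpec],
    params: ScoringParams | None = None,
) -> ExplorationSummary:
    """Score a session under the proximity/heading/climbing/criterion rules."""
    params = params or ScoringParams()
    if not objects:
        raise ValueError("at least one object is required")
    labels = [o.label for o in objects]
    if len(set(labels)) != len(labels):
        raise ValueError("object labels must be unique")
    df = traj.data
    t = df["time_s"].to_numpy()
    if t.size < 2 or (t[-1] - t[0]) < 1.0:
        raise ValueError("trajectory shorter than 1 s")

    nose = df[["nose_x_cm", "nose_y_cm"]].to_numpy()
    body = df[["body_x_cm", "body_y_cm"]].to_numpy()
    climbing = df["climbing"].to_numpy().astype(bool)
    heading = nose - body
    heading_norm = np.linalg.norm(heading, axis=1)
    cos_cone = np.cos(np.deg2rad(params.heading_deg))
    dt = 1.0 / traj.sample_rate

    # per-object qualification per sample
    qual = np.zeros((t.size, len(objects)), dtype=bool)
    boundary_dist = np.zeros((t.size, len(objects)))
    for j, obj in enumerate(objects):
        delta = np.asarray(obj.center)[None, :] - nose
        center_dist = np.linalg.norm(delta, axis=1)
        b_dist = np.clip(center_dist - obj.radius, 0.0, None)
        boundary_dist[:, j] = b_dist
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", heading, delta) / (
                heading_norm * center_dist
            )
        facing = np.where(
            (heading_norm > 0) & (center_dist > 0), cosang >= cos_cone, False
        )
        qual[:, j] = (b_dist <= params.proximity_cm) & facing & ~climbing

    per_object = {o.label: 0.0 for o in objects}
    total = 0.0
    latency: float | None = None
    for i in range(t.size):
        if t[i] - t[0] > params.session_s:
            break
        row = qual[i]
        if not row.any():
            continue
        # nearest qualifying object wins
        j = int(np.argmin(np.where(row, boundary_dist[i], np.inf)))
        per_object[objects[j].label] += dt
        total += dt
        if latency is None:
            latency = float(t[i] - t[0])
        if total >= params.criterion_s - 1e-9:
            break

    reached = total >= params.criterion_s - 1e-9
    return ExplorationSummary(
        per_object_s=per_object,
        total_s=total,
        latency_s=latency,
        reached_criterion=reached,
        excluded=not reached,
    )


def object_preference(
    summary: ExplorationSummary, novel_label: str
) -> tuple[float, float]:
    """Split scored seconds into (novel, familiar) for group-level tests."""
    if summary.excluded:
        raise ValueError("summary is excluded from analysis")
    if novel_label not in summary.per_object_s:
        raise KeyError(f"unknown object label {novel_label!r}")
    novel = summary.per_object_s[novel_label]
    familiar = sum(v for k, v in summary.per_object_s.items() if k != novel_label)
    return novel, familiar


def latency_ratio(day14_latency: float, day0_latency: float) -> float:
    """Latency ratio Day 14 / Day 0; values below 1 indicate improvement."""
    if day0_latency is None or day0_latency <= 0:
        raise ZeroDivisionError("Day-0 latency must be positive")
    if day14_latency is None or day14_latency < 0:
        raise ValueError("Day-14 latency must be non-negative")
    return day14_latency / day0_latency


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Sucrose preference in percent: 100 * sucrose / (sucrose + water)."""
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("consumed masses must be non-negative")
    total = sucrose_g + water_g
    if total == 0:
        raise ZeroDivisionError("no fluid consumed: preference undefined")
    return 100.0 * sucrose_g / total


def read_trajectory_csv(path, sample_rate: float | None = None) -> Trajectory:
    """Load a trajectory CSV (columns as written by the synthetic generator)."""
    df = pd.read_csv(path)
    if sample_rate is None:
        t = df["time_s"].to_numpy()
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return Trajectory(data=df, sample_rate=sample_rate)
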