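"""Sampling of synthetic dendritic-spine shape specifications.

Spine shape is summarised by the scale-free length-to-(head-)width ratio
R = L/W. Five morphological classes are mapped onto consecutive ratio bins,
preserving the biological ordering from mature to immature shapes:

    stubby    [0, 1)     short, wide, no clear neck
    mushroom  [1, 2)     bulbous head on a short neck
    thin      [2, 3)     elongated with a small head
    long_thin [3, 4)     long neck, faint head
    filopodia [4, inf)   hair-like protrusion, essentially headless

The 2.0 boundary separates the mature (stubby/mushroom) from the immature
(thin and longer) compartment and is the stratification threshold used in the
group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ..classes import CLASS_BINS, classify_ratio  # noqa: F401  (re-exported)

#: ratio sub-ranges actually sampled per class; narrower than the bins so
#: generated spines stay physically renderable (a ratio near 0 would give a
#: sub-pixel protrusion) and the open filopodia bin is capped
_SAMPLED_RATIO_RANGES: dict[str, tuple[float, float]] = {
    "stubby": (0.60, 1.0),
    "mushroom": (1.0, 2.0),
    "thin": (2.0, 3.0),
    "long_thin": (3.0, 4.0),
    "filopodia": (4.0, 6.0),
}

#: head-width ranges (um) per class; wider heads for mature shapes
_HEAD_WIDTH_RANGES: dict[str, tuple[float, float]] = {
    "stubby": (0.45, 0.80),
    "mushroom": (0.45, 0.75),
    "thin": (0.30, 0.50),
    "long_thin": (0.25, 0.40),
    "filopodia": (0.20, 0.35),
}

#: neck width as a fraction of head width, per class
_NECK_FRACTION_RANGES: dict[str, tuple[float, float]] = {
    "stubby": (0.80, 1.00),
    "mushroom": (0.40, 0.60),
    "thin": (0.45, 0.70),
    "long_thin": (0.50, 0.75),
    "filopodia": (0.60, 0.90),
}


@dataclass
class SpineShapeSpec:
    """Geometric ground truth for one synthetic spine.

    ``length`` is the curvilinear distance from the dendrite surface to the
    spine tip; ``head_width`` the diameter of the head; ``curvature`` the
    constant curvature (1/um) of the spine axis (0 = straight);
    ``attachment`` the arc position (um) along the dendrite core;
    ``orientation`` the absolute emanation angle in radians.
    """

    class_label: str
    length: float
    head_width: float
    neck_width: float
    orientation: float = 0.0
    attachment: float = 0.0
    curvature: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_BINS:
            raise ValueError(f"unknown spine class {self.class_label!r}")
        if self.length <= 0 or self.head_width <= 0 or self.neck_width <= 0:
            raise ValueError("length and widths must be strictly positive")
        if self.neck_width > self.head_width + 1e-12:
            raise ValueError("neck_width must not exceed head_width")
        lo, hi = CLASS_BINS[self.class_label]
        if not (lo <= self.ratio < hi):
            raise ValueError(
                f"ratio {self.ratio:.3f} outside bin [{lo}, {hi}) "
                f"of class {self.class_label!r}"
            )

    @property
    def ratio(self) -> float:
        return self.length / self.head_width


def sample_spine_shapes(
    mixture: Mapping[str, float],
    n: int,
    seed: int,
) -> list[SpineShapeSpec]:
    """Draw ``n`` spine specs from a class mixture, reproducibly per seed.

    Within the chosen class, the ratio is uniform over the class bin, the
    head width uniform over a class-typical range, and the length follows as
    ratio * head_width, so the ratio ground truth is exact by construction.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    unknown = set(mixture) - set(CLASS_BINS)
    if unknown:
        raise ValueError(f"unknown classes in mixture: {sorted(unknown)}")
    labels = [c for c in CLASS_BINS if mixture.get(c, 0.0) > 0]
    weights = np.array([mixture[c] for c in labels], dtype=float)
    if np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    specs: list[SpineShapeSpec] = []
    for _ in range(n):
        label = labels[rng.choice(len(labels), p=weights)]
        r_lo, r_hi = _SAMPLED_RATIO_RANGES[label]
        ratio = float(rng.uniform(r_lo, r_hi))
        w_lo, w_hi = _HEAD_WIDTH_RANGES[label]
        head_width = float(rng.uniform(w_lo, w_hi))
        f_lo, f_hi = _NECK_FRACTION_RANGES[label]
        neck_width = head_width * float(rng.uniform(f_lo, f_hi))
        specs.append(
            SpineShapeSpec(
                class_label=label,
                length=ratio * head_width,
                head_width=head_width,
                neck_width=neck_width,
                orientation=float(rng.uniform(0, 2 * np.pi)),
            )
        )
    return specs
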