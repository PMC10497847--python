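"""Morphological spine classes and their length-to-width ratio bins.

The five classes are ordered from mature to immature shapes; the 2.0 ratio
boundary splits the mature (stubby/mushroom) from the immature (thin,
long_thin, filopodia) compartment used in the stratified statistics.
"""

from __future__ import annotations

import numpy as np

#: ratio bins per class; upper edge of the last bin is open
CLASS_BINS: dict[str, tuple[float, float]] = {
    "stubby": (0.0, 1.0),
    "mushroom": (1.0, 2.0),
    "thin": (2.0, 3.0),
    "long_thin": (3.0, 4.0),
    "filopodia": (4.0, np.inf),
}

#: ratio threshold between the mature and immature compartments
MATURITY_THRESHOLD = 2.0


def classify_ratio(ratio: float) -> str:
    """Map a length-to-width ratio to its morphological class label."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    for label, (lo, hi) in CLASS_BINS.items():
        if lo <= ratio < hi:
            return label
    return "filopodia"
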