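"""Rendering of synthetic DiI-like dendrite images with known ground truth.

A scene is a dendrite tube (constant radius around a polyline core) plus a
set of spines attached to the core. Each spine is a tapered neck (width
interpolating from neck_width at the dendrite surface to head_width at the
head centre) ending in a circular head of diameter head_width; the spine
axis may carry a constant curvature. The binary geometry is blurred with a
Gaussian point-spread function, scaled to an expected photon count, and
corrupted with Poisson photon noise plus additive Gaussian read noise —
a standard widefield/confocal image formation model in 2-D projection.

All geometry is computed analytically from pixel-centre coordinates (pixel
centres at (index + 0.5) * pixel_size, origin top-left), so ground-truth
masks are exact at pixel resolution and the ground-truth length-to-width
ratio is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..morpho import FluorescenceImage
from .spines import SpineShapeSpec


def _as_polyline(path) -> np.ndarray:
    arr = np.asarray(path, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("dendrite_path must be an (N>=2, 2) array of (x, y) um")
    return arr


def polyline_arc_length(poly: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length steps."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    total = arc[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arc, poly[:, 0])
    y = np.interp(s, arc, poly[:, 1])
    return np.column_stack([x, y])


def point_on_polyline(poly: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc position ``s`` along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    s = float(np.clip(s, 0.0, arc[-1]))
    i = int(np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(seg) - 1))
    t = (s - arc[i]) / seg[i] if seg[i] > 0 else 0.0
    pt = poly[i] + t * (poly[i + 1] - poly[i])
    tangent = (poly[i + 1] - poly[i]) / (seg[i] if seg[i] > 0 else 1.0)
    return pt, tangent


@dataclass
class ImageSceneConfig:
    """Configuration of one synthetic dendrite scene.

    Defaults mirror the acquisition geometry emulated here: 1024 x 1024
    pixels at 0.07 um/pixel (63x confocal objective with digital zoom).
    """

    dendrite_path: np.ndarray
    spine_specs: list[SpineShapeSpec] = field(default_factory=list)
    pixel_size: float = 0.07
    image_shape: tuple[int, int] = (1024, 1024)
    dendrite_radius: float = 0.5
    psf_sigma: float = 0.1
    photon_scale: float = 500.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.dendrite_path = _as_polyline(self.dendrite_path)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")
        if self.dendrite_radius <= 0:
            raise ValueError("dendrite_radius must be positive")
        core_len = polyline_arc_length(self.dendrite_path)
        for i, spec in enumerate(self.spine_specs):
            if not (0.0 <= spec.attachment <= core_len):
                raise ValueError(
                    f"spine {i}: attachment {spec.attachment:.2f} um outside "
                    f"core of length {core_len:.2f} um"
                )


@dataclass
class GroundTruth:
    """Exact per-spine geometry and masks for a rendered scene."""

    lengths: np.ndarray          # um, dendrite surface to tip
    head_widths: np.ndarray      # um
    ratios: np.ndarray           # lengths / head_widths, exact
    spine_labels: np.ndarray     # int mask, 0 = background, i+1 = spine i
    base_points: np.ndarray      # (n, 2) um, on the dendrite surface
    tip_points: np.ndarray       # (n, 2) um
    core_polyline: np.ndarray    # (m, 2) um
    core_length: float           # um


def _pixel_centers(shape: tuple[int, int], pixel_size: float):
    rows, cols = shape
    xs = (np.arange(cols) + 0.5) * pixel_size
    ys = (np.arange(rows) + 0.5) * pixel_size
    return np.meshgrid(xs, ys)  # X, Y with image indexing [row, col]


def _dist_to_segments(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline, vectorised per segment."""
    dist = np.full(px.shape, np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.hypot(px - a[0], py - a[1])
        else:
            t = np.clip(((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom, 0.0, 1.0)
            d = np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))
        np.minimum(dist, d, out=dist)
    return dist


def spine_axis(
    base: np.ndarray, orientation: float, length: float, curvature: float,
    step: float,
) -> np.ndarray:
    """Spine axis polyline from the dendrite surface to the tip.

    Constant-curvature arc: the local direction rotates by curvature * s.
    """
    n = max(int(np.ceil(length / step)) + 1, 2)
    s = np.linspace(0.0, length, n)
    ang = orientation + curvature * s
    if abs(curvature) < 1e-12:
        x = base[0] + s * np.cos(orientation)
        y = base[1] + s * np.sin(orientation)
    else:
        # integral of (cos(theta + k s), sin(theta + k s)) ds
        x = base[0] + (np.sin(ang) - np.sin(orientation)) / curvature
        y = base[1] - (np.cos(ang) - np.cos(orientation)) / curvature
    return np.column_stack([x, y])


def _spine_region(
    spec: SpineShapeSpec,
    base: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
    index: int,
) -> tuple[np.ndarray, tuple[slice, slice], np.ndarray]:
    """Boolean crop of the spine region, its slices, and the tip point."""
    L, W = spec.length, spec.head_width
    axis = spine_axis(base, spec.orientation, L, spec.curvature, pixel_size / 4)
    tip = axis[-1]
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(axis, axis=0), axis=1))]
    s_head = max(L - W / 2.0, 0.0)
    # tapered neck half-width up to the head centre, then the head disk
    halfw = np.where(
        arc <= s_head,
        (spec.neck_width + (W - spec.neck_width) * arc / max(s_head, 1e-9)) / 2.0,
        0.0,
    )

    pad = W / 2.0 + 2 * pixel_size
    x_min, y_min = axis.min(axis=0) - pad
    x_max, y_max = axis.max(axis=0) + pad
    if x_min < 0 or y_min < 0 or x_max > shape[1] * pixel_size or y_max > shape[0] * pixel_size:
        raise ValueError(
            f"spine {index} (class {spec.class_label!r}) extends outside the image"
        )
    c0 = int(x_min / pixel_size)
    c1 = int(np.ceil(x_max / pixel_size)) + 1
    r0 = int(y_min / pixel_size)
    r1 = int(np.ceil(y_max / pixel_size)) + 1
    sl = (slice(r0, min(r1, shape[0])), slice(c0, min(c1, shape[1])))

    xs = (np.arange(sl[1].start, sl[1].stop) + 0.5) * pixel_size
    ys = (np.arange(sl[0].start, sl[0].stop) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    region = np.zeros(X.shape, dtype=bool)
    # neck: union of disks of local half-width along the axis
    for (ax, ay), hw in zip(axis, halfw):
        if hw > 0:
            region |= (X - ax) ** 2 + (Y - ay) ** 2 <= hw * hw
    # head disk centred at arc position s_head
    head_center, _ = point_on_polyline(axis, s_head)
    region |= (X - head_center[0]) ** 2 + (Y - head_center[1]) ** 2 <= (W / 2.0) ** 2
    return region, sl, tip


def render_scene(config: ImageSceneConfig) -> tuple[FluorescenceImage, GroundTruth]:
    """Render a scene and return the image plus exact ground truth.

    Deterministic per config.seed; identical configs yield bit-identical
    images.
    """
    shape = tuple(config.image_shape)
    px = config.pixel_size
    X, Y = _pixel_centers(shape, px)
    core = resample_polyline(config.dendrite_path, px / 4)
    core_len = polyline_arc_length(config.dendrite_path)

    dend_dist = _dist_to_segments(X, Y, config.dendrite_path)
    dendrite = dend_dist <= config.dendrite_radius

    indicator = dendrite.copy()
    labels = np.zeros(shape, dtype=np.int32)
    n = len(config.spine_specs)
    lengths = np.zeros(n)
    widths = np.zeros(n)
    bases = np.zeros((n, 2))
    tips = np.zeros((n, 2))
    for i, spec in enumerate(config.spine_specs):
        attach_pt, _tangent = point_on_polyline(core, spec.attachment)
        direction = np.array([np.cos(spec.orientation), np.sin(spec.orientation)])
        base = attach_pt + direction * config.dendrite_radius
        region, sl, tip = _spine_region(spec, base, shape, px, i)
        indicator[sl] |= region
        spine_only = region & ~dendrite[sl]
        lab = labels[sl]
        lab[spine_only & (lab == 0)] = i + 1
        labels[sl] = lab
        lengths[i] = spec.length
        widths[i] = spec.head_width
        bases[i] = base
        tips[i] = tip

    field_img = indicator.astype(float)
    if config.psf_sigma > 0:
        field_img = gaussian_filter(field_img, sigma=config.psf_sigma / px)
    expected = config.photon_scale * field_img + config.background_level

    rng = np.random.default_rng(config.seed)
    if config.poisson_noise:
        img = rng.poisson(expected).astype(float)
    else:
        img = expected.copy()
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = GroundTruth(
        lengths=lengths,
        head_widths=widths,
        ratios=lengths / np.where(widths > 0, widths, 1.0),
        spine_labels=labels,
        base_points=bases,
        tip_points=tips,
        core_polyline=core,
        core_length=core_len,
    )
    return FluorescenceImage(intensity=img, pixel_size=px), truth


def arrange_spines_along_core(
    specs: list[SpineShapeSpec],
    dendrite_path: np.ndarray,
    margin: float = 2.0,
    jitter_deg: float = 15.0,
    seed: int = 0,
) -> list[SpineShapeSpec]:
    """Assign evenly spaced attachments and alternating-side orientations.

    Spines are placed at uniform arc spacing (leaving ``margin`` um at both
    ends) and emanate perpendicular to the local core tangent, alternating
    sides, with a small random angular jitter. Returns the same spec objects,
    mutated in place.
    """
    poly = _as_polyline(dendrite_path)
    core_len = polyline_arc_length(poly)
    n = len(specs)
    if n == 0:
        return specs
    usable = core_len - 2 * margin
    if usable <= 0:
        raise ValueError("dendrite core too short for the requested margin")
    rng = np.random.default_rng(seed)
    positions = margin + (np.arange(n) + 0.5) / n * usable
    for i, spec in enumerate(specs):
        _pt, tangent = point_on_polyline(poly, float(positions[i]))
        normal_angle = np.arctan2(tangent[1], tangent[0]) + np.pi / 2
        side = 1 if i % 2 == 0 else -1
        jitter = np.deg2rad(jitter_deg) * rng.uniform(-1, 1)
        spec.attachment = float(positions[i])
        spec.orientation = float(normal_angle + (0 if side == 1 else np.pi) + jitter)
    return specs
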