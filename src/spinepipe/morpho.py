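"""Dendritic-spine morphometry on 2-D fluorescence images.

The measurement chain mirrors a semi-automatic confocal workflow:

1. ``define_dendrite_core`` traces the intensity ridge of the dendrite
   between rough anchor points and refines it to a sub-pixel centreline;
   its arc length is the denominator of the linear spine density.
2. ``fit_spine_skeleton`` fits, inside a spine region of interest, a virtual
   skeleton — a smooth curve from the spine base into the ROI chosen to
   maximise the mean fluorescence sampled along it, subject to a curvature
   penalty. The curvilinear arc length of this skeleton is the spine length L.
3. ``measure_head_width`` scans intensity profiles perpendicular to the
   skeleton over the distal two thirds of the spine (the basal third adjacent
   to the dendrite is excluded) and reports the maximal full width at half
   maximum above background as the head width W.
4. ``compute_shape_ratio`` forms the scale-free shape parameter R = L/W and
   assigns the morphological class from its ratio bin.

Conventions: images are (row, col) grids of non-negative counts; pixel
centres sit at (index + 0.5) * pixel_size with the origin at the top-left;
all reported lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter1d
from scipy.stats import pearsonr
from skimage.filters import threshold_otsu
from skimage.graph import MCP_Geometric, route_through_array

from .classes import classify_ratio  # noqa: F401  (re-exported)


@dataclass
class FluorescenceImage:
    """Single-channel fluorescence image with physical pixel size (um)."""

    intensity: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def sample(self, points_um: np.ndarray) -> np.ndarray:
        """Bilinear intensity at (x, y) um points."""
        pts = np.asarray(points_um, dtype=float)
        rows = pts[:, 1] / self.pixel_size - 0.5
        cols = pts[:, 0] / self.pixel_size - 0.5
        return map_coordinates(self.intensity, [rows, cols], order=1, mode="nearest")


@dataclass
class DendriteCore:
    polyline: np.ndarray        # (n, 2) sub-pixel (x, y) um
    length: float               # um, arc length of the polyline
    radius_estimate: float      # um


@dataclass
class SpineRoi:
    """Region of interest for one spine: pixel mask plus base point."""

    mask: np.ndarray            # boolean, full image frame
    base_point: np.ndarray      # (x, y) um, on the dendrite surface
    region_id: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.base_point = np.asarray(self.base_point, dtype=float)


@dataclass
class SpineSkeleton:
    points: np.ndarray          # (n, 2) um, base to tip
    length: float               # um
    mean_fluorescence: float    # mean intensity sampled along the curve
    region_id: int = 0


@dataclass
class SpineMeasurement:
    length: float
    head_width: float
    ratio: float
    class_label: str
    region_id: int = 0


@dataclass
class SpineGroupSample:
    """Per-group collection of spine measurements with linear density."""

    group: str
    measurements: list[SpineMeasurement]
    dendrite_length: float      # total um of core analysed

    @property
    def count(self) -> int:
        return len(self.measurements)

    @property
    def density(self) -> float:
        return compute_linear_density(self.count, self.dendrite_length)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([m.ratio for m in self.measurements])


def _arc_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def estimate_background(image: FluorescenceImage) -> float:
    """Background level: median of pixels below the Otsu threshold."""
    thr = threshold_otsu(image.intensity)
    below = image.intensity[image.intensity < thr]
    if below.size == 0:
        return float(image.intensity.min())
    return float(np.median(below))


def define_dendrite_core(
    image: FluorescenceImage,
    anchor_points: Sequence[Sequence[float]],
    smooth_sigma_px: float = 2.0,
    profile_halfwidth: float = 1.0,
) -> DendriteCore:
    """Trace the dendrite centreline between rough anchors.

    The maximal-intensity path between the anchors is found on a smoothed
    copy of the image, then each path point is refined to the sub-pixel
    intensity centroid of the profile perpendicular to the local tangent,
    and the refined polyline is lightly smoothed before measuring its arc
    length. ``profile_halfwidth`` (um) bounds the perpendicular search.
    """
    anchors = np.asarray(anchor_points, dtype=float)
    if anchors.ndim != 2 or anchors.shape[0] < 2:
        raise ValueError("need at least two anchor points")
    if np.any(np.all(np.isclose(anchors[:-1], anchors[1:]), axis=1)):
        raise ValueError("consecutive anchor points are identical")

    px = image.pixel_size
    smooth = gaussian_filter(image.intensity, smooth_sigma_px)
    thr = threshold_otsu(smooth)
    anchor_rc = np.column_stack(
        [anchors[:, 1] / px - 0.5, anchors[:, 0] / px - 0.5]
    )
    anchor_idx = np.round(anchor_rc).astype(int)
    anchor_idx[:, 0] = np.clip(anchor_idx[:, 0], 0, smooth.shape[0] - 1)
    anchor_idx[:, 1] = np.clip(anchor_idx[:, 1], 0, smooth.shape[1] - 1)
    for k, (r, c) in enumerate(anchor_idx):
        if smooth[r, c] < thr:
            raise ValueError(
                f"anchor {k} at ({anchors[k, 0]:.2f}, {anchors[k, 1]:.2f}) um "
                "lies on background"
            )

    cost = (smooth.max() - smooth) + 1e-3 * smooth.max()
    path_rc: list[tuple[int, int]] = []
    for a, b in zip(anchor_idx[:-1], anchor_idx[1:]):
        seg, _ = route_through_array(
            cost, tuple(a), tuple(b), fully_connected=True, geometric=True
        )
        if path_rc:
            seg = seg[1:]
        path_rc.extend(seg)
    path = np.array([[ (c + 0.5) * px, (r + 0.5) * px ] for r, c in path_rc])

    bg = estimate_background(image)
    refined = _refine_centerline(image, path, bg, profile_halfwidth)
    # smooth out pixel staircase before measuring length
    if refined.shape[0] >= 7:
        win = min(9, refined.shape[0] // 2 * 2 + 1)
        sm = np.column_stack([
            uniform_filter1d(refined[:, 0], win, mode="nearest"),
            uniform_filter1d(refined[:, 1], win, mode="nearest"),
        ])
        sm[0], sm[-1] = refined[0], refined[-1]
        refined = sm
    radius = _estimate_tube_radius(image, refined, bg, profile_halfwidth)
    return DendriteCore(
        polyline=refined, length=_arc_length(refined), radius_estimate=radius
    )


def _tangents(points: np.ndarray) -> np.ndarray:
    grad = np.gradient(points, axis=0)
    norm = np.linalg.norm(grad, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return grad / norm


def _refine_centerline(
    image: FluorescenceImage,
    path: np.ndarray,
    background: float,
    halfwidth: float,
) -> np.ndarray:
    """Shift each path point to the perpendicular intensity centroid."""
    px = image.pixel_size
    tang = _tangents(path)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-halfwidth, halfwidth + px / 2, px / 2)
    refined = path.copy()
    for i, (pt, nrm) in enumerate(zip(path, normals)):
        samples = pt[None, :] + offsets[:, None] * nrm[None, :]
        vals = image.sample(samples) - background
        vals = np.clip(vals, 0.0, None)
        total = vals.sum()
        if total > 0:
            shift = float((vals * offsets).sum() / total)
            refined[i] = pt + shift * nrm
    return refined


def _estimate_tube_radius(
    image: FluorescenceImage,
    centerline: np.ndarray,
    background: float,
    halfwidth: float,
) -> float:
    px = image.pixel_size
    tang = _tangents(centerline)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-halfwidth, halfwidth + px / 2, px / 4)
    widths = []
    step = max(1, centerline.shape[0] // 20)
    for pt, nrm in zip(centerline[::step], normals[::step]):
        samples = pt[None, :] + offsets[:, None] * nrm[None, :]
        profile = image.sample(samples)
        w = _profile_fwhm(offsets, profile, background)
        if w is not None:
            widths.append(w)
    return float(np.median(widths) / 2.0) if widths else 0.0


def _profile_fwhm(
    offsets: np.ndarray, profile: np.ndarray, background: float
) -> float | None:
    """Full width at half maximum (above background) of a 1-D profile.

    The peak is taken near the profile centre; crossings of the half level
    are located by walking outward from the peak with linear interpolation.
    Returns None when the profile carries no peak above background.
    """
    n = profile.size
    center_lo, center_hi = n // 4, 3 * n // 4
    center_slice = profile[center_lo:center_hi]
    if center_slice.size == 0:
        return None
    peak_idx = center_lo + int(np.argmax(center_slice))
    peak = profile[peak_idx]
    if peak <= background or (peak - background) < 1e-9:
        return None
    half = background + (peak - background) / 2.0

    def _cross(idx_range) -> float | None:
        prev = peak_idx
        for j in idx_range:
            if profile[j] < half:
                # interpolate between prev (>= half) and j (< half)
                f = (profile[prev] - half) / (profile[prev] - profile[j])
                return float(offsets[prev] + f * (offsets[j] - offsets[prev]))
            prev = j
        return None

    right = _cross(range(peak_idx + 1, n))
    left = _cross(range(peak_idx - 1, -1, -1))
    if right is None or left is None:
        return None
    return float(right - left)


def _tophat_observed_fwhm(w: float, sigma: float) -> float:
    """FWHM of a unit top-hat of width ``w`` convolved with a Gaussian."""
    from scipy.stats import norm as _norm

    center = 2.0 * _norm.cdf(w / (2.0 * sigma)) - 1.0
    half = center / 2.0

    def f(t: float) -> float:
        return _norm.cdf((t + w / 2) / sigma) - _norm.cdf((t - w / 2) / sigma) - half

    t_hi = w / 2 + 5 * sigma
    return 2.0 * optimize.brentq(f, 0.0, t_hi)


def deconvolve_fwhm(measured: float, psf_sigma: float) -> float:
    """Invert PSF broadening of a measured FWHM (top-hat object model).

    Solves observed_fwhm(w; sigma) = measured for the true width w. Below
    the resolution floor (~2.355 sigma, where any object measures like the
    PSF itself) the measurement is returned uncorrected.
    """
    if psf_sigma <= 0 or measured <= 0:
        return measured
    lo = 1e-4 * measured
    if _tophat_observed_fwhm(lo, psf_sigma) >= measured:
        return measured  # at or below the resolution floor
    return float(optimize.brentq(
        lambda w: _tophat_observed_fwhm(w, psf_sigma) - measured, lo, measured
    ))


def _refine_tip(
    image: FluorescenceImage,
    points: np.ndarray,
    background: float,
    max_shift: float,
) -> np.ndarray:
    """Move the curve end to the half-max intensity edge along its tangent.

    The fitted tip sits on a mask pixel centre, half a pixel or so inside
    the true blurred edge; this walks the end point (out or in, bounded by
    ``max_shift`` um) to where the intensity crosses half of the local
    plateau above background.
    """
    tip = points[-1]
    back_idx = max(0, points.shape[0] - 6)
    u = tip - points[back_idx]
    norm = np.linalg.norm(u)
    if norm == 0:
        return points
    u = u / norm
    plateau = float(image.sample(points[back_idx:]).max())
    half = background + (plateau - background) / 2.0
    step = max_shift / 20.0
    ts = np.arange(-max_shift, max_shift + step, step)
    profile = image.sample(tip[None, :] + ts[:, None] * u[None, :])
    above = profile >= half
    if not above.any():
        return points
    last = int(np.nonzero(above)[0][-1])
    if last == ts.size - 1:
        t_star = ts[last]
    else:
        # interpolate the crossing between the last above and first below
        f = (profile[last] - half) / (profile[last] - profile[last + 1])
        t_star = ts[last] + f * (ts[last + 1] - ts[last])
    if t_star > 0:
        return np.vstack([points, tip + t_star * u])
    # shorten: drop dense points beyond the refined tip
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    keep = arc <= arc[-1] + t_star
    if keep.sum() < 2:
        return points
    return np.vstack([points[keep], tip + t_star * u])


def _tip_candidates(
    mask: np.ndarray, base_rc: tuple[int, int], k: int = 3
) -> tuple[list[tuple[int, int]], MCP_Geometric]:
    """Geodesically farthest mask pixels from the base, k mutually separated.

    Only genuine tip contenders are returned — pixels within 2 px of the
    maximal geodesic distance — so the multi-start cannot drift to a
    geodesically nearer boundary point with a straighter (cheaper) curve.
    """
    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    dist, _ = mcp.find_costs([base_rc])
    dist = np.where(mask, dist, -np.inf)
    dmax = float(dist.max())
    if not np.isfinite(dmax):
        return [], mcp
    order = np.argsort(dist, axis=None)[::-1]
    cand: list[tuple[int, int]] = []
    for flat in order:
        r, c = np.unravel_index(flat, mask.shape)
        if not np.isfinite(dist[r, c]) or dist[r, c] < dmax - 2.0:
            break
        if all(abs(r - cr) + abs(c - cc) > 2 for cr, cc in cand):
            cand.append((int(r), int(c)))
        if len(cand) >= k:
            break
    # candidates come ordered by decreasing geodesic distance
    return cand, mcp


def _resample_points(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    if arc[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    s = np.linspace(0, arc[-1], n)
    return np.column_stack(
        [np.interp(s, arc, points[:, 0]), np.interp(s, arc, points[:, 1])]
    )


def _curve_through(control: np.ndarray, n_dense: int = 200) -> np.ndarray:
    """Smooth curve through control points (natural cubic in arc parameter)."""
    t = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(control, axis=0), axis=1))]
    if t[-1] == 0:
        return control
    t = t / t[-1]
    # guard against coincident control points
    t = np.maximum.accumulate(t + np.arange(t.size) * 1e-12)
    cs_x = CubicSpline(t, control[:, 0])
    cs_y = CubicSpline(t, control[:, 1])
    u = np.linspace(0, 1, n_dense)
    return np.column_stack([cs_x(u), cs_y(u)])


def fit_spine_skeleton(
    image: FluorescenceImage,
    roi: SpineRoi,
    n_control: int = 7,
    curvature_penalty: float = 1.0,
    n_samples: int = 40,
    background: float | None = None,
) -> SpineSkeleton:
    """Fit the virtual skeleton of a spine inside its ROI.

    The skeleton is a curve with ``n_control`` control points from the ROI
    base point to a candidate tip, chosen to maximise the mean fluorescence
    sampled along the curve (normalised by the ROI's peak intensity, so the
    term is O(1)) minus a curvature penalty
    ``curvature_penalty * sum(second differences^2) / ds^2``. Candidate tips
    are the geodesically farthest ROI pixels from the base (in decreasing
    distance order); among candidates whose optimised objective comes within
    5% of the best, the geodesically farthest tip wins — on a round head all
    rim pixels are near-equidistant and equally bright, and the farthest one
    is the spine tip by definition. Candidates more than 5% dimmer are
    rejected as noise artifacts. Deterministic.
    """
    if roi.mask.sum() < 4:
        raise ValueError("ROI too small")
    px = image.pixel_size
    roi_peak = float(image.intensity[roi.mask].max())
    norm = roi_peak if roi_peak > 0 else 1.0
    base_rc = (
        int(np.clip(round(roi.base_point[1] / px - 0.5), 0, roi.mask.shape[0] - 1)),
        int(np.clip(round(roi.base_point[0] / px - 0.5), 0, roi.mask.shape[1] - 1)),
    )
    # snap the base to the nearest ROI pixel if it sits just outside the mask
    if not roi.mask[base_rc]:
        rr, cc = np.nonzero(roi.mask)
        j = int(np.argmin((rr - base_rc[0]) ** 2 + (cc - base_rc[1]) ** 2))
        base_rc = (int(rr[j]), int(cc[j]))

    cands, mcp = _tip_candidates(roi.mask, base_rc)
    if not cands:
        raise ValueError("ROI has no reachable tip from the base")

    def objective(curve: np.ndarray) -> float:
        dense = _resample_points(curve, n_samples)
        mean_int = float(image.sample(dense).mean()) / norm
        d2 = np.diff(curve, n=2, axis=0)
        ds = max(_arc_length(curve) / (curve.shape[0] - 1), 1e-9)
        penalty = curvature_penalty * float((d2**2).sum()) / ds**2
        return mean_int - penalty

    results: list[tuple[float, float, np.ndarray]] = []
    for tip_rc in cands:
        trace = mcp.traceback(tip_rc)
        init = np.array([[(c + 0.5) * px, (r + 0.5) * px] for r, c in trace])
        init[0] = roi.base_point
        control0 = _resample_points(init, n_control)
        control0[0] = roi.base_point
        tang = _tangents(control0)
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])

        def neg_obj(offsets: np.ndarray, c0=control0, nrm=normals) -> float:
            curve = c0.copy()
            curve[1:-1] += offsets[:, None] * nrm[1:-1]
            return -objective(curve)

        n_free = n_control - 2
        res = optimize.minimize(
            neg_obj,
            np.zeros(n_free),
            method="Powell",
            bounds=[(-3 * px, 3 * px)] * n_free,
            options={"maxiter": 10, "xtol": px / 4, "ftol": 1e-3},
        )
        curve = control0.copy()
        curve[1:-1] += res.x[:, None] * normals[1:-1]
        obj = objective(curve)
        dense = _curve_through(curve)
        length = _arc_length(dense)
        results.append((obj, length, dense))

    best_obj = max(r[0] for r in results)
    threshold = best_obj - 0.05 * abs(best_obj)
    obj, length, dense = next(r for r in results if r[0] >= threshold)
    if background is None:
        background = estimate_background(image)
    # pull interior points onto the local intensity ridge (the geodesic
    # initialisation hugs the inner edge of curved spines) and keep the
    # endpoints fixed
    interior = _refine_centerline(image, dense, background, halfwidth=0.15)
    interior[0], interior[-1] = dense[0], dense[-1]
    sm = np.column_stack([
        uniform_filter1d(interior[:, 0], 15, mode="nearest"),
        uniform_filter1d(interior[:, 1], 15, mode="nearest"),
    ])
    sm[0], sm[-1] = dense[0], dense[-1]
    dense = sm
    dense = _refine_tip(image, dense, background, max_shift=3 * px)
    length = _arc_length(dense)
    if length <= 0:
        raise ValueError("degenerate skeleton of zero length")
    return SpineSkeleton(
        points=dense,
        length=length,
        mean_fluorescence=float(image.sample(dense).mean()),
        region_id=roi.region_id,
    )


def measure_head_width(
    image: FluorescenceImage,
    skeleton: SpineSkeleton,
    roi: SpineRoi,
    max_extent: float = 1.0,
    background: float | None = None,
    psf_sigma: float | None = None,
) -> float:
    """Head width: maximal perpendicular FWHM over the distal 2/3 of the spine.

    Profiles are sampled perpendicular to the skeleton at arc positions
    s in (L/3, L]; the basal third adjacent to the dendrite is excluded.
    ``max_extent`` (um) is the perpendicular half-range scanned. When the
    acquisition PSF sigma (um) is known it can be passed to deconvolve the
    FWHM broadening, which matters for heads of only a few pixels.
    """
    if skeleton.length <= 0:
        raise ValueError("skeleton has zero length")
    if background is None:
        background = estimate_background(image)
    px = image.pixel_size
    pts = skeleton.points
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    L = arc[-1]
    tang = _tangents(pts)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-max_extent, max_extent + px / 4, px / 4)
    widths = []
    sel = arc > L / 3.0
    for pt, nrm in zip(pts[sel], normals[sel]):
        samples = pt[None, :] + offsets[:, None] * nrm[None, :]
        profile = image.sample(samples)
        w = _profile_fwhm(offsets, profile, background)
        widths.append(np.nan if w is None else w)
    widths = np.asarray(widths, dtype=float)
    if np.all(np.isnan(widths)):
        raise ValueError("no measurable head: all profiles below background")
    # median-smooth the width-vs-arc sequence so a single noisy profile
    # cannot inflate the maximum
    smoothed = (
        pd.Series(widths).rolling(5, center=True, min_periods=1).median().to_numpy()
    )
    width = float(np.nanmax(smoothed))
    if psf_sigma is not None:
        width = deconvolve_fwhm(width, psf_sigma)
    return width


def compute_shape_ratio(length: float, head_width: float, region_id: int = 0) -> SpineMeasurement:
    """Scale-free shape parameter R = L/W with its morphological class."""
    if length <= 0 or head_width <= 0:
        raise ValueError("length and head_width must be positive")
    ratio = length / head_width
    return SpineMeasurement(
        length=length,
        head_width=head_width,
        ratio=ratio,
        class_label=classify_ratio(ratio),
        region_id=region_id,
    )


def compute_linear_density(spine_count: int, dendrite_length: float) -> float:
    """Linear spine density in spines per um of dendrite core."""
    if dendrite_length <= 0:
        raise ValueError("dendrite_length must be positive")
    if spine_count < 0:
        raise ValueError("spine_count must be non-negative")
    return spine_count / dendrite_length


def measure_spine(
    image: FluorescenceImage,
    roi: SpineRoi,
    background: float | None = None,
    psf_sigma: float | None = None,
) -> SpineMeasurement:
    """Full single-spine measurement: skeleton fit, head width, shape ratio."""
    skeleton = fit_spine_skeleton(image, roi, background=background)
    width = measure_head_width(
        image, skeleton, roi, background=background, psf_sigma=psf_sigma
    )
    return compute_shape_ratio(skeleton.length, width, region_id=roi.region_id)


def rois_from_labels(
    labels: np.ndarray, base_points: np.ndarray, pixel_size: float
) -> list[SpineRoi]:
    """Build SpineRois from a label mask plus per-spine base points (um)."""
    rois = []
    for i in range(base_points.shape[0]):
        mask = labels == i + 1
        if mask.any():
            rois.append(SpineRoi(mask=mask, base_point=base_points[i], region_id=i + 1))
    return rois


def quantify_region_fluorescence(
    image: FluorescenceImage,
    region_mask: np.ndarray,
    low_threshold: float,
    high_threshold: float,
    background_regions: Sequence[np.ndarray],
) -> float:
    """Background-corrected mean intensity inside a thresholded selection.

    The mean is taken over in-mask pixels whose value lies inside
    [low_threshold, high_threshold] (an over/under threshold window, e.g.
    640–4095 for 12-bit data), minus the mean over the background-region
    pixels. The result may be negative when the region is dimmer than the
    background estimate.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if low_threshold >= high_threshold:
        raise ValueError("low_threshold must be below high_threshold")
    if not region_mask.any():
        raise ValueError("empty region mask")
    vals = image.intensity[region_mask]
    in_window = vals[(vals >= low_threshold) & (vals <= high_threshold)]
    if in_window.size == 0:
        raise ValueError("no pixels inside the threshold window")
    bg_vals = np.concatenate(
        [image.intensity[np.asarray(m, dtype=bool)] for m in background_regions]
    ) if background_regions else np.array([0.0])
    return float(in_window.mean() - bg_vals.mean())


def normalize_to_reference(group_means: dict[str, float], reference: str) -> dict[str, float]:
    """Scale group means so the reference group normalises to 1.0."""
    if reference not in group_means:
        raise KeyError(f"reference group {reference!r} not found")
    ref = group_means[reference]
    if ref == 0:
        raise ZeroDivisionError("reference group mean is zero")
    return {g: v / ref for g, v in group_means.items()}


def if_tpa_concordance(if_ratios: Sequence[float], tpa_ratios: Sequence[float]) -> float:
    """Pearson correlation between immunofluorescence and TPA group ratios."""
    a = np.asarray(if_ratios, dtype=float)
    b = np.asarray(tpa_ratios, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ZeroDivisionError("correlation undefined for zero-variance input")
    return float(pearsonr(a, b).statistic)
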