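"""Frame detection and canonical cropping.

A scanned chart arrives at an arbitrary size, slightly rotated and
sometimes with the printed frame partially cut off.  This module
binarizes the scan with Gaussian adaptive thresholding, finds the
largest dark contour (the printed frame), reduces it to a four-sided
polygon, and perspective-warps the frame interior onto the template's
canonical raster so that every later operation can use fixed pixel
positions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, transform

from .errors import FrameNotFound, FrameNotRectangular, InputError
from .template import ChartTemplate, DEFAULT_TEMPLATE
from .types import CanonicalChart, Quadrilateral, RawScan

__all__ = [
    "to_grayscale",
    "gaussian_kernel_1d",
    "binarize_adaptive",
    "find_main_frame",
    "crop_to_canonical",
]

#: ITU-R BT.601 luma weights, the standard grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) uint8 raster to single-channel uint8 luma."""
    return np.clip(np.asarray(rgb, dtype=np.float64) @ _LUMA, 0, 255).astype(np.uint8)


def gaussian_kernel_1d(window: int) -> np.ndarray:
    """Normalized 1-D Gaussian tap weights for a ``window``-wide neighborhood.

    The bandwidth follows the conventional ksize-to-sigma rule used by
    image-processing adaptive thresholds:
    ``sigma = 0.3 * ((window - 1) * 0.5 - 1) + 0.8``.
    """
    sigma = 0.3 * ((window - 1) * 0.5 - 1) + 0.8
    x = np.arange(window, dtype=np.float64) - (window - 1) / 2
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def binarize_adaptive(
    image: np.ndarray, window: int = 27, offset: float = 10.0
) -> np.ndarray:
    """Gaussian adaptive thresholding.

    Each pixel is compared with the Gaussian-weighted mean of its
    ``window x window`` neighborhood (borders replicated); it becomes
    foreground (ink) iff its intensity is *below* that local mean minus
    ``offset``.  The defaults (27x27 neighborhood, offset 10) suit
    150-300 dpi document scans.

    Parameters
    ----------
    image:
        Single-channel 8-bit raster.
    window:
        Odd neighborhood width, >= 3.
    offset:
        Constant subtracted from the local mean before comparison.

    Returns
    -------
    Boolean raster of the same shape; ``True`` marks foreground/ink.
    """
    if window % 2 == 0 or window < 3:
        raise InputError(f"window must be odd and >= 3, got {window}")
    img = np.asarray(image)
    if img.size == 0:
        raise InputError("empty image")
    if img.ndim != 2:
        raise InputError("binarize_adaptive expects a single-channel image")
    k = gaussian_kernel_1d(window)
    f = img.astype(np.float64)
    # the 2-D Gaussian window is separable: two 1-D passes, replicate borders
    local_mean = ndimage.correlate1d(f, k, axis=0, mode="nearest")
    local_mean = ndimage.correlate1d(local_mean, k, axis=1, mode="nearest")
    return f < local_mean - offset


def _hull_area(coords: np.ndarray) -> float:
    """Convex-hull area of a contour.

    For an intact frame this equals the enclosed area; for a frame with
    a corner cut off, whose boundary wraps around the remaining strip of
    ink, it still measures the spanned region rather than the (tiny)
    strip area.
    """
    if len(coords) < 3:
        return 0.0
    try:
        return float(ConvexHull(coords).volume)  # 2-D "volume" is area
    except QhullError:
        return 0.0


def _perimeter(coords: np.ndarray) -> float:
    d = np.diff(coords, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _line_intersection(p1, p2, p3, p4) -> tuple[float, float]:
    """Intersection of lines (p1,p2) and (p3,p4) in (x, y) coordinates."""
    x1, y1 = p1
    x2, y2 = p2
    x3, y3 = p3
    x4, y4 = p4
    den = (x1 - x2) * (y3 - y4) - (y1 - y2) * (x3 - x4)
    if abs(den) < 1e-9:
        raise FrameNotRectangular("frame edges are parallel; cannot intersect")
    a = x1 * y2 - y1 * x2
    b = x3 * y4 - y3 * x4
    return (
        (a * (x3 - x4) - (x1 - x2) * b) / den,
        (a * (y3 - y4) - (y1 - y2) * b) / den,
    )


def _order_clockwise_from_topleft(pts: list[tuple[float, float]]) -> tuple:
    c = np.mean(pts, axis=0)
    # image y grows downward, so ascending atan2 order is clockwise on screen
    pts = sorted(pts, key=lambda p: np.arctan2(p[1] - c[1], p[0] - c[0]))
    start = int(np.argmin([p[0] + p[1] for p in pts]))
    return tuple(tuple(map(float, pts[(start + i) % 4])) for i in range(4))


def _interior_angles(corners) -> np.ndarray:
    angles = []
    for i in range(4):
        p = np.array(corners[i])
        a = np.array(corners[(i - 1) % 4]) - p
        b = np.array(corners[(i + 1) % 4]) - p
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return np.array(angles)


def _fit_edge_line(contour_xy: np.ndarray, a, b, tol: float = 4.0, n_iter: int = 3):
    """Refine the line through DP vertices (a, b) by iterated PCA fits.

    Each round selects the contour points within ``tol`` of the current
    line (between its endpoints) and refits; noise blobs attached to the
    frame tilt the initial hull chord, but the straight frame edge
    dominates the inlier set so the fit converges onto it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    span = np.linalg.norm(b - a)
    if span < 1e-9:
        return a, b
    for _ in range(n_iter):
        u = (b - a) / np.linalg.norm(b - a)
        rel = contour_xy - a
        t = rel @ u
        dist = np.abs(rel @ np.array([-u[1], u[0]]))
        sel = (dist <= tol) & (t >= -tol) & (t <= np.linalg.norm(b - a) + tol)
        pts = contour_xy[sel]
        if len(pts) < 10:
            break
        c = pts.mean(axis=0)
        d = np.linalg.svd(pts - c, full_matrices=False)[2][0]
        # keep endpoints spanning the same extent on the refitted line
        proj = (pts - c) @ d
        a, b = c + proj.min() * d, c + proj.max() * d
    return a, b


def find_main_frame(
    binary: np.ndarray,
    angle_tol_deg: float = 10.0,
    min_frame_fraction: float = 0.20,
    despeckle_px: int = 64,
) -> Quadrilateral:
    """Locate the chart's printed frame in a binarized scan.

    The largest closed contour by enclosed area is taken as the frame.
    Its outline is simplified with the Douglas-Peucker algorithm (the
    tolerance starts at 1% of the contour perimeter and doubles until at
    most six vertices remain); the four longest edges of the simplified
    polygon are then intersected pairwise to complete the rectangle.
    Completing from edge lines rather than polygon vertices recovers a
    corner even when that corner is physically cut off in the scan.

    Raises
    ------
    FrameNotFound
        If no contour encloses at least ``min_frame_fraction`` of the
        image area.
    FrameNotRectangular
        If the simplified outline has fewer than four edges or its
        interior angles deviate from 90 deg by more than
        ``angle_tol_deg``.
    """
    binary = np.asarray(binary).astype(bool)
    if binary.size == 0:
        raise InputError("empty binary image")

    # Scan noise leaves salt specks — and, at high density, thin
    # percolating tendrils attached to the frame — after adaptive
    # thresholding; they corrupt the frame contour.  Clean with a
    # morphological opening, escalating downward if the opening also
    # destroys the frame itself (very thin printed strokes): full 3x3
    # block, then the 4-connected cross, then no opening at all.
    structures = (
        [np.ones((3, 3), bool), ndimage.generate_binary_structure(2, 1), None]
        if despeckle_px
        else [None]
    )
    contour = None
    best_frac = 0.0
    for structure in structures:
        cleaned = (
            ndimage.binary_opening(binary, structure=structure)
            if structure is not None
            else binary
        )
        if despeckle_px:
            labeled, n = ndimage.label(cleaned)
            if not n:
                continue
            sizes = ndimage.sum_labels(cleaned, labeled, index=np.arange(1, n + 1))
            cleaned = np.isin(labeled, np.flatnonzero(sizes >= despeckle_px) + 1)
        contours = measure.find_contours(cleaned.astype(float), 0.5)
        if not contours:
            continue
        areas = [_hull_area(c) for c in contours]
        best = int(np.argmax(areas))
        best_frac = max(best_frac, areas[best] / (binary.shape[0] * binary.shape[1]))
        if areas[best] >= min_frame_fraction * binary.shape[0] * binary.shape[1]:
            contour = contours[best]
            break
    if contour is None:
        raise FrameNotFound(
            f"largest contour covers {best_frac:.1%} of the image, "
            f"below the {min_frame_fraction:.0%} floor"
        )

    # Simplify the contour's convex hull rather than the raw boundary:
    # the boundary of a frame with a corner cut off wraps around the
    # remaining strip of ink, while its hull is simply the rectangle
    # with one chamfered corner — the four longest hull edges are the
    # frame sides in either case.
    hull_pts = contour[ConvexHull(contour).vertices]
    ring = np.vstack([hull_pts, hull_pts[:1]])
    # start fine: a coarse initial tolerance can swallow a true corner
    # when the hull is slightly chamfered there
    eps = max(2.0, 0.001 * _perimeter(ring))
    approx = measure.approximate_polygon(ring, tolerance=eps)
    while len(approx) - 1 > 6:  # first point repeats at the end
        eps *= 2
        approx = measure.approximate_polygon(ring, tolerance=eps)
    verts = approx[:-1] if np.allclose(approx[0], approx[-1]) else approx
    if len(verts) < 4:
        raise FrameNotRectangular(
            f"frame outline simplifies to {len(verts)} vertices; need 4"
        )

    # polygon edges in (x, y); keep the 4 longest, preserving cyclic order
    pts = [(float(p[1]), float(p[0])) for p in verts]
    n = len(pts)
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    lengths = [np.hypot(b[0] - a[0], b[1] - a[1]) for a, b in edges]
    keep = sorted(sorted(range(n), key=lambda i: -lengths[i])[:4])
    contour_xy = np.column_stack([contour[:, 1], contour[:, 0]])
    lines = [_fit_edge_line(contour_xy, *edges[i]) for i in keep]
    corners = [
        _line_intersection(*lines[i], *lines[(i + 1) % 4]) for i in range(4)
    ]
    corners = _order_clockwise_from_topleft(corners)

    angles = _interior_angles(corners)
    if np.any(np.abs(angles - 90.0) > angle_tol_deg):
        raise FrameNotRectangular(
            f"interior angles {np.round(angles, 1)} exceed 90+/-{angle_tol_deg} deg"
        )
    return Quadrilateral(corners=corners)


def crop_to_canonical(
    scan: RawScan,
    frame: Quadrilateral,
    template: ChartTemplate = DEFAULT_TEMPLATE,
    min_frame_fraction: float = 0.20,
) -> CanonicalChart:
    """Perspective-warp the frame interior onto the canonical raster.

    The four frame corners are mapped to the corners of the template's
    canonical rectangle, so skewed or rotated scans all land on the same
    fixed-size, axis-aligned raster.
    """
    h, w = scan.pixels.shape[:2]
    if frame.area < min_frame_fraction * h * w:
        raise FrameNotFound(
            f"frame area {frame.area:.0f} px^2 is below {min_frame_fraction:.0%} of the scan"
        )
    W, H = template.canonical_width, template.canonical_height
    dst = np.array([(0, 0), (W - 1, 0), (W - 1, H - 1), (0, H - 1)], dtype=float)
    src = np.array(frame.corners, dtype=float)
    try:
        tform = transform.ProjectiveTransform.from_estimate(dst, src)
    except AttributeError:  # older scikit-image
        tform = transform.ProjectiveTransform()
        if not tform.estimate(dst, src):
            raise FrameNotFound("degenerate frame quadrilateral")
    if not tform:
        raise FrameNotFound("degenerate frame quadrilateral")
    warped = transform.warp(
        scan.pixels.astype(np.float32),
        tform,
        output_shape=(H, W),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return CanonicalChart(
        pixels=np.clip(np.round(warped), 0, 255).astype(np.uint8),
        transform=tform,
        template=template,
    )
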