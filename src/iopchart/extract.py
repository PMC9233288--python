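"""Gridline calibration and colored-mark extraction.

On the canonical raster, the vertical time gridlines are found with
Canny edge detection plus a Hough line transform restricted to
near-vertical angles, then snapped to the template's nominal slot
positions.  Marks are segmented with hue/saturation/value color masks
(blue = right eye / OD, red = left eye / OS, the charting convention on
the German form) and converted to mmHg through the template's pixel-to-
value map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import feature, morphology, measure, transform as sktransform

from .errors import CalibrationError
from .preprocess import to_grayscale
from .template import ChartTemplate, SLOT_TIMES
from .types import CanonicalChart, DetectedEntry, TimeLine

__all__ = [
    "detect_time_lines",
    "color_mask",
    "extract_entries",
    "pixel_to_value",
    "value_to_pixel",
    "HSVThresholds",
]


def pixel_to_value(y_px: float, template: ChartTemplate) -> float:
    """mmHg value at a canonical y pixel (strictly decreasing in y)."""
    return template.pixel_to_value(y_px)


def value_to_pixel(mmhg: float, template: ChartTemplate) -> float:
    """Canonical y pixel of an mmHg value."""
    return template.value_to_pixel(mmhg)


def detect_time_lines(
    chart: CanonicalChart,
    max_angle_deg: float = 5.0,
    min_line_gap: float = 20.0,
    snap_tol: float = 12.0,
    min_lines: int = 3,
) -> list[TimeLine]:
    """Find the vertical time gridlines and assign them to template slots.

    Canny edges inside the plot band feed a Hough transform whose angle
    range is limited to ``max_angle_deg`` from vertical, which removes
    horizontal rulings outright.  Peaks closer together than
    ``min_line_gap`` are merged (strongest wins) and each survivor is
    snapped to the nearest nominal slot x position within ``snap_tol``
    pixels; at most one line per slot is kept.

    Raises
    ------
    CalibrationError
        If fewer than ``min_lines`` slots are detected (three is the
        minimum for a meaningful single-day calibration).
    """
    tpl = chart.template
    gray = to_grayscale(chart.pixels).astype(np.float64) / 255.0
    # plot band only: keeps header text and axis labels out of the votes
    r0 = int(tpl.y_top_px) - 30
    r1 = int(tpl.y_bottom_px) + 30
    band = gray[max(r0, 0) : min(r1, gray.shape[0])]
    edges = feature.canny(band, sigma=1.5, low_threshold=0.08, high_threshold=0.2)

    thetas = np.deg2rad(np.linspace(-max_angle_deg, max_angle_deg, 41))
    h, theta, dist = sktransform.hough_line(edges, theta=thetas)
    if h.max() == 0:
        raise CalibrationError("no line votes at all inside the plot band")
    _, angles, dists = sktransform.hough_line_peaks(
        h,
        theta,
        dist,
        min_distance=9,
        threshold=0.35 * h.max(),
        num_peaks=80,
    )
    votes = [
        h[np.argmin(np.abs(dist - d)), np.argmin(np.abs(theta - a))]
        for a, d in zip(angles, dists)
    ]

    y_mid = band.shape[0] / 2.0
    cands: list[tuple[float, float]] = []  # (x at band middle, support)
    for a, d, v in zip(angles, dists, votes):
        x = (d - y_mid * np.sin(a)) / np.cos(a)
        cands.append((float(x), float(v)))
    cands.sort()

    merged: list[tuple[float, float]] = []
    for x, v in cands:
        if merged and x - merged[-1][0] < min_line_gap:
            if v > merged[-1][1]:
                merged[-1] = (x, v)
        else:
            merged.append((x, v))

    lines: dict[tuple[int, str], TimeLine] = {}
    for d_idx, t, slot_x in tpl.iter_slots():
        best = None
        for x, v in merged:
            if abs(x - slot_x) <= snap_tol and (best is None or v > best[1]):
                best = (x, v)
        if best is not None:
            lines[(d_idx, t)] = TimeLine(x_px=best[0], slot=(d_idx, t), support=best[1])
    if len(lines) < min_lines:
        raise CalibrationError(
            f"only {len(lines)} time gridlines detected; need at least {min_lines}"
        )
    return sorted(lines.values(), key=lambda ln: ln.x_px)


def _hsv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue (degrees), saturation and value of an RGB uint8 raster."""
    f = rgb.astype(np.float32) / 255.0
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    v = f.max(axis=-1)
    c = v - f.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, c / v, 0.0)
        hc = np.where(c > 0, c, 1.0)
        h = np.select(
            [v == r, v == g],
            [(g - b) / hc, (b - r) / hc + 2.0],
            (r - g) / hc + 4.0,
        )
    h = np.where(c > 0, (h * 60.0) % 360.0, 0.0)
    return h, s, v


@dataclass(frozen=True)
class HSVThresholds:
    """Hue windows (degrees) and saturation/value floors for the two inks."""

    blue_hue: tuple[float, float] = (200.0, 260.0)
    red_hue_max: float = 20.0
    red_hue_min_wrap: float = 340.0
    sat_min: float = 0.30
    val_min: float = 0.20


def color_mask(
    chart: CanonicalChart, eye: str, thresholds: HSVThresholds = HSVThresholds()
) -> np.ndarray:
    """Binary mask of the eye's ink color (OD = blue, OS = red).

    The hue windows are disjoint, so for any pixel the OD and OS masks
    are disjoint by construction.
    """
    if eye not in ("OD", "OS"):
        raise ValueError("eye must be 'OD' or 'OS'")
    hue, sat, val = _hsv(chart.pixels)
    chroma = (sat >= thresholds.sat_min) & (val >= thresholds.val_min)
    if eye == "OD":
        return chroma & (hue >= thresholds.blue_hue[0]) & (hue <= thresholds.blue_hue[1])
    return chroma & ((hue <= thresholds.red_hue_max) | (hue >= thresholds.red_hue_min_wrap))


def _local_halfwidth(lines: list[TimeLine], i: int, vicinity_frac: float) -> float:
    xs = [ln.x_px for ln in lines]
    gaps = []
    if i > 0:
        gaps.append(xs[i] - xs[i - 1])
    if i < len(xs) - 1:
        gaps.append(xs[i + 1] - xs[i])
    gap = min(gaps) if gaps else 60.0
    return vicinity_frac * gap


def _component_extent_mmhg(rows: np.ndarray, template: ChartTemplate) -> float:
    lo = float(np.clip(rows.min(), template.y_top_px, template.y_bottom_px))
    hi = float(np.clip(rows.max(), template.y_top_px, template.y_bottom_px))
    return template.pixel_to_value(lo) - template.pixel_to_value(hi)


def extract_entries(
    chart: CanonicalChart,
    lines: list[TimeLine],
    eye: str,
    vicinity_frac: float = 0.40,
    stroke_max_mmhg: float = 6.0,
    min_blob_px: int = 12,
    open_radius: int = 2,
    thresholds: HSVThresholds = HSVThresholds(),
    mask: np.ndarray | None = None,
) -> list[DetectedEntry]:
    """Read the eye's marks in the immediate vicinity of each gridline.

    Within a window of ``vicinity_frac`` times the local inter-slot
    spacing around each line, connected components of the color mask are
    candidate marks.  Components taller than ``stroke_max_mmhg`` of
    vertical extent are treated as connecting-line strokes, not marks; a
    morphological opening is attempted once to split a mark that a
    stroke merged into, and whatever remains too tall is dropped.  The
    largest surviving blob per (line, eye) becomes the entry; additional
    accepted blobs are kept but flagged ``"extra"`` (they surface as
    false positives in evaluation).

    The entry's value is read at the median y of the mask pixels in a
    narrow column band centered on the gridline (falling back to the
    blob centroid), which keeps the reading unbiased when a connecting
    polyline enters the window; values are reported at 0.1 mmHg
    resolution.
    """
    tpl = chart.template
    if mask is None:
        mask = color_mask(chart, eye, thresholds)
    r0 = max(int(tpl.y_top_px) - 20, 0)
    r1 = min(int(tpl.y_bottom_px) + 20, mask.shape[0])
    entries: list[DetectedEntry] = []

    for i, line in enumerate(lines):
        halfw = _local_halfwidth(lines, i, vicinity_frac)
        c0 = max(int(line.x_px - halfw), 0)
        c1 = min(int(line.x_px + halfw) + 1, mask.shape[1])
        sub = mask[r0:r1, c0:c1]
        if not sub.any():
            continue
        labels = measure.label(sub, connectivity=2)
        cands: list[tuple[int, np.ndarray, np.ndarray]] = []  # (area, rows, cols)
        for region in measure.regionprops(labels):
            rows = region.coords[:, 0] + r0
            cols = region.coords[:, 1] + c0
            if _component_extent_mmhg(rows, tpl) <= stroke_max_mmhg:
                if region.area >= min_blob_px:
                    cands.append((int(region.area), rows, cols))
            else:
                # tall component: try to split mark from stroke by opening
                opened = morphology.binary_opening(
                    labels == region.label, morphology.disk(open_radius)
                )
                for sr in measure.regionprops(measure.label(opened, connectivity=2)):
                    rows2 = sr.coords[:, 0] + r0
                    cols2 = sr.coords[:, 1] + c0
                    if (
                        sr.area >= min_blob_px
                        and _component_extent_mmhg(rows2, tpl) <= stroke_max_mmhg
                    ):
                        cands.append((int(sr.area), rows2, cols2))
        if not cands:
            continue
        cands.sort(key=lambda c: -c[0])
        for rank, (area, rows, cols) in enumerate(cands):
            near = np.abs(cols - line.x_px) <= 4
            y_read = float(np.median(rows[near])) if near.sum() >= 5 else float(rows.mean())
            y_read = float(np.clip(y_read, tpl.y_top_px, tpl.y_bottom_px))
            entries.append(
                DetectedEntry(
                    eye=eye,
                    slot=line.slot,
                    value_mmhg=round(tpl.pixel_to_value(y_read), 1),
                    pixel=(float(line.x_px), y_read),
                    blob_area=area,
                    flag="" if rank == 0 else "extra",
                )
            )
    entries.sort(key=lambda e: (e.slot[0], SLOT_TIMES.index(e.slot[1]), e.flag))
    return entries
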