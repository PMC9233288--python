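"""Shared dataclasses passed between pipeline stages."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .template import ChartTemplate, Slot


@dataclass
class RawScan:
    """An unprocessed scanned page: RGB raster plus provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source_id: str = ""
    dpi_hint: Optional[float] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("scan must be an RGB (H, W, 3) raster")
        if p.shape[0] < 200 or p.shape[1] < 200:
            raise ValueError("scan too small: need at least 200x200 pixels")
        self.pixels = p


@dataclass(frozen=True)
class Quadrilateral:
    """Four corner points in scan pixel coordinates, clockwise from top-left."""

    corners: tuple[tuple[float, float], ...]  # ((x, y), ...) length 4

    def __post_init__(self) -> None:
        if len(self.corners) != 4:
            raise ValueError("a quadrilateral has exactly 4 corners")

    @property
    def area(self) -> float:
        xs = np.array([c[0] for c in self.corners])
        ys = np.array([c[1] for c in self.corners])
        return 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))


@dataclass
class CanonicalChart:
    """A chart warped onto the template's canonical raster."""

    pixels: np.ndarray  # (template H, template W, 3) uint8
    transform: object  # projective transform canonical -> source scan
    template: ChartTemplate

    def __post_init__(self) -> None:
        h, w = self.pixels.shape[:2]
        if (w, h) != (self.template.canonical_width, self.template.canonical_height):
            raise ValueError("canonical chart size must equal the template size")


@dataclass(frozen=True)
class TimeLine:
    """A detected vertical gridline assigned to a measurement slot."""

    x_px: float
    slot: Slot
    support: float  # accumulator votes behind the line


@dataclass(frozen=True)
class DetectedEntry:
    """One colored mark read off the chart (or one truth/simulated value)."""

    eye: str  # "OD" (blue, right) or "OS" (red, left)
    slot: Slot
    value_mmhg: float
    pixel: Optional[tuple[float, float]] = None  # (x, y) canonical px
    blob_area: int = 0
    flag: str = ""  # "" = primary detection, "extra" = surplus blob at the slot

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError("eye must be 'OD' or 'OS'")
        if self.value_mmhg < 0:
            raise ValueError("IOP cannot be negative")


@dataclass
class IOPProfile:
    """All measurements of one patient examination."""

    patient_id: str
    entries: list[DetectedEntry] = field(default_factory=list)
    exam_date: Optional[_dt.date] = None

    def for_eye(self, eye: str) -> list[DetectedEntry]:
        return [e for e in self.entries if e.eye == eye]


@dataclass
class GroundTruth:
    """What the synthetic renderer actually plotted, for evaluation."""

    patient_id: str
    entries: list[DetectedEntry] = field(default_factory=list)  # flag == "" truth marks
    exam_date: Optional[_dt.date] = None
    patient_name: str = ""
    # nominal canonical pixel of each plotted mark, filled in by the renderer
    pixel_positions: dict[tuple[str, Slot], tuple[float, float]] = field(default_factory=dict)

    def for_eye(self, eye: str) -> list[DetectedEntry]:
        return [e for e in self.entries if e.eye == eye]
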