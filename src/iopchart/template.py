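"""Geometry of the standard German 24-hour IOP chart form.

The form is a printed frame containing a grid: a nonlinear time axis
(measurement slots at 10:00, 14:00, 17:00, 21:00 and midnight, repeated
for up to six consecutive days, with uneven spacing because the slots
are unevenly spaced in time) and a nonlinear pressure axis that is
linear from 0 to 40 mmHg and compressed to half pixel density above
40 mmHg.  After the scan has been cropped and warped onto the canonical
raster defined here, every gridline, the header name label and the
handwritten date field sit at fixed pixel positions, so values can be
read off directly from pixel coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .errors import RangeError

#: Measurement slots of one chart day, in chart order.  Midnight is drawn
#: at the end of the day's band (it is the last measurement of that
#: inpatient day, taken supine with a handheld tonometer).
SLOT_TIMES: tuple[str, ...] = ("10:00", "14:00", "17:00", "21:00", "00:00")

#: Clock hour of each slot on a 24 h circle, with midnight counted as 24
#: so the sequence is increasing within a day.
SLOT_HOURS: tuple[float, ...] = (10.0, 14.0, 17.0, 21.0, 24.0)

#: Slots available during regular outpatient office hours.
OUTPATIENT_SLOTS: tuple[str, ...] = ("10:00", "14:00", "17:00")

Slot = tuple[int, str]  # (day_index, clock_time)


@dataclass(frozen=True)
class ChartTemplate:
    """Canonical pixel geometry of the IOP form.

    Parameters
    ----------
    canonical_width, canonical_height:
        Size of the canonical raster in pixels.  1800x1200 gives integral
        pixel spacing for every gridline of the template.
    y_anchors:
        ``(mmHg, y_px)`` knots of the piecewise-linear pressure axis.
        Default: 0 mmHg at y=1150, 40 mmHg at y=510 (16 px/mmHg) and
        80 mmHg at y=190 (8 px/mmHg, the compressed upper range).
    day_origin_x, day_width:
        x position of the first day's 10:00 gridline and the horizontal
        band width allotted to each day.
    slot_offsets_px:
        x offsets of the five slots within a day band; uneven because the
        slots are 4, 3, 4 and 3 hours apart.
    """

    canonical_width: int = 1800
    canonical_height: int = 1200
    y_anchors: tuple[tuple[float, float], ...] = (
        (0.0, 1150.0),
        (40.0, 510.0),
        (80.0, 190.0),
    )
    day_origin_x: float = 170.0
    day_width: float = 260.0
    slot_offsets_px: tuple[float, ...] = (0.0, 68.0, 120.0, 188.0, 240.0)
    days: int = 6
    header_region: tuple[int, int, int, int] = (40, 20, 560, 140)  # x0, y0, x1, y1
    date_region: tuple[int, int, int, int] = (620, 30, 1060, 130)

    def __post_init__(self) -> None:
        mmhg = [a[0] for a in self.y_anchors]
        ypx = [a[1] for a in self.y_anchors]
        if sorted(mmhg) != mmhg:
            raise ValueError("y_anchors must be sorted by mmHg")
        if sorted(ypx, reverse=True) != ypx:
            raise ValueError("y axis must be strictly monotone (higher mmHg, smaller y)")
        xs = [x for _, _, x in self.iter_slots()]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("time-slot x positions must be strictly increasing")

    # -- time axis -----------------------------------------------------

    def slot_x(self, day_index: int, clock_time: str) -> float:
        """Nominal x pixel of a slot's vertical gridline."""
        if not 0 <= day_index < self.days:
            raise RangeError(f"day_index {day_index} outside 0..{self.days - 1}")
        try:
            i = SLOT_TIMES.index(clock_time)
        except ValueError as exc:
            raise RangeError(f"unknown clock time {clock_time!r}") from exc
        return self.day_origin_x + day_index * self.day_width + self.slot_offsets_px[i]

    def iter_slots(self, days: int | None = None) -> Iterator[tuple[int, str, float]]:
        """Yield ``(day_index, clock_time, x_px)`` in chart (left-to-right) order."""
        for d in range(self.days if days is None else days):
            for i, t in enumerate(SLOT_TIMES):
                yield d, t, self.day_origin_x + d * self.day_width + self.slot_offsets_px[i]

    # -- pressure axis -------------------------------------------------

    @property
    def y_max_mmhg(self) -> float:
        return self.y_anchors[-1][0]

    @property
    def y_top_px(self) -> float:
        """y pixel of the highest drawable pressure."""
        return self.y_anchors[-1][1]

    @property
    def y_bottom_px(self) -> float:
        """y pixel of the 0 mmHg baseline."""
        return self.y_anchors[0][1]

    def value_to_pixel(self, mmhg: float) -> float:
        """Map a pressure to its y pixel on the canonical raster."""
        if not 0.0 <= mmhg <= self.y_max_mmhg:
            raise RangeError(f"{mmhg} mmHg outside drawable range 0..{self.y_max_mmhg}")
        v = np.array([a[0] for a in self.y_anchors])
        y = np.array([a[1] for a in self.y_anchors])
        return float(np.interp(mmhg, v, y))

    def pixel_to_value(self, y_px: float) -> float:
        """Map a y pixel back to mmHg (strictly decreasing in ``y_px``)."""
        if not self.y_top_px <= y_px <= self.y_bottom_px:
            raise RangeError(
                f"y={y_px} outside drawable band {self.y_top_px}..{self.y_bottom_px}"
            )
        # interp needs increasing sample points: reverse both knot arrays
        v = np.array([a[0] for a in self.y_anchors])[::-1]
        y = np.array([a[1] for a in self.y_anchors])[::-1]
        return float(np.interp(y_px, y, v))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChartTemplate":
        d = dict(d)
        if "y_anchors" in d:
            d["y_anchors"] = tuple(tuple(a) for a in d["y_anchors"])
        for k in ("slot_offsets_px", "header_region", "date_region"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChartTemplate":
        """Load a template from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        d = self.to_dict()
        if p.suffix in (".yml", ".yaml"):
            p.write_text(yaml.safe_dump(d))
        else:
            p.write_text(json.dumps(d, indent=2))


DEFAULT_TEMPLATE = ChartTemplate()
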