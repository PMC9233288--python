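"""Header metadata: handwritten examination date and printed patient name.

The date field is segmented into connected components, separated into
digits and delimiters by a size/aspect rule, classified digit by digit
and assembled into a ``day.month.year`` date (German convention).  The
machine-printed name label goes through an external OCR engine exposed
behind a small interface; the engine itself is deliberately not part of
this package, only the regular-expression name extraction applied to
its text output.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np
from skimage import measure

from .digits import DigitClassifier, classify_digit
from .errors import DateInvalid, DateNotFound, OCRUnavailable
from .preprocess import to_grayscale
from .template import ChartTemplate
from .types import CanonicalChart

__all__ = [
    "DigitRegion",
    "DateResult",
    "NameResult",
    "segment_date_digits",
    "parse_date",
    "read_date",
    "extract_names",
    "OCREngine",
    "TesseractOCR",
    "NullOCR",
    "read_header_text",
    "pseudonymize",
]


@dataclass(frozen=True)
class DigitRegion:
    """One connected component of ink inside the date field."""

    box: tuple[int, int, int, int]  # x0, y0, x1, y1 in canonical px
    glyph: np.ndarray  # binary raster of the component
    role: str  # "digit" or "delimiter"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DateResult:
    date: _dt.date
    digit_confidences: tuple[float, ...]


@dataclass(frozen=True)
class NameResult:
    raw_text: str
    candidates: tuple[tuple[str, str], ...]  # (surname, given name)


def segment_date_digits(
    chart: CanonicalChart,
    template: ChartTemplate | None = None,
    ink_threshold: int = 128,
    min_area: int = 6,
) -> list[DigitRegion]:
    """Connected-component segmentation of the handwritten date field.

    Components are ordered left to right.  A component is labeled
    ``delimiter`` if its area is below 25% of the median digit-sized
    component area or its aspect ratio is flatter than 1:2; everything
    else is a ``digit``.  A digit wider than 1.6x the median digit width
    is flagged ``double-width`` (two touching digits merged into one
    component).
    """
    tpl = template or chart.template
    x0, y0, x1, y1 = tpl.date_region
    gray = to_grayscale(chart.pixels[y0:y1, x0:x1])
    ink = gray < ink_threshold
    labels = measure.label(ink, connectivity=2)
    regions = [r for r in measure.regionprops(labels) if r.area >= min_area]
    if not regions:
        raise DateNotFound("no ink in the date field")
    regions.sort(key=lambda r: r.bbox[1])

    heights = np.array([r.bbox[2] - r.bbox[0] for r in regions])
    tall = heights >= 0.5 * heights.max()
    med_area = float(np.median([r.area for r, t in zip(regions, tall) if t]))
    med_width = float(np.median([r.bbox[3] - r.bbox[1] for r, t in zip(regions, tall) if t]))

    out: list[DigitRegion] = []
    for r in regions:
        rr0, cc0, rr1, cc1 = r.bbox
        w, h = cc1 - cc0, rr1 - rr0
        is_delim = r.area < 0.25 * med_area or (h > 0 and w / h > 2.0)
        flags: tuple[str, ...] = ()
        if not is_delim and w > 1.6 * med_width:
            flags = ("double-width",)
        out.append(
            DigitRegion(
                box=(x0 + cc0, y0 + rr0, x0 + cc1, y0 + rr1),
                glyph=(labels[rr0:rr1, cc0:cc1] == r.label),
                role="delimiter" if is_delim else "digit",
                flags=flags,
            )
        )
    return out


def _expand_two_digit_year(yy: int, year_range: tuple[int, int]) -> int:
    for century in (1900, 2000):
        y = century + yy
        if year_range[0] <= y <= year_range[1]:
            return y
    raise DateInvalid(f"two-digit year {yy:02d} has no expansion in {year_range}")


def parse_date(
    regions: list[DigitRegion],
    predictions: list[int],
    confidences: Optional[list[float]] = None,
    year_range: tuple[int, int] = (1950, 2030),
) -> DateResult:
    """Assemble classified digits into a day.month.year calendar date.

    Digits are grouped at the delimiter positions; with no delimiters, a
    6- or 8-digit run is split 2/2/2 or 2/2/4.  Two-digit years are
    expanded into ``year_range``.  Illegal dates raise
    :class:`DateInvalid`.
    """
    digit_idx = [i for i, r in enumerate(regions) if r.role == "digit"]
    if len(predictions) != len(digit_idx):
        raise ValueError("predictions must align with the digit regions")

    groups: list[list[int]] = [[]]
    pred_iter = iter(predictions)
    n_delims = 0
    for r in regions:
        if r.role == "delimiter":
            n_delims += 1
            if n_delims > 2:
                raise DateInvalid("more than two delimiters in the date field")
            if groups[-1]:
                groups.append([])
        else:
            groups[-1].append(next(pred_iter))
    groups = [g for g in groups if g]

    if len(groups) == 1:
        run = groups[0]
        if len(run) == 6:
            groups = [run[0:2], run[2:4], run[4:6]]
        elif len(run) == 8:
            groups = [run[0:2], run[2:4], run[4:8]]
        else:
            raise DateInvalid(f"cannot split an undelimited run of {len(run)} digits")
    if len(groups) != 3:
        raise DateInvalid(f"expected day.month.year groups, got {len(groups)} groups")

    def as_int(ds: list[int]) -> int:
        return int("".join(str(d) for d in ds))

    day, month = as_int(groups[0]), as_int(groups[1])
    year = as_int(groups[2])
    if len(groups[2]) <= 2:
        year = _expand_two_digit_year(year, year_range)
    if not year_range[0] <= year <= year_range[1]:
        raise DateInvalid(f"year {year} outside plausible range {year_range}")
    try:
        date = _dt.date(year, month, day)
    except ValueError as exc:
        raise DateInvalid(f"not a legal calendar date: {day:02d}.{month:02d}.{year}") from exc
    return DateResult(date=date, digit_confidences=tuple(confidences or []))


def read_date(
    chart: CanonicalChart,
    template: ChartTemplate | None = None,
    classifier: DigitClassifier | None = None,
) -> DateResult:
    """Segment, classify and parse the handwritten date in one call."""
    regions = segment_date_digits(chart, template)
    preds, confs = [], []
    for r in regions:
        if r.role == "digit":
            d, c = classify_digit(r.glyph, classifier)
            preds.append(d)
            confs.append(c)
    return parse_date(regions, preds, confs)


# -- patient name ------------------------------------------------------

# Capitalized surname, comma, capitalized given name; umlauts/diacritics
# allowed anywhere, hyphenated parts allowed.
_WORD = r"[^\W\d_](?:[^\W\d_]|[-'])*"
_NAME_PATTERN = re.compile(rf"({_WORD})\s*,\s*({_WORD})", re.UNICODE)


def extract_names(ocr_text: str, pattern: re.Pattern | None = None) -> NameResult:
    """Find ``Surname, Givenname`` patterns in OCR output.

    Both parts must start with an uppercase letter (including non-ASCII
    uppercase such as umlauts) followed by lowercase; matches are
    returned in reading order.  An empty candidate list is a valid
    result.
    """
    pat = pattern or _NAME_PATTERN
    cands = []
    for m in pat.finditer(ocr_text):
        surname, given = m.group(1), m.group(2)
        ok = all(
            part[0].isupper() and (len(part) == 1 or not part[1:].isupper())
            for part in (surname, given)
        )
        if ok:
            cands.append((surname, given))
    return NameResult(raw_text=ocr_text, candidates=tuple(cands))


class OCREngine(Protocol):
    """External optical-character-recognition backend."""

    def image_to_text(self, image: np.ndarray) -> str: ...


class NullOCR:
    """Fallback engine returning no text (name extraction then yields none)."""

    def image_to_text(self, image: np.ndarray) -> str:
        return ""


class TesseractOCR:
    """Adapter for the Tesseract engine via pytesseract, if installed."""

    def __init__(self, lang: str = "deu") -> None:
        try:
            import pytesseract  # noqa: F401
        except ImportError as exc:
            raise OCRUnavailable("pytesseract is not installed") from exc
        self._pt = pytesseract
        self.lang = lang

    def image_to_text(self, image: np.ndarray) -> str:
        from PIL import Image

        return self._pt.image_to_string(Image.fromarray(image), lang=self.lang)


def read_header_text(
    chart: CanonicalChart,
    engine: OCREngine,
    template: ChartTemplate | None = None,
) -> NameResult:
    """Run OCR on the header band and extract name candidates."""
    tpl = template or chart.template
    x0, y0, x1, y1 = tpl.header_region
    text = engine.image_to_text(chart.pixels[y0:y1, x0:x1])
    return extract_names(text)


def pseudonymize(surname: str, given: str) -> str:
    """Stable non-reversible identifier for a patient name."""
    import hashlib

    h = hashlib.sha256(f"{surname}|{given}".encode("utf-8")).hexdigest()
    return f"pt-{h[:12]}"
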