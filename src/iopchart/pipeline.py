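"""End-to-end digitization of one scanned chart."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .digits import DigitClassifier
from .errors import IOPChartError
from .extract import color_mask, detect_time_lines, extract_entries
from .metadata import (
    DateResult,
    NameResult,
    NullOCR,
    OCREngine,
    pseudonymize,
    read_date,
    read_header_text,
)
from .preprocess import binarize_adaptive, crop_to_canonical, find_main_frame, to_grayscale
from .template import ChartTemplate, DEFAULT_TEMPLATE
from .types import CanonicalChart, IOPProfile, RawScan


@dataclass
class ExtractionResult:
    """Everything one chart yields: profile, metadata, review flags."""

    profile: IOPProfile
    chart: CanonicalChart
    date_result: Optional[DateResult] = None
    name_result: Optional[NameResult] = None
    review_flags: list[str] = field(default_factory=list)


def extract_chart(
    scan: RawScan,
    template: ChartTemplate = DEFAULT_TEMPLATE,
    classifier: DigitClassifier | None = None,
    ocr: OCREngine | None = None,
    read_metadata: bool = True,
    pseudonymize_names: bool = True,
    confidence_floor: float = 0.8,
) -> ExtractionResult:
    """Run preprocess -> extraction -> metadata on one scan.

    Rows needing manual review (surplus blobs, low-confidence or failed
    metadata) are collected in ``review_flags`` — the headless
    replacement for an interactive correction interface.
    """
    gray = to_grayscale(scan.pixels)
    binary = binarize_adaptive(gray)
    frame = find_main_frame(binary)
    chart = crop_to_canonical(scan, frame, template)

    lines = detect_time_lines(chart)
    entries = [
        e
        for eye in ("OD", "OS")
        for e in extract_entries(chart, lines, eye, mask=color_mask(chart, eye))
    ]

    flags = [f"{e.eye}@{e.slot[0]}/{e.slot[1]}: extra blob" for e in entries if e.flag]

    patient_id = scan.source_id or "unknown"
    exam_date = None
    date_result = name_result = None
    if read_metadata:
        try:
            date_result = read_date(chart, template, classifier)
            exam_date = date_result.date
            if date_result.digit_confidences and min(date_result.digit_confidences) < confidence_floor:
                flags.append("date: low-confidence digit")
        except IOPChartError as exc:
            flags.append(f"date: {exc}")
        name_result = read_header_text(chart, ocr or NullOCR(), template)
        if name_result.candidates:
            surname, given = name_result.candidates[0]
            patient_id = pseudonymize(surname, given) if pseudonymize_names else f"{surname}, {given}"
        else:
            flags.append("name: no candidate found")

    profile = IOPProfile(patient_id=patient_id, entries=entries, exam_date=exam_date)
    return ExtractionResult(
        profile=profile,
        chart=chart,
        date_result=date_result,
        name_result=name_result,
        review_flags=flags,
    )
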