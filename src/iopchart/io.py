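"""Reading scans and writing/reading the entry CSV schema.

One CSV row per detected (or truth) entry:
``patient_id, exam_date, eye, day_index, clock_time, iop_mmhg, x_px,
y_px, blob_area, flag`` — truth files carry two extra columns
``true_x_px, true_y_px`` with the nominal render positions.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InputError
from .types import DetectedEntry, GroundTruth, IOPProfile, RawScan

CSV_COLUMNS = [
    "patient_id", "exam_date", "eye", "day_index", "clock_time",
    "iop_mmhg", "x_px", "y_px", "blob_area", "flag",
]


def read_scan(path: str | Path, dpi_hint: float | None = None) -> RawScan:
    """Load a PNG/TIFF/JPEG scan as an RGB raster."""
    try:
        img = Image.open(path).convert("RGB")
    except Exception as exc:  # unreadable / not an image
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return RawScan(pixels=np.asarray(img, dtype=np.uint8), source_id=str(path), dpi_hint=dpi_hint)


def write_canonical_png(chart_pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(chart_pixels).save(path)


def _entry_row(pid: str, date, e: DetectedEntry) -> dict:
    return {
        "patient_id": pid,
        "exam_date": date.isoformat() if date else "",
        "eye": e.eye,
        "day_index": e.slot[0],
        "clock_time": e.slot[1],
        "iop_mmhg": e.value_mmhg,
        "x_px": round(e.pixel[0], 2) if e.pixel else "",
        "y_px": round(e.pixel[1], 2) if e.pixel else "",
        "blob_area": e.blob_area,
        "flag": e.flag,
    }


def profile_to_frame(profile: IOPProfile) -> pd.DataFrame:
    rows = [_entry_row(profile.patient_id, profile.exam_date, e) for e in profile.entries]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    df = pd.DataFrame(
        [_entry_row(truth.patient_id, truth.exam_date, e) for e in truth.entries],
        columns=CSV_COLUMNS,
    )
    tx, ty = [], []
    for e in truth.entries:
        pos = truth.pixel_positions.get((e.eye, e.slot))
        tx.append(round(pos[0], 2) if pos else "")
        ty.append(round(pos[1], 2) if pos else "")
    df["true_x_px"] = tx
    df["true_y_px"] = ty
    return df


def frame_to_profiles(df: pd.DataFrame) -> list[IOPProfile]:
    """Group a CSV frame back into per-patient profiles."""
    profiles = []
    for pid, g in df.groupby("patient_id", sort=True):
        date = None
        ds = str(g["exam_date"].iloc[0])
        if ds and ds not in ("nan", "NaT"):
            try:
                date = _dt.date.fromisoformat(ds)
            except ValueError:
                date = None
        entries = [
            DetectedEntry(
                eye=r.eye,
                slot=(int(r.day_index), str(r.clock_time)),
                value_mmhg=float(r.iop_mmhg),
                blob_area=int(r.blob_area) if not pd.isna(r.blob_area) else 0,
                flag="" if pd.isna(r.flag) else str(r.flag),
            )
            for r in g.itertuples()
        ]
        profiles.append(IOPProfile(patient_id=str(pid), entries=entries, exam_date=date))
    return profiles


def read_profiles_csv(path: str | Path) -> list[IOPProfile]:
    return frame_to_profiles(pd.read_csv(path, keep_default_na=False))
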