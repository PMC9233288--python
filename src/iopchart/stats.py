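"""Clinical statistics on 24-hour IOP profiles.

Implements the summary quantities used in nycthemeral IOP studies —
T_max, T_min, T_avg, IOP_var = T_max - T_min, the acrophase (slot of
peak IOP), mean ocular perfusion pressure MOPP = (2/3)(MAP - T_avg) —
plus acrophase-aligned mean curves, cutoff contingency analysis
(sensitivity/specificity of a T_max or IOP_var threshold for disease
progression) and ROC curves.  The "outpatient" slot filter restricts a
profile to the office-hours measurements (10:00, 14:00, 17:00), which
lets 24-hour and outpatient diagnostic performance be compared on the
same patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics

from .errors import EmptyProfile, InputError, ROCUndefined
from .template import OUTPATIENT_SLOTS, SLOT_TIMES
from .types import IOPProfile

__all__ = [
    "ProfileSummary",
    "PerfusionRecord",
    "DiagnosticResult",
    "ROCCurve",
    "summarize_profile",
    "compute_mopp",
    "align_acrophases",
    "mean_curve",
    "cutoff_contingency",
    "roc_curve",
    "exclude_low_variation",
]


@dataclass(frozen=True)
class ProfileSummary:
    t_max: float
    t_min: float
    t_avg: float
    iop_var: float
    acrophase_slot: str  # clock time of the peak, ties -> earliest slot
    n_measurements: int


@dataclass(frozen=True)
class PerfusionRecord:
    systolic: float
    diastolic: float
    map_mmhg: float
    mopp: float


@dataclass(frozen=True)
class DiagnosticResult:
    cutoff: float
    statistic: str  # "t_max" or "iop_var"
    slot_set: str  # "24h" or "outpatient"
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ROCCurve:
    fpr: tuple[float, ...]  # 1 - specificity, nondecreasing from 0 to 1
    tpr: tuple[float, ...]  # sensitivity
    thresholds: tuple[float, ...]
    auc: float


def _slot_filter_times(slot_set: str) -> tuple[str, ...]:
    if slot_set == "24h":
        return SLOT_TIMES
    if slot_set == "outpatient":
        return OUTPATIENT_SLOTS
    raise ValueError("slot_set must be '24h' or 'outpatient'")


def summarize_profile(
    profile: IOPProfile, eye: str = "OD", slot_set: str = "24h"
) -> ProfileSummary:
    """Max, min, mean, range and acrophase of one eye's profile.

    The acrophase is the clock time at which the peak IOP of the session
    was reached; on ties the earliest slot in chart order wins.
    """
    keep = _slot_filter_times(slot_set)
    entries = [e for e in profile.for_eye(eye) if e.slot[1] in keep]
    if not entries:
        raise EmptyProfile(f"no {eye} measurements after the {slot_set} filter")
    entries.sort(key=lambda e: (e.slot[0], SLOT_TIMES.index(e.slot[1])))
    values = np.array([e.value_mmhg for e in entries])
    peak = entries[int(np.argmax(values))]  # argmax returns the first maximum
    return ProfileSummary(
        t_max=float(values.max()),
        t_min=float(values.min()),
        t_avg=float(values.mean()),
        iop_var=float(values.max() - values.min()),
        acrophase_slot=peak.slot[1],
        n_measurements=len(values),
    )


def compute_mopp(systolic: float, diastolic: float, t_avg: float) -> PerfusionRecord:
    """Mean ocular perfusion pressure from a brachial blood pressure.

    MAP is estimated as diastolic + pulse pressure / 3, and
    MOPP = (2/3)(MAP - T_avg).
    """
    if not 0 < diastolic < systolic:
        raise InputError("need 0 < diastolic < systolic")
    map_mmhg = diastolic + (systolic - diastolic) / 3.0
    return PerfusionRecord(
        systolic=systolic,
        diastolic=diastolic,
        map_mmhg=map_mmhg,
        mopp=(2.0 / 3.0) * (map_mmhg - t_avg),
    )


def _profile_values(profile: IOPProfile, eye: str) -> np.ndarray | None:
    by_time = {e.slot[1]: e.value_mmhg for e in profile.for_eye(eye)}
    if len(by_time) < 2:
        return None
    if set(by_time) != set(SLOT_TIMES):
        return None
    return np.array([by_time[t] for t in SLOT_TIMES])


def align_acrophases(
    profiles: list[IOPProfile], eye: str = "OD", reference_slot: str = "10:00"
) -> dict[str, tuple[float, float]]:
    """Per-slot mean +/- SD after shifting all peaks onto one slot.

    Each profile's five-slot sequence is rotated circularly so its
    acrophase lands on ``reference_slot``, then slots are averaged
    across profiles.  Profiles without a full day of measurements are
    skipped with a warning.
    """
    ref = SLOT_TIMES.index(reference_slot)
    rows = []
    for p in profiles:
        values = _profile_values(p, eye)
        if values is None:
            warnings.warn(f"profile {p.patient_id}: too few slots, skipped", stacklevel=2)
            continue
        rows.append(np.roll(values, ref - int(np.argmax(values))))
    if not rows:
        raise EmptyProfile("no complete profiles to align")
    arr = np.array(rows)
    return {
        t: (float(arr[:, i].mean()), float(arr[:, i].std(ddof=1)) if len(arr) > 1 else 0.0)
        for i, t in enumerate(SLOT_TIMES)
    }


def mean_curve(profiles: list[IOPProfile], eye: str = "OD") -> dict[str, tuple[float, float]]:
    """Observed (unshifted) per-slot mean +/- SD across profiles."""
    rows = [v for p in profiles if (v := _profile_values(p, eye)) is not None]
    if not rows:
        raise EmptyProfile("no complete profiles")
    arr = np.array(rows)
    return {
        t: (float(arr[:, i].mean()), float(arr[:, i].std(ddof=1)) if len(arr) > 1 else 0.0)
        for i, t in enumerate(SLOT_TIMES)
    }


def cutoff_contingency(
    summaries: list[ProfileSummary],
    labels: list[bool],
    cutoff: float,
    statistic: str = "t_max",
    slot_set: str = "24h",
) -> DiagnosticResult:
    """2x2 contingency of (statistic > cutoff) against progression labels.

    Test-positivity uses strict inequality.  If all labels are the same
    class, the undefined rate is reported as NaN with a warning.
    """
    if len(summaries) != len(labels):
        raise InputError("summaries and labels must align by patient")
    if statistic not in ("t_max", "iop_var"):
        raise ValueError("statistic must be 't_max' or 'iop_var'")
    values = np.array([getattr(s, statistic) for s in summaries])
    y = np.array(labels, dtype=bool)
    pos = values > cutoff
    tp = int(np.sum(pos & y))
    fp = int(np.sum(pos & ~y))
    tn = int(np.sum(~pos & ~y))
    fn = int(np.sum(~pos & y))
    if tp + fn == 0:
        warnings.warn("no progressors: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no nonprogressors: specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return DiagnosticResult(
        cutoff=cutoff, statistic=statistic, slot_set=slot_set,
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec,
    )


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve and trapezoid AUC over all score thresholds.

    Equal scores are grouped into a single threshold step.  Raises
    :class:`ROCUndefined` unless both classes are present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ROCUndefined("need at least one positive and one negative label")
    fpr, tpr, thr = skmetrics.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(
        fpr=tuple(map(float, fpr)),
        tpr=tuple(map(float, tpr)),
        thresholds=tuple(map(float, thr)),
        auc=float(skmetrics.auc(fpr, tpr)),
    )


def exclude_low_variation(
    summaries: list[ProfileSummary], labels: list[bool], threshold: float = 5.0
) -> tuple[list[ProfileSummary], list[bool]]:
    """Drop patients whose IOP_var is below ``threshold`` mmHg.

    Mirrors the convention of analyzing only clinically notable
    nycthemeral variation (variations above 5 mmHg were historically
    read as a progression signal).
    """
    kept = [(s, l) for s, l in zip(summaries, labels) if s.iop_var >= threshold]
    if not kept:
        return [], []
    ss, ll = zip(*kept)
    return list(ss), list(ll)
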