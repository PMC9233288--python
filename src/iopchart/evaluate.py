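"""Accuracy metrics for detected entries against ground truth.

A detection matches a truth entry iff it has the same eye and the same
time slot; at most one detection matches per truth entry (the one whose
value is nearest wins), surplus detections are false positives and
missed truth entries are false negatives.  Aggregated over a chart set,
the report carries the four headline numbers of a digitization
benchmark: false-positive rate, false-negative rate, mean absolute
value distance (mmHg) and mean relative error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EvalError
from .types import DetectedEntry, GroundTruth

__all__ = ["Matching", "EvalReport", "match_entries", "compute_eval_report", "report_from_counts"]


@dataclass
class Matching:
    """Per-curve (one chart, one eye) matching outcome."""

    matches: list[tuple[DetectedEntry, float]] = field(default_factory=list)  # (det, truth value)
    false_positives: list[DetectedEntry] = field(default_factory=list)
    false_negatives: list[DetectedEntry] = field(default_factory=list)  # missed truth entries
    n_truth: int = 0
    n_detected: int = 0


@dataclass(frozen=True)
class EvalReport:
    n_curves: int
    mean_entries_per_eye: float
    fp_per_curve: float
    fn_per_curve: float
    fp_rate: float  # fraction, = fp_per_curve / mean_entries_per_eye
    fn_rate: float
    mean_distance: float  # mmHg over matched pairs
    mean_true_value: float
    mean_relative_error: float  # = mean_distance / mean_true_value

    def as_percent(self) -> dict:
        """The report with rates as percentages, rounded for display."""
        return {
            "n_curves": self.n_curves,
            "mean_entries_per_eye": round(self.mean_entries_per_eye, 2),
            "fp_per_curve": round(self.fp_per_curve, 4),
            "fn_per_curve": round(self.fn_per_curve, 4),
            "fp_rate_pct": round(100 * self.fp_rate, 2),
            "fn_rate_pct": round(100 * self.fn_rate, 2),
            "mean_distance_mmhg": round(self.mean_distance, 4),
            "mean_true_value_mmhg": round(self.mean_true_value, 2),
            "mean_relative_error_pct": round(100 * self.mean_relative_error, 2),
        }


def match_entries(detected: list[DetectedEntry], truth: GroundTruth | list[DetectedEntry],
                  eye: str | None = None) -> Matching:
    """Match detections to truth entries of the same chart.

    Matching is slot-exact: a detection can only match the truth entry
    at its own (eye, slot).  When several detections share a slot, the
    one with the smallest absolute value difference is the match and the
    rest are false positives — with a single truth entry per slot this
    greedy rule coincides with the optimal assignment.
    """
    truth_entries = truth.entries if isinstance(truth, GroundTruth) else truth
    if eye is not None:
        truth_entries = [e for e in truth_entries if e.eye == eye]
        detected = [e for e in detected if e.eye == eye]

    truth_by_slot: dict = {}
    for t in truth_entries:
        truth_by_slot[(t.eye, t.slot)] = t

    m = Matching(n_truth=len(truth_entries), n_detected=len(detected))
    claimed: set = set()
    by_slot: dict = {}
    for d in detected:
        by_slot.setdefault((d.eye, d.slot), []).append(d)

    for key, dets in by_slot.items():
        t = truth_by_slot.get(key)
        if t is None:
            m.false_positives.extend(dets)
            continue
        dets = sorted(dets, key=lambda d: abs(d.value_mmhg - t.value_mmhg))
        m.matches.append((dets[0], t.value_mmhg))
        m.false_positives.extend(dets[1:])
        claimed.add(key)
    for key, t in truth_by_slot.items():
        if key not in claimed:
            m.false_negatives.append(t)
    return m


def compute_eval_report(matchings: list[Matching]) -> EvalReport:
    """Aggregate per-curve matchings into the four accuracy metrics.

    Raises :class:`EvalError` when there are no matchings or no truth
    entries at all, since every rate would be undefined.
    """
    if not matchings:
        raise EvalError("no matchings to aggregate")
    n_curves = len(matchings)
    total_truth = sum(m.n_truth for m in matchings)
    if total_truth == 0:
        raise EvalError("zero ground-truth entries: rates undefined")
    total_fp = sum(len(m.false_positives) for m in matchings)
    total_fn = sum(len(m.false_negatives) for m in matchings)
    pairs = [p for m in matchings for p in m.matches]
    mean_entries = total_truth / n_curves
    mean_distance = (
        sum(abs(d.value_mmhg - tv) for d, tv in pairs) / len(pairs) if pairs else 0.0
    )
    mean_true = sum(tv for _, tv in pairs) / len(pairs) if pairs else float("nan")
    return report_from_counts(
        n_curves=n_curves,
        mean_entries_per_eye=mean_entries,
        fp_per_curve=total_fp / n_curves,
        fn_per_curve=total_fn / n_curves,
        mean_distance=mean_distance,
        mean_true_value=mean_true,
    )


def report_from_counts(
    n_curves: int,
    mean_entries_per_eye: float,
    fp_per_curve: float,
    fn_per_curve: float,
    mean_distance: float,
    mean_true_value: float,
) -> EvalReport:
    """Build a report from per-curve counts via the defining identities:
    ``fp_rate = fp_per_curve / mean_entries_per_eye`` (likewise FN) and
    ``mean_relative_error = mean_distance / mean_true_value``."""
    if mean_entries_per_eye <= 0:
        raise EvalError("mean entries per eye must be positive")
    return EvalReport(
        n_curves=n_curves,
        mean_entries_per_eye=mean_entries_per_eye,
        fp_per_curve=fp_per_curve,
        fn_per_curve=fn_per_curve,
        fp_rate=fp_per_curve / mean_entries_per_eye,
        fn_rate=fn_per_curve / mean_entries_per_eye,
        mean_distance=mean_distance,
        mean_true_value=mean_true_value,
        mean_relative_error=(
            mean_distance / mean_true_value if mean_true_value else float("nan")
        ),
    )
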