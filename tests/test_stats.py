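import numpy as np
import pytest

import iopchart as ic
from iopchart import stats as st
from iopchart.errors import EmptyProfile, InputError, ROCUndefined
from iopchart.synth import CohortConfig, simulate_cohort


def profile(values, eye="OD", pid="p"):
    entries = [
        ic.DetectedEntry(eye=eye, slot=(0, t), value_mmhg=float(v))
        for t, v in zip(ic.SLOT_TIMES, values)
    ]
    return ic.IOPProfile(patient_id=pid, entries=entries)


class TestSummarizeProfile:
    def test_worked_example(self):
        s = st.summarize_profile(profile((15, 18, 17, 14, 16)))
        assert (s.t_max, s.t_min, s.t_avg, s.iop_var) == (18, 14, 16, 4)
        assert s.acrophase_slot == "14:00"
        assert s.n_measurements == 5

    def test_constant_profile_tie_breaks_to_earliest_slot(self):
        s = st.summarize_profile(profile((16, 16, 16, 16, 16)))
        assert s.iop_var == 0
        assert s.acrophase_slot == "10:00"

    def test_outpatient_filter_keeps_office_hours(self):
        s = st.summarize_profile(profile((15, 18, 17, 14, 16)), slot_set="outpatient")
        assert (s.t_max, s.t_min) == (18, 15)
        assert s.n_measurements == 3

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            values = rng.uniform(5, 40, size=5).round(1)
            s = st.summarize_profile(profile(values))
            assert s.t_max == values.max()
            assert s.t_min == values.min()
            assert s.t_avg == pytest.approx(values.mean())
            assert s.iop_var == pytest.approx(values.max() - values.min())
            assert s.acrophase_slot == ic.SLOT_TIMES[int(np.argmax(values))]

    def test_empty_after_filter_raises(self):
        p = ic.IOPProfile(
            patient_id="x",
            entries=[ic.DetectedEntry(eye="OD", slot=(0, "21:00"), value_mmhg=15.0)],
        )
        with pytest.raises(EmptyProfile):
            st.summarize_profile(p, slot_set="outpatient")


class TestMOPP:
    def test_hand_arithmetic(self):
        rec = st.compute_mopp(120, 80, 15)
        assert rec.map_mmhg == pytest.approx(93.33, abs=0.01)
        assert rec.mopp == pytest.approx(52.22, abs=0.01)
        assert rec.diastolic < rec.map_mmhg < rec.systolic

    def test_zero_when_iop_equals_map(self):
        rec = st.compute_mopp(120, 80, 93.3333333)
        assert rec.mopp == pytest.approx(0.0, abs=1e-6)

    def test_linearity_slope_minus_two_thirds(self):
        a = st.compute_mopp(120, 80, 15).mopp
        b = st.compute_mopp(120, 80, 18).mopp
        assert a - b == pytest.approx(2.0)

    def test_inverted_pressures_rejected(self):
        with pytest.raises(InputError):
            st.compute_mopp(80, 120, 15)


class TestAlignAcrophases:
    def test_identity_when_all_peaks_at_reference(self):
        profiles = [profile((20, 15, 14, 13, 12)), profile((22, 16, 15, 14, 13))]
        aligned = st.align_acrophases(profiles)
        observed = st.mean_curve(profiles)
        for t in ic.SLOT_TIMES:
            assert aligned[t][0] == pytest.approx(observed[t][0])

    def test_aligned_curve_peaks_at_reference_slot(self):
        rng = np.random.default_rng(3)
        profiles = [
            profile(np.roll((21, 17, 15, 13, 14), rng.integers(5)) + rng.normal(0, 1, 5))
            for _ in range(30)
        ]
        aligned = st.align_acrophases(profiles, reference_slot="10:00")
        means = {t: m for t, (m, _) in aligned.items()}
        assert max(means, key=means.get) == "10:00"

    def test_alignment_sharpens_the_peak(self):
        """With spread acrophases the aligned peak exceeds the observed peak."""
        cohort = simulate_cohort(CohortConfig(n=150, seed=77))
        profiles = [p.profile for p in cohort]
        observed_peak = max(m for m, _ in st.mean_curve(profiles).values())
        aligned_peak = max(m for m, _ in st.align_acrophases(profiles).values())
        assert aligned_peak > observed_peak

    def test_incomplete_profiles_skipped_with_warning(self):
        good = profile((18, 15, 14, 13, 12))
        bad = ic.IOPProfile(
            patient_id="short",
            entries=[ic.DetectedEntry(eye="OD", slot=(0, "10:00"), value_mmhg=15.0)],
        )
        with pytest.warns(UserWarning):
            aligned = st.align_acrophases([good, bad])
        assert aligned["10:00"][0] == pytest.approx(18.0)


class TestCutoffContingency:
    def test_perfect_classifier(self):
        summaries = [st.summarize_profile(profile(v)) for v in
                     ((25, 24, 23, 22, 26), (26, 25, 24, 23, 27), (12, 11, 13, 10, 12))]
        labels = [True, True, False]
        d = st.cutoff_contingency(summaries, labels, cutoff=15.0)
        assert (d.sensitivity, d.specificity) == (1.0, 1.0)
        assert d.tp + d.fp + d.tn + d.fn == 3

    def test_four_patient_worked_set(self):
        """T_max (23, 14, 25, 16), labels (P, P, N, N), cutoff 22."""
        summaries = [st.summarize_profile(profile((v, v - 1, v - 2, v - 3, v - 2)))
                     for v in (23, 14, 25, 16)]
        labels = [True, True, False, False]
        d = st.cutoff_contingency(summaries, labels, cutoff=22.0)
        assert (d.tp, d.fn, d.fp, d.tn) == (1, 1, 1, 1)
        assert d.sensitivity == 0.5 and d.specificity == 0.5

    def test_strict_inequality_at_the_cutoff(self):
        summaries = [st.summarize_profile(profile((22, 20, 19, 18, 17)))]
        with pytest.warns(UserWarning):  # single-class toy labels
            d = st.cutoff_contingency(summaries, [True], cutoff=22.0)
        assert d.tp == 0 and d.fn == 1  # exactly at the cutoff is test-negative

    def test_outpatient_slot_set_changes_t_max(self):
        """Excluding evening/night slots can flip a positive to negative."""
        p = profile((14, 15, 14, 23, 16))  # peak at 21:00
        s24 = st.summarize_profile(p, slot_set="24h")
        sop = st.summarize_profile(p, slot_set="outpatient")
        with pytest.warns(UserWarning):  # single-class toy labels
            d24 = st.cutoff_contingency([s24], [True], cutoff=22.0, slot_set="24h")
            dop = st.cutoff_contingency([sop], [True], cutoff=22.0, slot_set="outpatient")
        assert d24.tp == 1 and dop.tp == 0

    def test_single_class_labels_warn_and_nan(self):
        summaries = [st.summarize_profile(profile((20, 19, 18, 17, 16)))]
        with pytest.warns(UserWarning):
            d = st.cutoff_contingency(summaries, [True], cutoff=15.0)
        assert np.isnan(d.specificity)
        assert d.sensitivity == 1.0


def manual_roc_auc(scores, labels):
    """Independent threshold-sweep oracle for the ROC area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pts = [(0.0, 0.0)]
    for thr in sorted(set(scores), reverse=True):
        pos = scores >= thr
        tpr = (pos & labels).sum() / labels.sum()
        fpr = (pos & ~labels).sum() / (~labels).sum()
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    return float(np.trapezoid([p[1] for p in pts], [p[0] for p in pts]))


class TestROC:
    def test_perfect_separation(self):
        roc = st.roc_curve([1, 1, 0, 0], [True, True, False, False])
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_reversed_scores_mirror_auc(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        a = st.roc_curve(scores, labels).auc
        b = st.roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_matches_manual_threshold_sweep(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            scores = rng.normal(size=30).round(1)  # ties on purpose
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any():
                continue
            assert st.roc_curve(scores, labels).auc == pytest.approx(
                manual_roc_auc(scores, labels)
            )

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(77)
        scores = rng.normal(size=1000)
        labels = rng.random(1000) < 0.42
        assert st.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(4)
        roc = st.roc_curve(rng.normal(size=50), rng.random(50) < 0.5)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_single_class_raises(self):
        with pytest.raises(ROCUndefined):
            st.roc_curve([1, 2, 3], [True, True, True])


def test_exclude_low_variation_filters_patients():
    summaries = [st.summarize_profile(profile(v)) for v in
                 ((20, 18, 16, 12, 14), (16, 15, 15, 14, 16))]  # var 8 and 2
    kept, labels = st.exclude_low_variation(summaries, [True, False], threshold=5.0)
    assert len(kept) == 1 and kept[0].iop_var == 8
    assert labels == [True]
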