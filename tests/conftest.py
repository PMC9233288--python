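import numpy as np
import pytest

import iopchart as ic
from iopchart import preprocess as pp
from iopchart.digits import get_default_classifier
from iopchart.synth import render_canonical
from iopchart.types import CanonicalChart


@pytest.fixture(scope="session")
def template():
    return ic.DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def classifier():
    """The default stroke-font digit classifier, trained once per session."""
    clf = get_default_classifier()
    clf.predict_proba(np.ones((28, 28), dtype=np.float32))  # force the lazy fit
    return clf


def make_truth(values_od, values_os=None, days=1, patient_id="t", exam_date=None, name=""):
    """GroundTruth from explicit per-slot values (one day unless given more)."""
    entries = []
    for eye, vals in (("OD", values_od), ("OS", values_os)):
        if vals is None:
            continue
        flat = list(vals)
        for d in range(days):
            for t, v in zip(ic.SLOT_TIMES, flat[d * 5 : (d + 1) * 5]):
                entries.append(ic.DetectedEntry(eye=eye, slot=(d, t), value_mmhg=float(v)))
    return ic.GroundTruth(
        patient_id=patient_id, entries=entries, exam_date=exam_date, patient_name=name
    )


def preprocess_scan(scan, template=ic.DEFAULT_TEMPLATE):
    """Scan -> canonical chart via the standard preprocessing chain."""
    binary = pp.binarize_adaptive(pp.to_grayscale(scan.pixels))
    frame = pp.find_main_frame(binary)
    return pp.crop_to_canonical(scan, frame, template)


def chart_from_canonical(pixels, template=ic.DEFAULT_TEMPLATE):
    """Wrap an already-canonical raster as a CanonicalChart (identity warp)."""
    return CanonicalChart(pixels=pixels, transform=None, template=template)


@pytest.fixture()
def clean_chart(template):
    """A noiseless canonical chart with a known OD profile."""
    truth = make_truth((15, 18, 17, 14, 16), exam_date=None)
    arr = render_canonical(truth, ic.RenderConfig.noiseless(seed=1), template)
    return chart_from_canonical(arr, template), truth
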