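"""Exception hierarchy for the chart-digitization pipeline."""


class IOPChartError(Exception):
    """Base class for all pipeline errors."""


class InputError(IOPChartError):
    """Invalid caller-supplied data (bad image, bad parameter combination)."""


class FrameNotFound(IOPChartError):
    """No contour large enough to be the chart's main frame."""


class FrameNotRectangular(IOPChartError):
    """The largest contour does not approximate a four-sided, near-right-angled shape."""


class CalibrationError(IOPChartError):
    """Too few time gridlines detected to calibrate the time axis."""


class RangeError(IOPChartError):
    """Pixel or value outside the chart template's drawable range."""


class DateNotFound(IOPChartError):
    """The date field of the header contains no ink."""


class DateInvalid(IOPChartError):
    """Recognized digits do not assemble into a legal calendar date."""


class ClassificationError(IOPChartError):
    """A glyph could not be classified (e.g. blank input)."""


class OCRUnavailable(IOPChartError):
    """No optical-character-recognition backend is installed."""


class EvalError(IOPChartError):
    """Evaluation metrics undefined (e.g. no ground-truth entries at all)."""


class EmptyProfile(IOPChartError):
    """An IOP profile has no measurements after filtering."""


class ROCUndefined(IOPChartError):
    """ROC analysis impossible: labels contain only one class."""


class SimulationError(IOPChartError):
    """Cohort simulation could not satisfy its constraints within the retry cap."""
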