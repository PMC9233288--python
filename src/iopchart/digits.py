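"""Handwriting-style digit rendering and the default digit classifier.

The examination date on the form is handwritten.  To keep the whole
pipeline reproducible without any external dataset, digits are drawn
from an in-repo stroke font (control polylines in a unit box) with
random affine wobble, and the default classifier is a multinomial
logistic regression fitted on those same renders.  The classifier is a
pluggable interface: anything with ``predict_proba`` over normalized
28x28 glyphs can be dropped in (e.g. a convolutional net trained on
MNIST), the stroke-font model is simply the dependency-free default.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from PIL import Image, ImageDraw
from sklearn.linear_model import LogisticRegression

from .errors import ClassificationError

__all__ = [
    "DIGIT_STROKES",
    "render_digit",
    "normalize_glyph",
    "DigitClassifier",
    "SyntheticDigitClassifier",
    "get_default_classifier",
    "classify_digit",
]

# control polylines per digit, (x, y) in a unit box with y growing downward
DIGIT_STROKES: dict[str, list[list[tuple[float, float]]]] = {
    "0": [[(0.5, 0.08), (0.24, 0.2), (0.18, 0.5), (0.24, 0.8), (0.5, 0.92),
           (0.76, 0.8), (0.82, 0.5), (0.76, 0.2), (0.5, 0.08)]],
    "1": [[(0.3, 0.28), (0.55, 0.08), (0.55, 0.92)]],
    "2": [[(0.2, 0.28), (0.3, 0.1), (0.65, 0.08), (0.8, 0.25), (0.75, 0.45),
           (0.2, 0.9), (0.82, 0.9)]],
    "3": [[(0.22, 0.12), (0.75, 0.1), (0.45, 0.42), (0.75, 0.55), (0.8, 0.75),
           (0.6, 0.92), (0.22, 0.85)]],
    "4": [[(0.68, 0.92), (0.68, 0.08), (0.18, 0.62), (0.85, 0.62)]],
    "5": [[(0.78, 0.1), (0.26, 0.1), (0.22, 0.45), (0.6, 0.4), (0.8, 0.58),
           (0.75, 0.82), (0.5, 0.92), (0.2, 0.84)]],
    "6": [[(0.68, 0.1), (0.36, 0.3), (0.22, 0.62), (0.32, 0.88), (0.62, 0.9),
           (0.78, 0.7), (0.64, 0.52), (0.3, 0.6)]],
    "7": [[(0.18, 0.1), (0.82, 0.1), (0.45, 0.92)]],
    "8": [[(0.5, 0.08), (0.28, 0.16), (0.3, 0.36), (0.5, 0.46), (0.72, 0.58),
           (0.72, 0.82), (0.5, 0.92), (0.28, 0.82), (0.3, 0.58), (0.5, 0.46),
           (0.7, 0.35), (0.7, 0.16), (0.5, 0.08)]],
    "9": [[(0.74, 0.4), (0.48, 0.5), (0.24, 0.38), (0.28, 0.14), (0.55, 0.06),
           (0.74, 0.2), (0.74, 0.4), (0.62, 0.92)]],
}


def render_digit(
    char: str,
    size: int = 40,
    rng: np.random.Generator | None = None,
    max_rotation_deg: float = 0.0,
    wobble: float = 0.0,
    stroke_width: int | None = None,
) -> np.ndarray:
    """Render one digit as a boolean ink mask of shape (size, size).

    ``wobble`` is the standard deviation (in unit-box coordinates) of
    Gaussian noise added to every control point, emulating hand shake;
    rotation is drawn uniformly within ``+/- max_rotation_deg``.
    """
    if char not in DIGIT_STROKES:
        raise ValueError(f"no stroke definition for {char!r}")
    rng = rng or np.random.default_rng()
    angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    scale = size * rng.uniform(0.78, 0.9) if wobble else size * 0.84
    width = stroke_width or max(2, int(round(size * rng.uniform(0.06, 0.11))))
    cx = cy = size / 2.0
    cos_a, sin_a = np.cos(angle), np.sin(angle)

    img = Image.new("L", (size, size), 255)
    draw = ImageDraw.Draw(img)
    for stroke in DIGIT_STROKES[char]:
        pts = np.asarray(stroke, dtype=float)
        if wobble:
            pts = pts + rng.normal(0, wobble, pts.shape)
        p = (pts - 0.5) * scale
        xr = p[:, 0] * cos_a - p[:, 1] * sin_a + cx
        yr = p[:, 0] * sin_a + p[:, 1] * cos_a + cy
        draw.line(list(zip(xr, yr)), fill=0, width=width, joint="curve")
    return np.asarray(img) < 128


def normalize_glyph(glyph: np.ndarray, out_size: int = 28) -> np.ndarray:
    """Center a binary glyph in an ``out_size`` box, MNIST-style.

    The ink bounding box is scaled so its longer side spans 20 pixels,
    then pasted centered by center of mass.  Returns float32 in [0, 1].
    """
    glyph = np.asarray(glyph).astype(bool)
    rows = np.any(glyph, axis=1)
    cols = np.any(glyph, axis=0)
    if not rows.any():
        raise ClassificationError("blank glyph")
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    crop = glyph[r0 : r1 + 1, c0 : c1 + 1].astype(np.uint8) * 255
    h, w = crop.shape
    s = 20.0 / max(h, w)
    new_w, new_h = max(1, int(round(w * s))), max(1, int(round(h * s)))
    resized = np.asarray(
        Image.fromarray(crop).resize((new_w, new_h), Image.BILINEAR), dtype=np.float32
    ) / 255.0
    out = np.zeros((out_size, out_size), dtype=np.float32)
    ys, xs = np.nonzero(resized > 0.05)
    if len(ys) == 0:
        raise ClassificationError("glyph vanished during normalization")
    com_y = (resized[ys, xs] * ys).sum() / resized[ys, xs].sum()
    com_x = (resized[ys, xs] * xs).sum() / resized[ys, xs].sum()
    top = int(round(out_size / 2 - com_y))
    left = int(round(out_size / 2 - com_x))
    for y in range(new_h):
        for x in range(new_w):
            oy, ox = y + top, x + left
            if 0 <= oy < out_size and 0 <= ox < out_size:
                out[oy, ox] = resized[y, x]
    return out


class DigitClassifier(Protocol):
    """Anything that scores normalized 28x28 glyphs over the 10 classes."""

    def predict_proba(self, glyphs: np.ndarray) -> np.ndarray: ...  # (n, 10)


class SyntheticDigitClassifier:
    """Multinomial logistic regression fitted on stroke-font renders.

    Training data: ``n_per_class`` renders of each digit with rotation
    up to 12 deg, control-point wobble and varying stroke width, plus
    render sizes spanning the sizes seen on real headers.  Fitting takes
    a couple of seconds and happens lazily on first use.
    """

    def __init__(self, seed: int = 90210, n_per_class: int = 150) -> None:
        self.seed = seed
        self.n_per_class = n_per_class
        self._model: LogisticRegression | None = None

    def _train(self) -> None:
        rng = np.random.default_rng(self.seed)
        X, y = [], []
        for digit in range(10):
            for _ in range(self.n_per_class):
                size = int(rng.integers(32, 64))
                glyph = render_digit(
                    str(digit), size=size, rng=rng, max_rotation_deg=12.0, wobble=0.025
                )
                X.append(normalize_glyph(glyph).ravel())
                y.append(digit)
        model = LogisticRegression(max_iter=300, C=0.5)
        model.fit(np.array(X), np.array(y))
        self._model = model

    def predict_proba(self, glyphs: np.ndarray) -> np.ndarray:
        if self._model is None:
            self._train()
        glyphs = np.asarray(glyphs, dtype=np.float32)
        if glyphs.ndim == 2:
            glyphs = glyphs[None]
        return self._model.predict_proba(glyphs.reshape(len(glyphs), -1))


_DEFAULT: SyntheticDigitClassifier | None = None


def get_default_classifier() -> SyntheticDigitClassifier:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SyntheticDigitClassifier()
    return _DEFAULT


def classify_digit(
    glyph: np.ndarray, classifier: DigitClassifier | None = None
) -> tuple[int, float]:
    """Classify one binary glyph; returns ``(digit, confidence)``.

    The glyph is normalized to the classifier's 28x28 input convention
    first.  A blank glyph raises :class:`ClassificationError`.
    """
    if not np.asarray(glyph).astype(bool).any():
        raise ClassificationError("blank glyph")
    clf = classifier or get_default_classifier()
    proba = clf.predict_proba(normalize_glyph(glyph))[0]
    k = int(np.argmax(proba))
    return k, float(proba[k])
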