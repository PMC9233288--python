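"""Ground-truthed synthetic chart scans and synthetic patient cohorts.

Two generators live here.  ``render_chart`` draws the IOP form (frame,
nonlinear grid, header with a printed name label and a handwritten-style
date, blue/red marks) and then degrades it like a scanner would: slight
rotation, Gaussian intensity noise, optional frame cut-off.  Because the
renderer and the extractor share the same :class:`ChartTemplate`, every
plotted mark has a known nominal pixel and value, which makes the whole
digitization pipeline testable without any patient scans.

``simulate_cohort`` draws per-patient 24-hour profiles whose summary
statistics follow the distributions observed in a German inpatient
glaucoma population: mean IOP 15.2 +/- 4.0 mmHg, nycthemeral variation
6.9 +/- 4.2 mmHg, peak most often at 10:00, 42% progression prevalence,
and (by default) no association between IOP variables and progression.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy.stats import truncnorm

from .digits import render_digit
from .errors import RangeError, SimulationError
from .template import ChartTemplate, DEFAULT_TEMPLATE, SLOT_HOURS, SLOT_TIMES
from .types import DetectedEntry, GroundTruth, IOPProfile, RawScan

__all__ = [
    "RenderConfig",
    "render_chart",
    "random_truth",
    "CohortConfig",
    "SimulatedPatient",
    "simulate_cohort",
]

OD_COLOR = (25, 35, 170)  # blue ink, right eye
OS_COLOR = (190, 25, 25)  # red ink, left eye
_INK = (30, 30, 30)


@dataclass
class RenderConfig:
    """Scan-degradation model; the defaults are the reference noise model
    (intensity sigma 8, rotation within +/-3 deg, mark jitter up to 2 px)."""

    seed: int = 0
    noise_sigma: float = 8.0
    rotation_deg: float = 3.0  # rotation drawn uniformly in +/- this
    jitter_px: float = 2.0
    marker: str = "dot"  # dot | cross | tick
    join_lines: bool = False
    cutoff_fraction: float = 0.0  # 0..0.2 of the frame erased at the top-right
    days: int = 1
    scale: float = 1.0
    margin_px: int = 60

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff_fraction <= 0.2:
            raise ValueError("cutoff_fraction must be within [0, 0.2]")
        if not 1 <= self.days <= 6:
            raise ValueError("days must be 1..6")
        if self.marker not in ("dot", "cross", "tick"):
            raise ValueError("marker must be dot, cross or tick")

    @classmethod
    def noiseless(cls, seed: int = 0, **kw) -> "RenderConfig":
        return cls(seed=seed, noise_sigma=0.0, rotation_deg=0.0, jitter_px=0.0, **kw)


def _draw_marker(draw: ImageDraw.ImageDraw, x: float, y: float, color, marker: str) -> None:
    r = 5
    if marker == "dot":
        draw.ellipse([x - r, y - r, x + r, y + r], fill=color)
    elif marker == "cross":
        draw.line([x - r, y - r, x + r, y + r], fill=color, width=3)
        draw.line([x - r, y + r, x + r, y - r], fill=color, width=3)
    else:  # tick: short vertical dash
        draw.line([x, y - r, x, y + r], fill=color, width=4)


def _draw_axis_label(img: Image.Image, value: int, x_right: int, y_center: float) -> None:
    size = 26
    text = str(value)
    x = x_right - len(text) * int(size * 0.7)
    for ch in text:
        glyph = render_digit(ch, size=size, stroke_width=2)
        tile = np.full((size, size, 3), 255, dtype=np.uint8)
        tile[glyph] = _INK
        img.paste(Image.fromarray(tile), (int(x), int(y_center - size / 2)), Image.fromarray(glyph.astype(np.uint8) * 255))
        x += int(size * 0.7)


def _draw_date(
    img: Image.Image, date: _dt.date, region: tuple[int, int, int, int], rng: np.random.Generator
) -> None:
    x0, y0, x1, y1 = region
    size = min(56, y1 - y0 - 24)
    x = x0 + 20
    base = y0 + (y1 - y0 - size) // 2
    for ch in date.strftime("%d.%m.%Y"):
        if ch == ".":
            d = ImageDraw.Draw(img)
            d.rectangle([x + 6, base + size - 10, x + 13, base + size - 3], fill=_INK)
            x += 24
        else:
            glyph = render_digit(ch, size=size, rng=rng, max_rotation_deg=5.0, wobble=0.018)
            mask = Image.fromarray(glyph.astype(np.uint8) * 255)
            tile = np.full((size, size, 3), 255, dtype=np.uint8)
            tile[glyph] = _INK
            img.paste(Image.fromarray(tile), (int(x), int(base)), mask)
            x += int(size * 0.78)


def render_canonical(
    truth: GroundTruth,
    config: RenderConfig,
    template: ChartTemplate = DEFAULT_TEMPLATE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the clean chart on the canonical raster (no scan artifacts)."""
    tpl = template
    rng = rng or np.random.default_rng(config.seed)
    W, H = tpl.canonical_width, tpl.canonical_height
    img = Image.new("RGB", (W, H), (255, 255, 255))
    draw = ImageDraw.Draw(img)

    draw.rectangle([0, 0, W - 1, H - 1], outline=(0, 0, 0), width=4)

    x_left = int(tpl.day_origin_x - 20)
    x_right = int(tpl.day_origin_x + config.days * tpl.day_width + 10)
    for v in range(0, int(tpl.y_max_mmhg) + 1, 10):
        y = tpl.value_to_pixel(v)
        draw.line([x_left, y, x_right, y], fill=(150, 150, 150), width=1)
        _draw_axis_label(img, v, x_left - 12, y)
        draw = ImageDraw.Draw(img)
    for d_idx, t, x in tpl.iter_slots(days=config.days):
        draw.line([x, tpl.y_top_px - 20, x, tpl.y_bottom_px + 10], fill=(70, 70, 70), width=2)

    # header: machine-printed name label
    hx0, hy0, hx1, hy1 = tpl.header_region
    draw.rectangle([hx0, hy0, hx1, hy1], outline=(120, 120, 120), width=2)
    if truth.patient_name:
        font = ImageFont.load_default(34)
        draw.text((hx0 + 16, hy0 + 28), truth.patient_name, font=font, fill=(0, 0, 0))
    if truth.exam_date is not None:
        _draw_date(img, truth.exam_date, tpl.date_region, rng)

    # colored marks, optionally joined by polylines
    draw = ImageDraw.Draw(img)
    for eye, color in (("OD", OD_COLOR), ("OS", OS_COLOR)):
        pts = []
        for e in sorted(
            truth.for_eye(eye), key=lambda e: (e.slot[0], SLOT_TIMES.index(e.slot[1]))
        ):
            if not 0.0 <= e.value_mmhg <= tpl.y_max_mmhg:
                raise RangeError(f"{e.value_mmhg} mmHg outside the template's y-axis range")
            x = tpl.slot_x(*e.slot)
            y = tpl.value_to_pixel(e.value_mmhg)
            truth.pixel_positions[(eye, e.slot)] = (x, y)
            jx = rng.uniform(-config.jitter_px, config.jitter_px) if config.jitter_px else 0.0
            jy = rng.uniform(-config.jitter_px, config.jitter_px) if config.jitter_px else 0.0
            pts.append((x + jx, y + jy))
        if config.join_lines and len(pts) > 1:
            draw.line(pts, fill=color, width=3)
        for p in pts:
            _draw_marker(draw, p[0], p[1], color, config.marker)

    return np.asarray(img, dtype=np.uint8)


def render_chart(
    truth: GroundTruth,
    config: RenderConfig,
    template: ChartTemplate = DEFAULT_TEMPLATE,
) -> RawScan:
    """Render the form and simulate the scanning process.

    Deterministic given ``config.seed``.  The nominal (pre-jitter)
    canonical pixel of every mark is recorded in
    ``truth.pixel_positions`` as render provenance.
    """
    rng = np.random.default_rng(config.seed)
    arr = render_canonical(truth, config, template, rng)
    H, W = arr.shape[:2]
    m = config.margin_px
    page = np.full((H + 2 * m, W + 2 * m, 3), 255, dtype=np.uint8)
    page[m : m + H, m : m + W] = arr

    if config.cutoff_fraction > 0:
        ch = int(config.cutoff_fraction * H)
        cw = int(config.cutoff_fraction * W)
        page[: m + ch, m + W - cw :] = 255

    angle = rng.uniform(-config.rotation_deg, config.rotation_deg) if config.rotation_deg else 0.0
    if angle:
        page = np.asarray(
            Image.fromarray(page).rotate(
                -angle,  # positive = clockwise on screen, like a skewed scan
                resample=Image.BILINEAR,
                expand=True,
                fillcolor=(255, 255, 255),
            )
        )

    if config.noise_sigma > 0:
        noisy = page.astype(np.float32)
        noisy += rng.standard_normal(page.shape, dtype=np.float32) * config.noise_sigma
        page = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    if config.scale != 1.0:
        im = Image.fromarray(page)
        new = (max(200, int(im.width * config.scale)), max(200, int(im.height * config.scale)))
        page = np.asarray(im.resize(new, Image.BILINEAR), dtype=np.uint8)

    return RawScan(pixels=page, source_id=f"synthetic:{truth.patient_id}:{config.seed}")


_SURNAMES = ["Mustermann", "Schneider", "Öztürk", "Weber", "Köhler", "Fischer"]
_GIVEN = ["Erika", "Hans", "Ayşe", "Jürgen", "Monika", "Karl"]


def random_truth(
    seed: int,
    template: ChartTemplate = DEFAULT_TEMPLATE,
    days: int = 1,
    eyes: tuple[str, ...] = ("OD", "OS"),
    patient_id: str | None = None,
) -> GroundTruth:
    """A plausible random examination: per-eye values, name and date."""
    rng = np.random.default_rng(seed)
    entries = []
    bases = {eye: rng.uniform(11.0, 22.0) for eye in eyes}
    for d in range(days):
        for t in SLOT_TIMES:
            taken: list[float] = []
            for eye in eyes:
                # opaque ink: coincident marks of the two eyes would fully
                # occlude each other, so keep at least 1 mmHg between them
                for _ in range(20):
                    v = float(np.clip(bases[eye] + rng.normal(0, 2.5), 5.0, 38.0))
                    v = round(v * 2) / 2
                    if all(abs(v - o) >= 1.0 for o in taken):
                        break
                taken.append(v)
                entries.append(DetectedEntry(eye=eye, slot=(d, t), value_mmhg=v))
    name = f"{_SURNAMES[rng.integers(len(_SURNAMES))]}, {_GIVEN[rng.integers(len(_GIVEN))]}"
    date = _dt.date(2015, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 3000)))
    return GroundTruth(
        patient_id=patient_id or f"synth-{seed:05d}",
        entries=entries,
        exam_date=date,
        patient_name=name,
    )


# -- cohort simulation -------------------------------------------------


@dataclass
class CohortConfig:
    """Population model for simulated patients.

    Defaults reproduce the reference inpatient glaucoma population:
    mean 24-hour IOP 15.2 +/- 4.0 mmHg, nycthemeral variation
    6.9 +/- 4.2 mmHg, modal IOP peak at 10:00 with an 8.4 h spread,
    progression prevalence 42%, and no IOP-progression association.
    Mean arterial pressure is calibrated so that the resulting mean
    ocular perfusion pressure averages about 59 mmHg.
    """

    n: int = 200
    seed: int = 0
    t_avg_mean: float = 15.2
    t_avg_sd: float = 4.0
    iop_var_mean: float = 6.9
    iop_var_sd: float = 4.2
    map_mean: float = 103.9
    map_sd: float = 12.7
    acrophase_mode: str = "10:00"
    acrophase_spread_h: float = 8.4
    progression_prevalence: float = 0.42
    association_strength: float = 0.0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.progression_prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if min(self.t_avg_sd, self.iop_var_sd, self.map_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SimulatedPatient:
    profile: IOPProfile
    map_mmhg: float
    progressor: bool
    t_avg: float
    iop_var: float


# within-day shape: zero mean, unit range, peak at index 0 and trough at
# index 3 (10:00 peak, 21:00 trough in the unrotated frame)
_SHAPE = np.array([0.55, 0.15, -0.05, -0.45, -0.20])


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _acrophase_probs(cfg: CohortConfig) -> np.ndarray:
    mode_h = SLOT_HOURS[SLOT_TIMES.index(cfg.acrophase_mode)]
    sigma = max(cfg.acrophase_spread_h / 2.0, 0.5)
    d = np.array([min(abs(h - mode_h), 24 - abs(h - mode_h)) for h in SLOT_HOURS])
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum()


def simulate_cohort(config: CohortConfig) -> list[SimulatedPatient]:
    """Draw a cohort of synthetic patients.

    Per patient: T_avg and IOP_var come from truncated normal
    distributions; the peak slot is drawn from the acrophase
    distribution; five slot values are constructed so that their mean is
    exactly the drawn T_avg and their range exactly the drawn IOP_var;
    mean arterial pressure is drawn independently; the progression label
    is Bernoulli with a logit linear in the standardized IOP variables
    times the association strength.
    """
    rng = np.random.default_rng(config.seed)
    probs = _acrophase_probs(config)
    logit0 = (
        np.log(config.progression_prevalence / (1.0 - config.progression_prevalence))
        if 0.0 < config.progression_prevalence < 1.0
        else (np.inf if config.progression_prevalence == 1.0 else -np.inf)
    )
    patients: list[SimulatedPatient] = []
    for i in range(config.n):
        for attempt in range(config.max_retries + 1):
            t_avg = _trunc_normal(rng, config.t_avg_mean, config.t_avg_sd, 2.0, 60.0)
            var = _trunc_normal(rng, config.iop_var_mean, config.iop_var_sd, 0.2, 30.0)
            peak = t_avg + var * _SHAPE.max()
            trough = t_avg + var * _SHAPE.min()
            if 0.5 <= trough and peak <= 79.0:
                break
        else:
            raise SimulationError("could not draw a physiologically valid profile")

        peak_idx = int(rng.choice(len(SLOT_TIMES), p=probs))
        shape = np.roll(_SHAPE, peak_idx)
        values = t_avg + var * shape
        lo, hi = values.min(), values.max()
        for j in range(len(values)):  # wobble the non-extreme slots only
            if values[j] not in (lo, hi):
                values[j] = float(
                    np.clip(values[j] + rng.uniform(-0.3, 0.3), lo + 0.05, hi - 0.05)
                )
        values = np.round(values, 1)

        map_mmhg = _trunc_normal(rng, config.map_mean, config.map_sd, 60.0, 160.0)

        z_var = (var - config.iop_var_mean) / max(config.iop_var_sd, 1e-9)
        z_tavg = (t_avg - config.t_avg_mean) / max(config.t_avg_sd, 1e-9)
        logit = logit0 + config.association_strength * (z_var + z_tavg)
        p = 1.0 / (1.0 + np.exp(-logit)) if np.isfinite(logit) else float(logit > 0)
        progressor = bool(rng.random() < p)

        pid = f"sim-{config.seed}-{i:04d}"
        entries = [
            DetectedEntry(eye="OD", slot=(0, t), value_mmhg=float(v))
            for t, v in zip(SLOT_TIMES, values)
        ]
        patients.append(
            SimulatedPatient(
                profile=IOPProfile(patient_id=pid, entries=entries),
                map_mmhg=map_mmhg,
                progressor=progressor,
                t_avg=t_avg,
                iop_var=var,
            )
        )
    return patients
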