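# iopchart

**iopchart** digitizes hand-drawn 24-hour (nycthemeral) intraocular-pressure
charts and analyzes the resulting IOP profiles.

In many German eye hospitals, inpatient 24-hour IOP profiles are still
recorded by hand on a standard printed form: a framed grid with a nonlinear
time axis (measurements at 10 am, 2 pm, 5 pm, 9 pm by Goldmann applanation
and midnight by Perkins tonometry, for up to six consecutive days) and a
nonlinear pressure axis compressed above 40 mmHg, with the right eye (OD)
charted in blue and the left eye (OS) in red. Decades of such charts hold
clinically valuable data — peak pressure T_max, trough T_min, mean T_avg,
nycthemeral variation IOP_var = T_max − T_min, the acrophase (time of peak
IOP), and the mean ocular perfusion pressure
MOPP = ⅔·(MAP − T_avg) — but only as ink on paper. This package turns
scanned charts into structured per-eye time series and computes those
clinical quantities, together with the diagnostic-performance analyses
(cutoff contingency tables, ROC curves) used to ask whether 24-hour IOP
variables predict glaucoma progression.

The pipeline, for each scan:

1. **preprocess** — Gaussian adaptive thresholding (27×27 neighborhood,
   offset 10), largest-contour frame detection with Douglas–Peucker
   simplification (robust to cut-off corners), and a perspective warp onto a
   canonical 1800×1200 px raster so that all later steps can use fixed pixel
   positions.
2. **extract** — Canny edges + a near-vertical Hough transform find the time
   gridlines, which snap to the template's slot positions; HSV color masks
   separate blue (OD) from red (OS) ink; connected components near each
   gridline become entries, with tall components rejected as connecting-line
   strokes; the y position of each mark maps directly to mmHg through the
   template's piecewise-linear axis.
3. **metadata** — the handwritten examination date is segmented into digit
   and delimiter components, classified by a pluggable digit classifier
   (default: logistic regression trained on the package's own stroke-font
   renders, no downloads needed), and parsed as day.month.year; the printed
   name label goes through a pluggable OCR engine and a
   `Surname, Givenname` regular expression, pseudonymized by default.
4. **evaluate** — detections are matched slot-exactly against ground truth
   and scored with false-positive rate, false-negative rate, mean value
   distance (mmHg), and mean relative error.
5. **stats** — profile summaries, MOPP, acrophase alignment, cutoff
   contingency (sensitivity/specificity for T_max cutoffs such as 15 and
   22 mmHg, over the full 24 h or outpatient office hours only), and ROC
   curves.

A fully deterministic synthetic generator (**synth**) renders
ground-truthed chart scans — frame, grid, header with printed name label and
handwritten-style date, colored marks, scan noise, rotation, frame cut-off —
and simulates patient cohorts with realistic population statistics
(T_avg 15.2 ± 4.0 mmHg, IOP_var 6.9 ± 4.2 mmHg, modal acrophase at 10:00,
42% progression prevalence, configurable IOP–progression association), so
every stage is testable without any patient data.

## Worked example

Render a synthetic scan (with noise, rotation, and handwritten date), run
the full pipeline on it, and summarize the right eye:

```python
import iopchart as ic
from iopchart.pipeline import extract_chart
from iopchart.stats import compute_mopp, summarize_profile

truth = ic.random_truth(seed=7)
scan = ic.render_chart(truth, ic.RenderConfig(seed=7))   # noisy, rotated scan
result = extract_chart(scan)

print("exam date:", result.profile.exam_date)
for e in result.profile.for_eye("OD"):
    print(f"  OD {e.slot[1]}  {e.value_mmhg:5.1f} mmHg")

s = summarize_profile(result.profile, eye="OD")
print(f"T_max {s.t_max:.1f}  T_min {s.t_min:.1f}  T_avg {s.t_avg:.1f}  "
      f"IOP_var {s.iop_var:.1f}  acrophase {s.acrophase_slot}")
rec = compute_mopp(systolic=120, diastolic=80, t_avg=s.t_avg)
print(f"MAP {rec.map_mmhg:.1f} mmHg  MOPP {rec.mopp:.1f} mmHg")
```

prints

```
exam date: 2023-02-19
  OD 10:00   17.0 mmHg
  OD 14:00   16.6 mmHg
  OD 17:00   18.1 mmHg
  OD 21:00   16.6 mmHg
  OD 00:00   19.0 mmHg
T_max 19.0  T_min 16.6  T_avg 17.5  IOP_var 2.4  acrophase 00:00
MAP 93.3 mmHg  MOPP 50.6 mmHg
```

The handwritten date on the header was read back correctly, and every
extracted value sits within 0.1 mmHg of the plotted truth
(17.0, 16.5, 18.0, 16.5, 19.0): the residual is the pixel quantization of
the value axis plus the mark-placement jitter of the renderer. `T_max`,
`T_min`, `T_avg` and `IOP_var` are the standard descriptors of a 24-hour
session; the acrophase is the slot at which the peak occurred; MOPP
estimates the eye's perfusion pressure from mean arterial pressure
(diastolic + pulse pressure/3) and mean IOP.

## Command line

The same stages are available as subcommands:

```bash
iopchart simulate --out data/ --n-charts 10 --cohort-n 200 --seed 1
iopchart extract data/images/*.png --out extraction.csv
iopchart evaluate --pred extraction.csv --truth data/truth.csv
iopchart stats --profiles extraction.csv --labels labels.csv \
               --cutoffs 15,22 --slot-set 24h --roc-plot roc.png
```

`extract` writes one CSV row per detected entry (patient, date, eye, day,
clock time, mmHg, pixel position, blob area, review flag) and prints a
review listing for anything that needs a human look — surplus blobs,
low-confidence digits, missing name candidates — in place of an interactive
correction UI. Batch extraction never aborts on a single unreadable file.

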