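# mtmkin

Quantification of infant **movements toward the midline (MTM)** from
markerless 2D pose landmarks.

In the first months after term, supine infants begin bringing hands and
feet toward the body's midline — foot–foot and hand–hand contact,
hand-to-mouth, pedipulation and related behaviours. These early antigravity
movements are clinically interesting precursors of goal-directed motor
development, and they leave a geometric signature in ordinary overhead
video: the distal limb landmarks spend time closer to the body axis, and
the area they enclose shrinks. `mtmkin` turns a 33-landmark 2D pose
trajectory (the standard full-body pose-estimation schema, normalized image
coordinates, nominally 120 s at 30 fps) plus human MTM annotations into
per-video kinematic features, occurrence scores, and the cohort statistics
that relate them. It is intended for movement-science and early-development
researchers working with phone-camera recordings, and ships a fully seeded
synthetic supine-infant generator so every stage is testable without any
video data.

## What it computes

For each frame, with limb landmarks 15/16 (wrists) and 27/28 (ankles):

* the **midbody line** through the shoulder midpoint (landmarks 11, 12) and
  hip midpoint (23, 24), parameterized `x = a·y + b` (stable for the
  near-vertical body axis of a top-down recording);
* **signed distances** `Dlm = (x_line(y_lm) − x_lm) / L`: the horizontal
  offset of each limb landmark from the line at its own image row,
  normalized by the body length `L` (mean of the 11–23 and 12–24 Euclidean
  distances);
* **areas**: the shoelace area of the wrist–wrist–ankle–ankle quadrilateral
  and the wrist-pair and ankle-pair triangles to the body centre (mean of
  all 33 landmarks), normalized by body length.

Per-video means of these features meet the MTM annotations, scored under
the whole-second rule (an event counts `floor(frames/fps)` seconds; a
contact shorter than 30 frames at 30 fps counts nothing):

```
occurrence % = total MTM seconds / duration(s) × 100
rate per min = group MTM seconds / duration(s) × 60     (total | lower | upper)
```

with lower = {FF, FL, pedipulation} and upper = {HH, HF, HM, HT, HL,
manipulation, fiddling}. The statistics layer provides Spearman correlation
with Fisher-z 95% CIs, `tanh(atanh(r) ± z₀.₉₇₅/√(n−3))`, between each
distance and each occurrence metric, plus shows/no-shows group comparisons
of the areas (Student's t for the whole area, Mann–Whitney U for the upper
and lower areas). `docs/methods.md` has the full model description.

## Worked example

Simulate a small cohort and run the whole analysis:

```bash
mtmkin simulate --out-dir demo --n-videos 8 --duration 60 --seed 11
mtmkin run-all --landmark-dir demo/landmarks \
               --annotations demo/annotations.csv --out-dir demo/results
# included 8 videos, excluded 0; tables in demo/results
```

`demo/results/features.csv` holds one row per video:

```
video_id,mean_dlm15,mean_dlm16,mean_dlm27,mean_dlm28,mean_area_whole,...
video000,0.5138912057709719,-0.5014388674042894,0.31546377611610027,-0.31185965476440897,0.22479425770357772,...
```

The left wrist sits about +0.51 body lengths to one side of the midline and
the right wrist −0.50 to the other; signs encode side, so midline contact
drives both magnitudes toward zero. `correlations.csv` gives the
distance-vs-occurrence Spearman cells with their Fisher-z CIs:

```
feature,metric,r,ci_low,ci_high,p,n,significant
mean_dlm15,rate_upper,-0.766,-0.955,-0.134,0.0265,8,False
```

— in this tiny seeded cohort the left-wrist distance falls as upper-limb
MTM rate rises (r = −0.77, 95% CI [−0.96, −0.13], not starred since
flagging uses p < 0.01). `comparisons.csv` holds the shows/no-shows area
tests, e.g. the Lower-MTM lower-area cell
(`mann_whitney, p = 0.31, median_show 0.0911 < median_noshow 0.0943` —
the expected direction, underpowered at n = 4/4 by design of the demo).

The same objects are available as a library:

```python
from mtmkin import SyntheticConfig, simulate, summarize_video, fisher_ci

bundle = simulate(SyntheticConfig(duration_s=120, fps=30, seed=1))
summary = summarize_video(bundle.series)   # mean Dlm and areas for the video
fisher_ci(0.315, 94)                       # (0.1200, 0.4866)
```

## Data formats

* Landmark CSV (per video): `frame,landmark,x,y,visibility` — long format,
  33 rows per frame, frames contiguous from 0, coordinates normalized,
  visibility optional in [0, 1].
* Annotation CSV: `video_id,item,start_frame,end_frame` — items from the
  10-item MTM catalogue, intervals half-open `[start, end)`.
* Outputs: `features.csv`, `scores.csv`, `correlations.csv`,
  `comparisons.csv`, and `manifest.json` (config snapshot, input digests,
  per-video included/excluded status with reasons).

`mtmkin` consumes landmarks; it does not run a pose estimator or decode
video.
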