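# Methods

## Problem and measurement model

During the first months after term, healthy infants begin to bring their
hands and feet toward and across the body's midline — movements toward the
midline (MTM), an early antigravity behaviour whose absence can flag
neuromotor risk. `mtmkin` quantifies MTM-related kinematics from markerless
2D pose estimates of supine infants filmed from above: a 33-landmark (x, y)
trajectory per video, in normalized image coordinates, nominally 120 s at
30 fps.

Two families of features are computed per frame and averaged per video:

**Signed limb-to-midline distances.** The midbody line joins the midpoint of
the shoulders (landmarks 11, 12) and the midpoint of the hips (23, 24). We
parameterize it as `x = a·y + b` rather than `y = m·x + c`: the supine
top-down protocol makes the body axis near-vertical in the image, where the
slope `m` diverges but `a = 1/m` stays near zero. An exactly vertical
midline is an ordinary case; an exactly horizontal body axis
(`|y_shoulder_mid − y_hip_mid| ≤ 1e-6 × body length`) is degenerate and is
refused (or flagged invalid in bulk processing). The distance for a limb
landmark (15/16 wrists, 27/28 ankles) is the *horizontal offset*
`x_line(y_lm) − x_lm`: evaluate the midline at the landmark's own image row
and subtract the landmark's x. This is deliberately not the perpendicular
distance — it is the measure the feature definitions prescribe — but a
perpendicular variant (`distance_mode="perpendicular"`, the offset divided
by `sqrt(1 + a²)`) is available; it is the rotation-invariant form the
invariance test-suite exercises. Distances are signed (positive = landmark
on the smaller-x side of the line). Signs must be retained through
averaging: left and right limbs sit on opposite sides, and folding them to
magnitudes would erase the left/right asymmetry that the cohort analysis
measures.

**Enclosed areas.** The whole area is the absolute shoelace area of the
quadrilateral left wrist → right wrist → right ankle → left ankle (fixed
traversal 15→16→28→27, which walks around the body and cannot
self-intersect for an anatomically ordered pose). The upper and lower areas
are the triangles joining the wrist pair, respectively the ankle pair, to
the body centre (the arithmetic mean of all 33 landmarks). Contact-type
movements pull the distal landmarks toward the midline and shrink these
areas.

**Normalization.** Every distance is divided by that frame's body length —
the mean of the two shoulder-to-hip Euclidean distances (11–23 and 12–24) —
computed per frame rather than per video so that frame-to-frame
camera-distance changes are compensated where they occur. Areas are divided
by body length to the power `area_norm_exponent`; the default is 1 (a
literal length normalization), with 2 available when a fully dimensionless
area is wanted. Neither choice affects rank-based statistics within a
video-level analysis, but the default is stated so outputs are
reproducible.

**Validity.** A landmark is usable when its coordinates are finite and its
visibility (when present) is ≥ 0.5. Distance features need landmarks
{11, 12, 23, 24, 15, 16, 27, 28} and a non-degenerate midline; area
features need all 33 (the body centre does). Per-video means are taken over
each feature group's own valid frames. A video whose fully-valid-frame
fraction falls below 90% (`max_invalid_fraction = 0.10`) is flagged
unusable and excluded before any cohort statistics, with the reason
recorded in the run manifest.

## MTM occurrence scoring

Annotated events are half-open frame intervals `[start, end)` labelled with
one of ten items — foot–foot (FF), foot–leg (FL), hand–hand (HH),
hand–face (HF), hand–mouth (HM), hand–trunk (HT), hand–leg (HL),
pedipulation, manipulation, fiddling. Scoring follows the whole-second
rule: an event contributes `floor(frames / fps)` seconds, so at 30 fps a
29-frame contact contributes nothing and a 45-frame contact one second.
Whether a 59-frame run should count one second (flooring) or require
disjoint 30-frame blocks is genuinely ambiguous; flooring is implemented,
isolated in `event_seconds`, and a fractional `frames/fps` mode is provided
for sensitivity analyses. Same-item overlapping or abutting annotations are
merged before counting (one behaviour, annotated twice, is still one
behaviour); different items overlapping in time each count in full, since
per-item times are summed independently.

From the per-item seconds: occurrence percentage = total seconds / duration
× 100, and per-minute rates = group seconds / duration × 60 for three
groups — lower (FF, FL, pedipulation), upper (the other seven), and total.
The canonical duration is 120 s; the actual video duration is substituted
when it differs. `rate_total = rate_lower + rate_upper` holds exactly by
construction. A video "shows" a category when the corresponding rate is
positive.

## Statistics

* **Normality screening**: one-sample Kolmogorov–Smirnov against a normal
  with plugged-in sample mean and SD. The default p-value uses the
  Lilliefors correction for the estimated parameters (via statsmodels); the
  fixed-parameter classical p is available (`method="ks"`). The statistic
  is identical either way.
* **Correlation**: Spearman rank correlation (mid-ranks for ties), p from
  the t-approximation with n−2 df, for each of the four per-video mean
  distances against each of the four occurrence metrics. 95% CIs come from
  the Fisher z-transformation, `tanh(atanh(r) ± z_{0.975}/sqrt(n−3))`; this
  arithmetic reproduces published intervals for r = 0.315, −0.354 and
  −0.199 at n = 94 to their printed precision, which is why it is the
  package's CI method. Cells whose metric is constant across the cohort
  (e.g. no video shows lower MTM) are reported as NaN rather than failing
  the table; |r| = 1 cells carry a degenerate CI equal to r.
* **Group comparisons**: videos showing vs not showing each MTM category,
  compared on the three area measures — Student's pooled-variance t-test
  for the whole area (Welch configurable), Mann–Whitney U (tie-corrected
  normal approximation with continuity correction; exact enumeration when
  min(n) ≤ 8 without ties) for the upper and lower areas. α = 0.05
  two-sided. Categories with an empty or single-video side are skipped with
  a warning rather than failing the run.
* No multiple-testing correction is applied anywhere; per-cell significance
  flags (p < 0.01 for the correlation table) are descriptive. This is a
  deliberate, documented limitation of the analysis design being
  reproduced.

## Synthetic data generator

No infant video or landmark data are distributed, so validation runs on a
generative model of what the pose estimator emits:

* **Rest pose**: a bilaterally symmetric 33-landmark supine template,
  shoulder-to-hip span `scale = 0.25` normalized units, body axis vertical
  in the image by default, centroid at image centre.
* **Baseline motility**: each limb landmark (elbows, wrists, knees, ankles)
  wanders as a stationary mean-reverting AR(1) (exponentially smoothed
  Gaussian) with SD 0.03 normalized units and correlation time 1.5 s —
  smooth, bounded, plausible spontaneous movement. Hand and foot landmarks
  ride on their wrist/ankle plus smaller independent wander. These
  amplitudes are the package's own choices of a plausible regime; they are
  not estimates fitted to infant data.
* **Events**: scheduled explicitly or drawn per item as a Poisson process
  (events/min) with durations ≥ 1 s (shifted-exponential, mean 2 s). During
  an event the item's contact landmarks ease (cosine ramp, 0.3 s) toward
  the item's target — both ankles to the lower midline for FF/pedipulation,
  both wrists to the chest midline for HH/manipulation, one wrist to
  face/mouth/trunk/same-side knee for HF/HM/HT/HL, one ankle to the
  opposite leg for FL — hold within the contact radius (0.25 × body length)
  with small contact jitter, and ease back. Same-item overlaps in explicit
  schedules are errors; random draws that would overlap are dropped.
* **Camera jitter**: a smooth rigid per-frame rotation (SD 0.02 rad) and
  translation (SD 0.005) of all landmarks about the image centre — the
  hand-held-phone scenario. Rigidity is what makes the geometry module's
  invariance suite meaningful on generated data.
* **Measurement noise**: i.i.d. Gaussian, SD 0.003 normalized units
  (roughly 2–3 px at 1080p), added last. Optional per-landmark dropout
  zeroes the visibility score to exercise the validity machinery.

Determinism: one `numpy` Generator seeded from the config; identical
config + seed gives bit-identical output. Cohorts derive per-video seeds
from a `SeedSequence` spawn of the cohort seed.

What the generator does *not* emulate: pose-estimator failure modes beyond
Gaussian jitter and dropout (identity swaps, occlusion-correlated bias),
non-rigid perspective change, caregiver interference, or real
developmental variation in movement repertoires. Passing tests therefore
demonstrate that the pipeline computes its defined quantities correctly and
recovers effects that are mechanically present; they do not certify
performance on real infant video.

## Cohort validation studies

`make_cohort(coupling="strong")` draws per-video event rates (about half
the videos get lower-limb items; most get upper items, HT most often) and
lets events drive the limbs, so a higher lower-limb burden mechanically
yields more time with the ankles at the midline and a smaller mean lower
area — the association is emergent from the kinematics, never painted onto
the feature values. The power study simulates 100 independent cohorts of
60 videos (120 s at 30 fps each), runs the full feature → score →
comparison pipeline, and counts replicates where the Lower-category
lower-area Mann–Whitney test is significant at 0.05 in the correct
direction.

`coupling="none"` annotates the same event schedules but leaves the limbs
inert, making features independent of labels. The null calibration fully
simulates four such cohorts and then redraws the shows/no-shows label
assignment 250 times per cohort (fair coin, both groups non-empty),
recording the rejection rate of the same test. Redrawing labels over a
fixed decoupled cohort samples exactly the label-independent null — the
quantity a type-I error rate is defined over — at a per-replicate cost that
makes 1000 replicates practical; fully re-simulating each null cohort
would estimate the same rate far more slowly. Problem sizes (100 power
replicates, 4 × 250 null replicates, 60 videos) are chosen so the whole
study completes in a few minutes on one CPU while leaving the binomial
uncertainty on both rates well inside the asserted bands.

## Numerical choices and edge cases

* Midline degeneracy threshold: `|Δy| ≤ 1e-6 × body length`; coincident
  shoulder/hip midpoints and zero body length are errors in scalar calls
  and `valid=False` in bulk extraction.
* Whole-second flooring guards against float fuzz with a +1e-9 offset
  before `floor` (relevant for non-integer fps).
* Landmark CSVs are written with `%.17g` and parsed with pandas
  `float_precision="round_trip"`, so write → read is the identity on the
  coordinate arrays bit for bit.
* Mirroring (`reflect_frame_across_midline`) is a true Euclidean reflection
  across the midbody line plus a left/right landmark-index swap. An x-only
  reflection at fixed y would preserve the signed offsets but is a shear —
  it changes body lengths and would break the antisymmetry of the
  *normalized* distances.
* The event envelope excludes easing ramps from contact-fidelity
  guarantees; the hold phase keeps contact landmarks within the contact
  radius in ≥ 95% of frames.

## Known limitations

* The horizontal-offset distance is not rotation-invariant; rotational
  camera jitter perturbs it (by design — it reproduces the defined
  measure). The perpendicular mode exists for users who want invariance.
* Area normalization by body length¹ keeps a residual length dimension;
  exponent 2 is provided but changes absolute values, not ranks, within a
  fixed protocol.
* Whether real scoring would floor a 59-frame run to one second is
  unresolved ambiguity; both readings are one config flag apart.
* Statistical power numbers from synthetic cohorts characterize the
  pipeline under the generator's assumptions only.
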