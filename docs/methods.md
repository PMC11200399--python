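# Methods

## Scope and data model

`ethotrack` operates strictly downstream of an object detector. Its inputs
are per-frame detection records (frame index, behavior label, confidence,
box as `x_min, y_min, width, height` in pixels, top-left origin) for a
single focal subject, plus optional frame-complete manual codings. It never
touches video, images, or model files.

Two conventions run through everything:

- **Frames are the time axis.** Sessions are sampled at ~1 frame/s, so
  frame fractions and time fractions are treated as the same quantity. All
  percentages are per total session frames and are displayed to one decimal
  with half-up rounding; arithmetic and invariants always use the unrounded
  values.
- **`total_frames` travels with the data.** Frames without a detection are
  invisible in detection records, so the detection CSV carries
  `#total_frames=N` (and `#fps=F`) comment lines; without them the reader
  falls back to `max frame + 1`. Floats are serialized with `repr`, which
  makes write→read→write byte-identical.

The ethogram has exactly six categories. The detector emits four; all
frames without a surviving detection are pooled into
`Out of View/Not Labeled` because detector output cannot separate a hidden
subject from an unconfident model. `Other` exists only in manual codings.
`False Positive Locomotion` is deliberately *not* an ethogram category: it
is a correction artifact that appears only in corrected tracks and budgets,
and the comparison's total-disagreement summary is restricted to the four
detector categories for the same reason.

## Confidence thresholding

The threshold τ (default 0.8) is read as a minimum-acceptance rule:
detections with confidence ≥ τ survive. The boundary is inclusive because
"set to X% confidence" describes the least confidence the operator will
accept. Thresholding never changes `total_frames`; rejected detections move
frames into the unlabeled pool, which makes category counts conserved at
every τ and monotone in it (detector categories non-increasing, unlabeled
non-decreasing).

## Plateau filter

Movement shows up in the trajectory of the box's bottom corner
`(x_min, y_min + height)`; background-driven false Locomotion does not. The
filter's stillness rule is a **range criterion over a run**: a window of
entries is still when `max − min ≤ ε` per axis, rather than requiring small
frame-to-frame deltas, because real plateaus accumulate sub-pixel jitter
that a delta rule either misses (too strict) or lets drift (too loose).
Parameters, all exposed in `PlateauConfig`:

| parameter | default | unit | why |
|---|---|---|---|
| `epsilon_x`, `epsilon_y` | 5 | px | ≈ box-localization jitter of a detector on a still subject; well below one step of true locomotion |
| `min_run` | 3 | frames | a 3 s pause is the shortest stretch worth calling stationary at 1 frame/s |
| `max_gap` | 2 | frames | bridges isolated missed detections inside a plateau without merging distinct ones |
| `require_both_axes_still` | true | — | movement normally shows in both coordinates; the either-axis mode is provided because a subject can move exactly along one image axis |

Detection is greedy left-to-right: extend a window from each candidate
start while the gap and range predicates hold (the range predicate is
monotone under window growth, so maximal extension is well-defined), emit
it if it reaches `min_run`, and resume past its end. Runs are therefore
disjoint and ordered. The test suite checks this against an independent
all-windows enumeration oracle.

Flagged frames are relabeled `False Positive Locomotion`, never reassigned
to another behavior — the filter knows the subject was not locomoting, not
what it was doing. Conservation (`FP% + retained% = raw Locomotion%`) holds
exactly because all three shares are integer frame counts over one
denominator. Shrinking ε or raising `min_run` can only shrink the flagged
set (monotone filter), and the criterion is translation-invariant since
only coordinate ranges enter.

## Posture channel

`r = height/width` with two limits; boundaries classify toward the extreme
call so that "at the limit" means the behavior is present. The default
limits 2.0/0.6 bracket a sitting great ape's typical box ratio (~1.2–1.5)
with margin but are placeholders: the discriminating values depend on
camera angle and subject, and real use must calibrate them on example
frames. Posture is reported alongside the behavior label, not merged into
it — it is an independent, post-hoc channel.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes, with
one RNG substream per stage (`default_rng([seed, stage])`) so stages are
independently reproducible and identical (scenario, seed) pairs are
byte-identical on disk.

**Behavior sequence.** Bouts are semi-Markov with geometric (memoryless)
durations — the minimal assumption absent published bout statistics. Bout
*categories* are drawn with probability proportional to
`mix[b] / mean_bout_frames[b]`, which by renewal-reward makes the long-run
frame occupancy converge to `behavior_mix`; drawing categories from the mix
directly would confound the target time budget with the bout-length
choices. The default mix is the study regime's manual time budget
(Locomotion 3.6%, Foraging/Feeding 18.1%, Inactive 13.9%, Covered Inactive
15.6%, Other 7.5%, out of view 41.3%). Default bout means (15/40/60/90/20/
120 s) are chosen as plausible zoo-ape scales: short travel bursts, long
rests, longer disappearances. With bouts this long a single session is a
small-sample draw from the mix — occupancy of a 100k-frame session has an
sd of 1–2 percentage points — so calibration tests average over replicate
seeds rather than reading one draw.

**Trajectory.** Locomotion bouts translate the box at `locomotion_speed`
(default 15 px/frame) in a per-bout random direction with reflecting arena
walls (1280×720 px default); a wall reflection folds a step, so net
displacement at reflection frames is below nominal speed while path length
is preserved. Stationary bouts pin an anchor and add independent per-frame
N(0, `stationary_jitter_sd`²) offsets (default 1 px). A fraction of
Inactive bouts (10%) carries a planted posture, reshaping the box to the
arms-up (2.5) or lying (0.4) ratio at constant area.

**Detector.** Each in-view frame is detected with a per-behavior
probability (default 0.95 for the four detector classes — an idealized
detector, since the object under test is the filter, not detector recall;
`Other` and out-of-view frames are never detected). Emitted labels come
from a confusion matrix whose only off-diagonal mass is
stationary → Locomotion at 0.1. By default the confusion is drawn **once
per bout** (`mislabel_per_bout=True`): the failure mechanism is the
detector recognizing the background at the subject's resting spot, which
persists as long as the subject stays there, and it is exactly this
persistence that makes the errors appear as plateaus. A per-frame mode
exists for variance analyses; there the planted-FP frame count is
binomial, while in the default mode the binomial count is the number of
affected bouts. Confidences are N(0.92, 0.05²) for correct and
N(0.88, 0.05²) for incorrect emissions, clipped to [0, 1], so most
detections survive the 0.8 threshold regime.

**What the generator does not model:** observer error (manual coding is
the reference, so it is simulated error-free), multiple subjects or
occlusion between them, appearance or lighting, detector drift, and any
correlation between confidence and box geometry. Passing recovery tests
therefore show that the filter finds persistent stationary mislabels under
realistic geometry and noise — not that it would survive, say, a detector
whose false positives jitter as much as its true ones.

## Numerical and degenerate-input choices

- Percentages: half-up rounding at one decimal via `Decimal`, applied only
  at display; sums and conservation checks use unrounded floats with 1e-9
  tolerance where floating division is involved, and integer counts where
  possible.
- Empty inputs: empty tracks are valid everywhere (empty coordinate
  series, 100% unlabeled budgets, empty plateau reports); a zero-frame
  session cannot be budgeted.
- Duplicate frames and multi-object VOC files are errors by default
  (single focal subject); explicit flags keep the most confident / first
  object instead.
- Frame indices are 0-based internally; VOC filename stems with 1-based
  numbering are normalized via `index_base=1`.
- The pipeline's report CSVs (budgets, comparisons, plateau report) are
  plain tables; the detection-format outputs (thresholded and corrected
  tracks) re-parse with the package's own readers, corrected files via the
  `False Positive Locomotion` label.

## Problem sizes in tests

The default synthetic scenario uses 4,348 frames — the 12-h comparison
session scaled by ten — which keeps a full session comfortably inside a
unit-test budget while leaving dozens of bouts per session; occupancy
calibration uses 100k-frame sequences, and filter recovery pools ten
replicate sessions.

## Known limitations

- The plateau parameters and posture limits that best match any particular
  enclosure are empirical; the defaults are engineering choices.
- A subject genuinely pacing in place (movement smaller than ε) is
  indistinguishable from a false positive; conversely slow drift just
  above ε is never flagged.
- The filter assumes one subject: with multiple animals, box identity
  switches would corrupt the coordinate series.
- Budgets treat frames as exchangeable; no bout-level or sequential
  statistics are computed on real data.
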