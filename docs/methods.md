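# Methods

`handuse` detects, frame by frame, whether a hand seen in egocentric video
is interacting with an object, and — within bimanual interactions — whether
it acts as a *stabilizer* (static contact, constant hand-object contact
area) or a *manipulator* (moving the object, contact area changing over
time). The intended unit of reporting is the clinical hand side of a
stroke survivor: the more-affected versus the less-affected hand.

## Pipeline

The pipeline operates downstream of hand detection and segmentation: its
inputs are ordered colour frames plus, per frame and per hand, a bounding
box, a binary segmentation mask, and (for training/evaluation) interaction
and role labels. Detection and segmentation themselves are out of scope;
boxes and masks come from annotation files or from the synthetic scene
generator. The quality of externally supplied boxes can still be audited
with the IoU matcher (`evaluation.match_detections`), which counts a
predicted box as a true positive when its IoU with the same-side ground
truth is strictly above 0.15.

Stages, with their defaults:

1. **Region partition** (`region_features.partition_regions`). Around each
   hand box, three disjoint pixel sets covering the frame exactly: *hand*
   (mask ∩ box), *surround* (box expanded ×1.5 about its centre, minus the
   hand pixels) and *background* (rest of the frame). The expansion factor
   is configurable; 1.5 keeps the surround a thin collar in which a held
   object is expected to appear.
2. **Colour features** (6 values). Per-channel HSV histograms (32 bins;
   hue over the full circle, S and V over [0, 1]) per region, compared
   with the Bhattacharyya distance `sqrt(1 − Σ√(p·q))`: three channels ×
   {hand-vs-surround, surround-vs-background}. The histograms are 1-D per
   channel rather than joint; the bin count is a package choice — the
   distances are insensitive to it over a broad range.
3. **Motion features** (60 values). Dense optical flow between consecutive
   frames (iterative Lucas–Kanade, `skimage.registration.optical_flow_ilk`,
   radius 7, 2 warps; the algorithm is pluggable behind the `dense_flow`
   contract). Per region, a 15-bin magnitude histogram over [0, m99]
   (m99 = 99th-percentile magnitude over the frame, larger values clipped
   into the top bin) and a 15-bin direction histogram over [0, 2π), with
   angle = atan2(−dy, dx) so bin 0 starts east and proceeds
   counter-clockwise in the y-down image frame. The feature is the
   *bin-wise signed difference* of histograms for the two region pairings
   (2 pairings × 2 histogram kinds × 15 bins). The first frame of every
   task has a zero flow field; its motion features are zeros and the row
   is retained.
4. **Shape features** (60 values). The box crop is resized to 40×72
   (width × height — hands are taller than wide in egocentric crops), and
   a HOG is computed with 16×16-px cells, 2×2-cell blocks at one-cell
   stride, 9 unsigned orientation bins, L2-Hys normalization: 108 raw
   values, reduced to 60 principal components. The PCA is fitted on
   training-fold rows only inside every cross-validation split and applied
   to the held-out rows; fitting it globally would leak test information.
5. **Size-change feature** (10 values, role stage only). Forward
   differences of the mask pixel count over the 10 following frames,
   normalized by the current frame's count. Differences reaching past the
   end of the task contribute 0, which keeps row/label alignment trivial
   at task boundaries.
6. **Classification** (`classifiers`). One binary random forest with 150
   trees per stage and per cross-validation fold, trained on instances
   pooled from both hands (pooling maximizes the scarcer more-affected
   interaction instances; side-specific models are not used). Interaction
   rows carry colour + motion + shape (126 features); role rows carry
   motion + shape + size change (130 features) and exist only on frames
   with a role label, within bimanual tasks. Scores are positive-class
   probabilities (average tree vote); see *Numerical choices* for the
   bootstrap sample size, the one hyperparameter not left at the
   library default.
7. **Temporal post-processing** (`temporal_postprocess`). Scores are
   smoothed by a centred 120-frame moving average (4 s at 30 fps) with
   truncated windows at task edges, min-max normalized per task, and
   thresholded at 0.5 with strict-above semantics (exactly 0.5 maps to
   the negative class: no interaction / stabilizer). Ground-truth label
   tracks pass through the *same code path* before any metric is
   computed, so predictions and annotations are compared on equal footing.
8. **Evaluation** (`evaluation`). Leave-one-subject-out (LOSOCV) and
   leave-one-task-out (LOTOCV) cross-validation. Fold metrics (F1,
   precision, recall, accuracy) pool the fold's frames; scheme summaries
   are fold means ± SD. Metrics with a zero denominator are *undefined*
   and excluded from averages rather than scored 0 — in particular a
   held-out hand-waving task has no true positives, so it contributes
   accuracy but no F1, while the waving tasks not held out remain in
   every training set. Per-subject interaction percentage (interacting
   instances / labeled instances, per side) is correlated with
   per-subject F1 (Pearson) to probe whether low hand use depresses the
   score.

## Degenerate tracks

Min-max normalization after heavy smoothing has a known degenerate case:
a track that is (nearly) constant — a task that is interaction throughout,
or a waving task with no interactions — has zero range. The package maps
such tracks to all-zeros and flags them; evaluation then sees an
all-negative truth track, for which only accuracy-style metrics are
defined. A related artefact is that on a truly all-negative task the
*prediction* track's residual noise is stretched across [0, 1] by the
normalization, producing spurious positives; this is inherent to the
per-task normalization design and is the reason no-interaction tasks are
scored by accuracy only.

Role tracks are post-processed over the sequence of role-labeled
instances (interaction frames), indexed consecutively; gaps between
interaction segments are not expanded to wall-clock frames.

## Synthetic scenes

The generator (`synthetic_scenes`) renders two textured ellipse "hands"
over a smoothed-noise background at 30 fps. During an interaction segment
a textured, distinctly-hued rectangle "object" sits at the hand's edge —
static for a stabilizer (whose mask area is exactly constant), riding
along for a manipulator (whose mask area fluctuates by ±25 % per frame).
Hands in contact with anything take a rotated "grasp" ellipse pose.
Movement alone is deliberately uninformative: manipulator hands follow
the *same* sinusoidal waving path as non-interacting hands, and waving
hands also flicker in area, so interaction must be read from the object
in the hand's surround, not from trajectory or flicker. Gaussian pixel
noise is added after compositing. Internal textures translate rigidly
with their carrier so dense flow has structure to track.

Cohorts default to 9 subjects × (6 interaction tasks + 2 waving tasks),
the structure of the study the pipeline is designed for. Every
interaction task is bimanual: each hand interacts in one contiguous
block per task, swapping stabilizer and manipulator roles halfway (a
single constant role per task would collapse to a degenerate track
after post-processing, and contiguous blocks keep the smoothed truth
track well-conditioned). The last interaction task of each subject is
an *anchor* task whose block spans 58 % of the task: a role track
shorter than about half the smoothing window is constant after the
truncated-window moving average (every window spans the whole track)
and degenerates to all-stabilizer, so the anchor guarantees each
subject at least one role track long enough to survive smoothing. The
other five tasks carry variable fractions (capped at half the task)
that spread per-subject ground-truth interaction percentages
monotonically over roughly (0.12, 0.35) for the less-affected hand,
scaled ×0.75 for the more-affected hand.

Per-subject difficulty decreases with the planted fraction, so subjects
who use a hand less are also harder to score — a planted positive
F1-versus-percentage relation whose *sign* (not its magnitude) the
correlation analysis must recover. Three dials shrink with hand use:
object size, object-hue contrast against the background, and pixel
noise; the decisive fourth is *rest-contact*: a growing share (up to
18 % of each task) of the low-use subjects' non-interaction time is
spent with the hand statically resting on a full-size object — visually
identical to a stabilizer but labeled non-interacting, mirroring the
field's functional-purpose definition under which a hand resting on an
object does not count as an interaction. Because rest-contact blocks
are appearance-equivalent to stabilizer blocks, no classifier can fully
separate them; the induced F1 loss scales with the planted share, which
no frame-level noise could achieve once the 120-frame smoothing and
per-task normalization have averaged it away. Per-subject hand and
background hues are jittered, giving subject-aware cross-validation
(LOTOCV) a subject-specific appearance signal unavailable to LOSOCV.

Scale: cohorts render at 128×72 px with 120 frames (4 s) per task. These
sizes were chosen so that a full end-to-end double cross-validation runs
on a laptop-class single core; frame geometry (hand size, wave amplitude,
object size) scales with frame width, and nothing in the feature stack is
resolution-specific. Single tasks default to 640×360, the resolution the
pipeline targets on real video. What the generator does *not* emulate:
photorealistic hands and objects, finger articulation and occlusion,
camera ego-motion, lighting changes, or detector/segmenter noise
(ground-truth boxes and masks stand in for detector output; the
`corrupt_boxes` operator provides controlled box noise for
detection-evaluation tests). Passing the end-to-end tests therefore shows
that the pipeline recovers the planted colour/motion/shape/size signals
through the full train–smooth–evaluate loop — not that it would reach any
particular score on real egocentric video.

## Numerical choices

* Histograms are normalized to sum 1 (±1e-9) before any distance or
  difference; empty regions (e.g. no background when a box covers the
  frame) are represented by uniform histograms and flagged.
* `bhattacharyya_distance` refuses unnormalized inputs rather than
  normalizing silently.
* Moving-average edges use truncated windows (divisor = in-range taps),
  not reflection or zero padding — no data is invented at task edges.
* Boxes are 0-based, half-open; IoU is exact integer arithmetic.
  At exactly the 0.15 IoU threshold a detection is a false positive
  (strictly-above rule); at exactly the 0.5 score threshold a frame is
  negative (same rule).
* With several predicted boxes for one hand in one frame, the highest-IoU
  box is matched first; the rest are false positives.
* Random forests use reduced bootstrap samples per tree
  (``max_samples=0.4``): task-held-out cross-validation retrains one
  150-tree forest per fold, and shrinking the bootstrap cuts
  tree-building cost proportionally without measurably changing fold
  metrics on the synthetic cohorts. All other forest hyperparameters are
  the library defaults.
* Folds whose pooled training labels collapse to a single class are
  skipped with a logged reason and excluded from summaries.
* Determinism: generation is fully driven by integer seeds
  (`numpy.random.default_rng`); forests are seeded; PCA uses the
  deterministic full SVD solver. Repeated runs with the same seeds are
  bit-identical.

## Known limitations

* The synthetic signal family is deliberately easy; absolute synthetic
  metric values say nothing about real-video performance.
* Per-task min-max normalization makes scores incomparable across tasks
  when a task's score range is extreme (see *Degenerate tracks*).
* The role stage assumes bimanual tasks are identifiable a priori and
  that role labels exist only within interactions.
* Partially visible hands are expected to arrive unannotated; they are
  excluded from training and metrics rather than imputed.
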