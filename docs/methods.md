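# Methods

This note documents the models and procedures `rovannot` implements, the
defaults and why, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real survey data.

## The pipeline in one paragraph

Long ROV movies are split into fixed-length clips that many citizen
scientists classify independently; agreement-thresholded consensus turns
those raw choices into per-clip species labels and first-appearance times.
Still frames sampled after the first appearance are annotated with
rectangles by several more annotators; depth-thresholded region consensus
turns the rectangles into training boxes for an object detector. The
detector's raw per-frame output is thresholded on confidence and linked
across consecutive frames into observation periods — the ecological unit
exported as a Darwin Core occurrence — and periods are intersected with a
spatial grid's footage spans to produce presence/absence maps that are
evaluated against expert labels.

## Clip and frame planning

Movies are cut into consecutive clips of `clip_len_s` (default 10 s,
matching the subjects citizen scientists can annotate attentively) starting
at t = 0; a trailing remainder shorter than one clip is dropped rather than
padded so all subjects have identical length. Frames are indexed 0-based
with frame *k* covering `[k/fps, (k+1)/fps)`; a timestamp maps to a frame
by `floor(t·fps)`. Frame sampling takes the consensus first-appearance
time `t0` (clip-relative) and plans `t0, t0+1 s, t0+2 s`, truncated both at
`max_frames` (default 3) and at the clip end; with first appearances
uniform over a 10-second clip this yields between 2 and 3 frames per clip
on average.

## Clip consensus

A choice is retained for a clip iff the number of *distinct* annotators
selecting it is at least `min_support(n, threshold) = min{k : k/n ≥
threshold}`, where `n` is the number of distinct annotators **on that
clip** — never a global constant — so 8 annotators at the 0.8 default
require 7. `min_support` is computed by ceiling with an explicit fix-up
loop so binary-float rounding of `threshold·n` can never move the result
off the exact rational definition (e.g. `0.6·5` evaluating to
`3.0000000000000004` must still give 3).

Supporters' first-seen times are combined by arithmetic mean. Individual
counts are combined by the *lower median*: the aggregation of counts was a
genuinely open design point; the median resists the occasional wild count,
and taking the lower middle value on even splits keeps the statistic an
integer an annotator actually reported. An annotator selecting the same
choice twice on one clip counts once (first record wins). Retention is
monotone: raising the threshold can only shrink the retained set — the law
behind the bundled matrices' citizen-positive totals rising 113 → 337 → 559
as the agreement bar drops 80% → 60% → 40%.

## Box consensus

"Agreement" on rectangles is formalised as depth thresholding: the
consensus region of a frame is the set of points covered by rectangles from
at least `k = min_support(n, threshold)` distinct annotators, where `n`
counts every annotator who submitted the frame — including those who drew
nothing, since "no individuals here" is an answer. An annotator's own
overlapping rectangles count once. Each 4-connected component of the
region becomes one consensus box (the component's axis-aligned bounding
box, since detector training needs rectangles), with support equal to the
maximum depth inside it. This reduces to the plain intersection of
rectangles when each annotator draws one box, and handles any number of
objects per frame.

The production path computes the region exactly with a
coordinate-compressed 2-D sweep (the rectangles' x/y edges partition the
plane into cells on which coverage is constant; connected components of
cells are connected components of the plane region because adjacent cells
share a positive-length edge). A deliberately naive per-pixel oracle
(≤ 512×512 canvas, integer coordinates) exists solely as an independent
cross-check; the suites compare the two on hundreds of random instances and
require exact equality of boxes and supports.

## Tracker augmentation and color correction

Each consensus box is propagated through subsequent frames by grayscale
normalized cross-correlation template matching: the patch under the
previous box is searched within ±20 px of its last position, the best
placement is accepted while its NCC score ≥ `stop_score` (default 0.5), and
the template is refreshed after every accepted step so slow appearance
changes are tolerated. NCC was chosen because it is deterministic,
dependency-light and exactly testable; `max_steps` defaults to 10, giving a
ten-fold augmentation for persistent objects. Propagation stops at the
first score below threshold (typically the object leaving the view) and
never emits a box outside the frame.

Color correction is gray-world white balance (scale each channel mean to
the overall mean; a zero-mean channel passes through) followed by a linear
contrast stretch mapping the balanced image's 1st/99th percentiles to
0/255. The stretch uses one lo/hi pair pooled over the three channels
rather than per-channel pairs: on 8-bit frames, per-channel percentile
estimates differ by up to a quantisation step and the resulting per-channel
gains re-tilt the channel means that the white balance just equalised;
pooling preserves the balance exactly and is identical for grayscale
content. The operation is idempotent to within 1 gray level in the channel
means and leaves an image with no dynamic range unchanged.

## Observation aggregation

Detections below the confidence threshold are discarded. Within a movie,
a surviving detection at frame f+1 extends a period whose last member is at
frame f iff the IoU of its box with the period's last box **strictly
exceeds** `link_iou` (default 0.5, i.e. "more than 50% overlap"; an IoU of
exactly 0.5 splits). When several detections and several live periods are
eligible, pairs are matched greedily in descending IoU (deterministic
tie-break by input order); each detection joins at most one period and
unmatched detections open new periods. A `gap` parameter tolerates missing
frames but defaults to 0: continuity means strictly consecutive frames.
On streams with at most one detection per frame, greedy linking provably
equals the brute-force segmentation that splits exactly where the frame gap
exceeds 1 or the IoU fails the threshold; the suites check this equivalence
on random streams.

A grid square is labelled Coral iff at least one observation period lies in
the same movie and its closed frame interval intersects the square's
footage span. Because raising the confidence threshold only removes
detections, the Coral square set is monotone non-increasing in the
threshold — the law behind the bundled square matrices' machine-Coral
totals falling 67 → 57 → 29 across 0.5 → 0.7 → 0.9.

## Evaluation

Confusion matrices are plain 2×2 contingency tables over a shared unit set
(rows expert, columns pipeline). `best_threshold` maximises accuracy with
ties going to the *higher* threshold: when two settings perform equally the
conservative one produces fewer false-positive occurrences, which is the
preferred error direction for automated species maps.

Detection metrics use greedy confidence-ordered matching (each prediction
takes the unmatched truth box of highest IoU ≥ 0.5) and all-point
interpolated average precision — the interpolation variant was an open
choice and all-point is exactly defined and oracle-checkable. With a
single class, mAP@0.5 equals AP@0.5. The exhaustive reference enumerates
every injective prediction→truth assignment, preferring more matches, then
higher total matched confidence, then higher total IoU. Greedy equals the
exhaustive optimum whenever ground-truth boxes are pairwise disjoint (a box
cannot have IoU > 0.5 with two disjoint truths), so the equivalence suites
generate scenes with non-overlapping truth objects — the realistic case of
distinct individuals; with heavily overlapping truths greedy matching can
in general be suboptimal, as in every standard detection benchmark.

Edge conventions: no truth and no predictions is vacuously perfect (all
metrics 1); predictions without truth give precision 0; truth without
predictions gives recall 0.

## Synthetic data: what it emulates and what it does not

Scenes place slowly drifting boxes (≤ 1 px/frame by default, so
consecutive-frame IoU stays far above the link threshold) on a virtual
canvas; clip-level truth (presence, first full appearance, count) is
derived from the tracks. Annotators are Bernoulli classifiers with stated
sensitivity/specificity, Gaussian first-seen noise, bounded integer count
noise, and rectangles jittered by independent Gaussian offsets on each
corner (corner jitter, not center+size, so intersections of jittered boxes
are non-trivial). Detector streams emit one detection per present
track-frame with confidence from a Gaussian clamped to [0.01, 0.99] (so
threshold sweeps never degenerate) plus spurious uniform-confidence boxes
at a per-frame false-positive rate. Rendered frames are a static seeded
noise texture with a high-contrast ellipse per present box, multiplied by
an RGB gain triplet to emulate the underwater color cast.

All generators are pure functions of (parameters, seed). In the noiseless
limits they reproduce ground truth exactly through every downstream stage,
which the end-to-end identity suite exploits.

What passing these tests shows: the aggregation, consensus, linking and
evaluation *algorithms* are correct against independent oracles and exact
ground truth, and behave monotonically as their thresholds move. What it
does not show: performance on real footage — real annotators are
correlated and improve with practice, real detectors have structured
(non-independent) errors, and real underwater imagery has motion blur,
lighting gradients and occlusion that the flat textured renders do not
model. The study-scale headline detector metrics are therefore out of
scope here; they require trained weights and the original footage.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| clip_len_s | 10 | s | attention span of a crowd annotation subject |
| max_frames_per_clip | 3 | frames | up to three stills per positive clip, 1 s apart |
| clip/frame agreement threshold | 0.8 | fraction | minimises citizen false positives (7 of 8) |
| link_iou | 0.5 | IoU | "more than 50% overlap" linking rule (strict) |
| conf_thresholds | 0.5 / 0.7 / 0.9 | fraction | the swept operating points; 0.7 wins on the bundled matrices |
| tracker max_steps | 10 | frames | ten-fold training-data augmentation |
| tracker stop_score | 0.5 | NCC | propagation stops when the match halves |
| search_radius | 20 | px | generous for ≤ a few px/frame drift |
| split_ratios | 0.7/0.2/0.1 | — | conventional train/val/test apportionment |
| annotator sens/spec | 0.9 | probability | competent non-expert annotators |
| box_jitter_sd | 2 | px | hand-drawn rectangle imprecision |
| box_miss_prob | 0.05 | probability | occasional overlooked individual |

## Problem sizes in the test and acceptance suites

The oracle-equivalence suites use 500 random frame instances (200×200
canvas, 3–8 annotators, 0–4 boxes each, thresholds 0.4–1.0), 300 random
detection streams (40 frames) and 300 random metric instances (≤ 4 truth
boxes, ≤ 6 predictions — the exhaustive oracle is factorial). The
false-positive experiment uses 500 absent clips × 8 annotators × 20
replicates; end-to-end identity runs on a 100-second, 3-track scene; the
miniature CLI study uses two 200-second movies. These sizes keep the whole
suite around ten seconds while every instance count stays large enough for
the stated empirical tolerances.

## Known limitations

* Box-consensus components that touch only at a corner are distinct
  (4-connectivity); a survey preferring 8-connectivity would merge them.
* Greedy period linking is deterministic but not globally optimal when many
  objects overlap heavily in the same frames.
* The Darwin Core export covers occurrence-core fields only, one record per
  observation period with `individualCount = 1`; counts per period are not
  estimated. Absent recording dates export as empty `eventDate` rather
  than being fabricated.
* The NCC tracker assumes approximately constant object scale; it does not
  handle zoom or rotation.
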