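# Methods

This note documents the models, parameter choices and numerical decisions
behind `affectfar`, and what the synthetic validation does and does not
establish about real clinical video.

## Face normalization and grid descriptor

Frames are aligned by the least-squares (Umeyama) similarity transform —
rotation, isotropic scale, translation — mapping the frame's landmarks
(left/right eye, nose tip, mouth corners, chin) onto fixed canonical
positions, then resampled bilinearly into a `out_size × out_size` face box
(default 96 px) with out-of-source pixels set to 0.  Degenerate landmark
configurations (coincident points, rank-deficient fits, near-zero scale)
raise instead of producing a collapsed image.  Similarity alignment
corrects rigid in-plane pose only; out-of-plane rotation, illumination and
non-rigid deformation are out of scope.

The video descriptor is X_r[n], the mean gray level of grid cell *r* at
frame *n*.  The grid defaults to 8×8 on a 96-px face: coarse enough for
stable cell means, fine enough that the six facial parts are unions of
whole cells.  `out_size` must be divisible by the grid dimensions so all
cells are exactly equal-sized; cells are indexed row-major from the
top-left, coordinates are 0-based with x rightward and y downward, and
color input is reduced to gray with the standard luma weights
0.299R + 0.587G + 0.114B.

The six-part partition (left/right eye, left/right cheek, mouth, nose) is
defined by rectangles in normalized [0,1]² face coordinates; a cell
belongs to a part iff its center lies inside the rectangle.  The default
rectangles sit on eighth-gridlines (eyes in the upper third, nose central,
mouth in the lower third, cheeks lateral), so on the default grid each
part is an exact union of cells.  Composite regions (eyes, mouth+nose,
cheeks, all parts) are exact unions of their constituents.

## Mid-level features

* **Expression** (length 7): one linear one-vs-all scorer per expression
  class (norm, anger, disgust, fear, happiness, sadness, surprise — fixed
  order) applied to each frame's cell vector.  The per-video aggregate of
  the per-frame score vectors is the arithmetic mean — the simplest
  length-invariant choice; max- or histogram-pooling would be drop-in
  alternatives.  Score ties resolve to the lowest class index, so an
  all-zero scorer labels a frame "norm".
* **Label** (length 1): the number of frames whose argmax expression
  differs from the previous frame's.
* **Motion** (length 1): the standard deviation over frames of the
  per-frame mean gray level of the selected cells, with the *population*
  denominator (N, not N−1) — fixed here for reproducibility.
* **Combinations**: motion⊕label (length 2) and motion⊕expression
  (length 8), motion first.  Combining features from different patients is
  an error.

Per-part analyses use the motion feature only: the expression scorers see
the whole face, so expression-derived features are not meaningful for a
single region.  The expression model used in the pipeline is trained on
synthetic labeled frames from the generator; it is pluggable — users with
a real expression corpus can substitute their own scorers.

## Classification and evaluation

Multiclass prediction uses one binary linear SVM per affect class
(`SVC(kernel="linear")`, C = 1 by default) against the rest; a sample
takes the label of the highest-response classifier, ties resolving to the
class earliest in the domain's fixed order.  Features are standardized
with training-fold statistics only (switchable): the concatenated kinds
mix a gray-level SD with a transition count and would otherwise be
dominated by one component.  Evaluation is leave-one-out over patients;
with n ≈ 25 and rare labels, folds where a class appears only in the
held-out sample are routine, so classes absent from a training fold get a
constant most-negative scorer, and a fold whose training labels are all
identical yields a flagged always-predict model rather than an exception.
A rater with no label variance at all is skipped with an explicit reason
recorded.  The improvement coefficient is LOO accuracy divided by the
frequency of the rater's most common label (chance baseline); it is
computed by the formula even where a published table prints a different
value.

On a one-dimensional feature (motion), the one-vs-all argmax is the upper
envelope of K lines, which can represent at most K ordered intervals and
in practice often fails to award the middle classes of a 4-class ordered
domain; LOO accuracies near 50–60% on well-separated range classes are an
intrinsic property of this classifier family, not an implementation
defect.

## Agreement and regression statistics

Agreement between two raters is the raw percentage of patients with
identical labels — no chance correction, by design.  The summary over a
rater panel is the mean and *sample* SD (denominator n_pairs − 1) of the
n(n−1)/2 unique off-diagonal entries, reported at full precision and
rounded to integer percent.

Feature–label association uses multinomial logistic regression:
LR = 2(ll_full − ll_null) against an intercepts-only baseline, referred to
χ² with (K−1)·p degrees of freedom for K observed classes and p
predictors.  The intercept-only log-likelihood has the closed form
Σ_k n_k log(n_k/n).  Zero-variance predictors are dropped with a warning
(p = 0 reduces the model to the baseline: LR = 0, p-value 1).  Cells with
a single observed class or with n ≤ (K−1)(p+1) parameters are skipped
with a machine-readable reason rather than fitted.  When the unpenalized
Newton fit fails or does not converge (perfect separation), a
bounded-iteration ridge-regularized fit supplies the likelihood and the
row is flagged.  Raw p-values are reported; Benjamini–Hochberg correction
is available but off by default.

The χ² reference is asymptotic: at n ≈ 25 with 4 outcome classes (8
parameters) the test is anti-conservative (≈ 11% rejections at the 5%
level under label permutation in our checks), which small-cohort results
inherit; at n = 200 with 3 classes the measured type-I error is ≈ 5%, and
the permutation-null uniformity property is verified at n = 100.

## Synthetic cohort generator

The generator emulates the study conditions — 25 patients, 5 raters, one
short video per patient — with known ground truth.  Videos default to 300
frames, scaled down from the study's 7–10-minute interviews; every
feature used is length-invariant (means, SDs, counts per video), so video
length affects only estimation noise.

**Face model.**  A parametric gray face (elliptical head and features at
the canonical landmark positions) on a 96-px canvas.  Dynamics are
intensity modulations over the six *rectangular* part regions — the same
rectangles as the analysis partition, which makes generator physics and
partition geometry coincide and gives closed-form feature expectations
(a pure sinusoid of amplitude A on the eye rectangles yields an eye-cell
motion SD of exactly A/√2 over whole periods):

* a shared sinusoid (period ~ U(40, 80) frames, random phase) whose
  per-region amplitude is `region_weight × range_amplitude`, with range
  amplitudes flat 2 / blunt 6 / restricted 12 / full 20 gray levels and a
  ±20% per-video jitter — the monotone ordering is the constructed ground
  truth the motion feature recovers;
* a two-state expression process switching between neutral and a
  quality-typical expression (dysphoric → sadness/anger, euthymic →
  norm/happiness, manic → surprise/happiness) at ~1 switch per 60 frames
  (doubled for agitated subtypes: anxious, frightened, irritable).
  Expression templates are approximately zero-mean over the face, so
  switching reshapes the face without moving the per-frame mean — the
  motion feature then isolates the oscillation amplitude;
* N(0, 2²) pixel noise and an optional per-video rigid pose offset
  (rotation ≤ 0.06 rad, scale ±5%, translation ≤ 3 px) that the
  landmark-based normalization must undo.

All effect sizes are free parameters of the generator — no quantitative
description of real patients' facial dynamics exists to calibrate them —
chosen once to make the recovery experiments well-posed, and exposed in
`EffectConfig`.

**Rater model.**  Each rater passes the latent label through a per-rater,
per-domain row-stochastic confusion matrix, independently per patient and
domain.  With a shared matrix C and latent prior π, expected pairwise
agreement is Σ_j π_j Σ_k C[j,k]², an analytic target the simulation is
tested against.  Default matrices are `r·I + (1−r)/K·J` with reliability
r = 0.9 (quality, range) and 0.7 (subtype): senior raters mostly follow
the latent presentation.  Emulating the *observed* clinical agreement
levels (≈ 54/43/25%) instead requires r ≈ 0.55/0.5/0.4 — at which point
each rater's labels are dominated by idiosyncratic noise that no
video-based predictor can recover, because the noise is independent of
the video by construction.  Real raters disagree *systematically* (each
one is internally consistent with the footage), which is exactly why the
study could predict individual raters despite low inter-rater agreement;
the independence assumption is the model's main simplification.

**Latent priors.**  quality (0.2, 0.7, 0.1) — euthymic-dominant; range
(0.2, 0.3, 0.3, 0.2); subtype unknown 0.35, stupid 0.20, others 0.045
each, loosely following the inpatient profile of the study's distribution
tables.

## What the validation shows — and does not

Passing tests establish that the pipeline recovers constructed signals:
agreement statistics match their analytic expectations; the motion
feature achieves mean LOO improvement ≥ 1.2 on the range domain across
seeds; eyes-only-signal cohorts rank the eye region's p-value below the
cheeks' in ≥ 90% of replicates; the LR test is calibrated at adequate n.
They do not establish photorealism, robustness to real-world detection
and tracking failures (landmarks are ground truth here), or that real
raters behave like confusion-matrix annotators.  Published-table numbers
(agreement summaries 43 ± 16 and 25 ± 13, improvement coefficients) are
recomputed from the shipped tables by the stated formulas.

## Problem sizes

Default runs use 25 patients × 300 frames at 96 px; the LOO recovery
experiment averages 10 cohorts and the face-part ranking experiment 50
(rendered in canonical pose and read directly off the frames; alignment
is exercised by the pipeline runs and the LOO experiment).  The null
calibration uses 1000 replicates at n = 200.  These sizes keep the whole
validation on a desk machine while leaving Monte-Carlo margins well clear
of the thresholds.
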