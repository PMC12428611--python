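# Methods

## Problem and overall design

Colon capsule endoscopy (CCE) produces tens of thousands of frames per
procedure; before any diagnostic reading, the recording must be judged
adequately clean. The CC-Clear scale grades cleanliness 0–3 from the
percentage of visible colonic mucosa. `capclean` implements a three-stage
pipeline that proposes CC-Clear scores for 10-minute video segments while
requiring only cheap, binary patch-level annotation:

1. **Weakly supervised segmentation.** An image → per-pixel probability
   model is trained to mark intraluminal content (stool, debris, bubbles,
   bile) from binary labels on randomly sampled 64×64 patches, via a
   cross-entropy loss restricted to labeled patches ("patch loss").
2. **Visibility features.** Each frame's binary content mask is converted
   to a visibility score — the unobscured fraction of the field of view
   (FOV) — and each clip's visibility series is binned into the four
   CC-Clear regions (<50 %, 50–75 %, 75–90 %, ≥90 %), giving a 4-vector of
   frame counts per clip.
3. **Segment classification.** A Random Forest (100 trees, depth 2) maps
   the 4-vector to a CC-Clear score under leave-one-out (LOO)
   cross-validation, trained either per individual rater or on the panel
   consensus (mean score rounded to the nearest integer; exact halves away
   from zero). Agreement is measured with unweighted Cohen's kappa.

Real CCE recordings are not redistributable, so the package ships a
synthetic-data module that generates phantoms with known ground truth;
every stage is validated against that truth.

## The patch loss

For a batch of B patches with binary labels `y_k` (1 = content that could
hide pathology) the loss is

    L = -(1/B) Σ_k Σ_{(i,j) ∈ P_k} [ y_k log p_ij + (1-y_k) log(1-p_ij) ]

i.e. each patch's label is broadcast to all of its H×W pixels and ordinary
cross-entropy is applied there; pixels outside labeled patches contribute
nothing (their gradient is exactly zero). The pixel reduction defaults to
the plain sum; a `"mean"` reduction (divide each patch term by H·W) is
offered because summed losses scale with patch area. Probabilities are
clamped to [1e-7, 1−1e-7] before the logarithm.

A consequence worth understanding: the minimizer of this loss at a pixel
is the *expected patch label* given the image, not the pixel's true class.
A clean pixel that mostly appears inside dirty-labeled patches is pushed
toward 1. Thresholding at 0.5 therefore recovers the true mask only when
content is spatially clustered enough that most pixels inherit the label
of their own region — which holds for real debris and for the phantoms
(see below). This is an inherent property of patch-level supervision, not
an implementation artifact.

## Segmentation backbone and training

The backbone is a deliberately small fully convolutional U-Net (one
down/up level; widths 8 and 16; ≈7 k parameters) implemented directly on
NumPy with explicit backpropagation. Content in endoscopic frames is
largely separable by color and local texture, so a shallow network
suffices at desk scale; the supervision scheme is the object of study, not
backbone capacity. A transformer-hybrid encoder is recognized in the
configuration but not provided.

Training details (defaults in `SegmenterConfig`):

- inputs scaled to [−0.5, 0.5]; leaky ReLU (slope 0.1) everywhere — plain
  ReLU occasionally collapsed whole layers under large early steps;
- one Adam step per frame per epoch, batch = that frame's labeled patches
  (at most `batch_size` = 8, resampled each epoch); learning rate 1e-2
  with cosine decay to 0 over the run; 30 epochs;
- the head gradient uses the fused sigmoid/cross-entropy form
  (∂L/∂z = (p − y)/B on patch pixels), which is exact and avoids
  clamping pathologies;
- everything is driven by a single seed; identical seed and data give
  bit-identical weights.

Post-processing follows the two-step rule: Gaussian-blur the probability
map with σ = 0.4 px (σ is configurable; the original description gives
only a kernel "size" of 0.4, which is read as a standard deviation in
pixels — the only self-consistent interpretation at that magnitude), then
binarize with a strict `> 0.5` comparison, so a probability of exactly 0.5
is clean.

Mask quality is scored as mean intersection-over-union (mIoU) of the
content class over held-out frames, with the convention that an image
where both masks are empty scores 1 (a correct all-clean prediction).
The comparison baseline is a patch-tiling classifier: logistic regression
on per-channel patch mean/std, painting each tile with its patch verdict
(stride = half a patch, majority vote on overlaps) — the approach
patch-level classification methods use to produce a pseudo-mask.

## Visibility and features

The FOV mask is computed by intensity: pixels whose 3×3-median-filtered
maximum channel value exceeds 10/255. (For synthetic frames a fixed
inscribed circle is also available.) Visibility of a frame is
`1 − |mask ∧ fov| / |fov|`. Timelines may be smoothed with a centered
moving average (window truncated at clip edges; default plot window 25
frames); the four bin edges 0.50 / 0.75 / 0.90 partition [0, 1] with each
boundary belonging to the upper bin, so the verbal bands "<50, 50–75,
75–90, >90" become a true partition. Frame counting for the classifier
uses the raw (unsmoothed) series by default; the smoothed series drives
the colored band in the timeline plot.

## Segment classification and agreement

Features are the raw 4-bin counts (a normalization flag exists for
variable-length clips, off by default since study clips share one length).
The classifier is scikit-learn's RandomForestClassifier with 100
estimators, `max_depth=2`, unweighted classes, fixed `random_state`; any
sklearn-style estimator can be substituted through
`ClassifierConfig.estimator_factory`. LOO evaluation fits one forest per
held-out clip; a fold whose training targets are single-class predicts
that class and logs a warning.

Cohen's kappa is computed unweighted from the contingency table,
symmetrized so κ(a, b) equals κ(b, a) bit-exactly; when both raters are
constant and identical (expected agreement 1) κ is defined as 1. Linear
and quadratic weights are available behind a flag for sensitivity
analysis. Score-distribution summaries report both the population and the
sample (n−1) standard deviation; the sample convention is what matches
published "mean ± sd" tables at two decimals for all three raters
(population sd differs in the second decimal for one of them).

A known LOO artifact is documented by test: with completely
uninformative features and *exactly balanced* targets, the held-out
class is always the training minority, the forest systematically avoids
it, and κ = −1/3 rather than 0. With a clear majority class, κ sits at
chance as expected.

The chance floor for an observed agreement is computed with the standard
label-permutation test: the LOO predictions are held fixed and the target
vector is permuted, which destroys the pairing while preserving both
marginals and yields an unbiased null (`permutation_null_kappas`). The
alternative of *retraining* the LOO pipeline on each permuted target
vector inherits the artifact above in diluted form — excluding a clip
tilts the 51-clip training balance against that clip's own permuted
label — and its κ distribution centers near −0.07 rather than 0 at this
study size, so it does not represent chance agreement.

## Synthetic phantoms: what they emulate and what they do not

`generate_frame` renders a bright circular FOV (radius 0.48·size) over
near-black corners, pink mucosa-like background (RGB ≈ 190/110/110 with
low-frequency texture), and yellow-brown content (RGB ≈ 180/140/60). The
content region is built by thresholding a two-scale Gaussian-noise field
(correlation lengths `blob_scale` and 3·`blob_scale`, coarse component
weighted 1.5×) at the quantile achieving the requested FOV coverage. The
two scales matter: the fine one gives the irregular, ill-defined borders
typical of intraluminal debris, and the coarse one pools content into
localized regions the way debris actually collects — which is also what
makes patch labels locally informative (see the patch-loss discussion).
Coverage is exact by construction (quantile thresholding), so the
generator's `dirty_fraction` is within ±0.01 of target in practice and
the contract allows ±0.05.

`generate_clip` draws a mean-reverting AR(1) visibility walk (φ = 0.9)
anchored mid-band per class — anchors 0.30 / 0.625 / 0.825 / 0.955 with
innovation sd 0.035 / 0.020 / 0.012 / 0.008 — clipped to [0.06, 1] so
every frame stays renderable. Rendered frames target coverage
1 − visibility. `simulate_raters` draws scores from a 4×4 row-stochastic
confusion kernel; the provided `neighbor_kernel(0.7, 0.15)` puts 0.15 on
each adjacent score (folded back onto the diagonal at the scale ends).

Segmenter training and evaluation frames draw content coverage uniformly
over [0.05, 0.75] — the spread a patch-labeling campaign covers, from
light to heavy occlusion.

The phantoms deliberately do **not** model: photorealistic mucosa,
specular highlights, capsule motion blur, adaptive frame rate, dual-camera
geometry, or content types (bile vs stool). Color separability makes
segmentation easier than on real footage, so passing the desk-scale tests
demonstrates that the weak-supervision machinery works — not that the
small backbone would reach comparable quality on real videos.

## Problem sizes used in tests and the acceptance script

Chosen as the package's desk-scale study design: segmentation uses 60
training and 20 held-out frames of 128×128 px with 8 labeled 64×64
patches per frame and 30 epochs; the scoring study uses 52 clips (13 per
class) of 60 rendered 64×64 frames each, with oracle (ground-truth) masks
isolating the feature/classifier stages from segmenter error; the
permutation null uses 100 target permutations. With these sizes a full
run completes in minutes on one CPU core.

## Known limitations

- An untrained (randomly initialized) network produces large, spatially
  smooth random masks, so its mIoU against content-bearing truth varies
  widely with the initialization seed; the "untrained model scores near
  zero" check in the test suite holds at its fixed seed but is not a
  seed-robust property.
- Held-out mIoU of the trained segmenter varies by roughly ±0.08 across
  seeds at the desk-scale study size (observed 0.68–0.84 over a 5-seed
  sweep during design).
- The patch-tiling baseline is intentionally simple (6 color features);
  it bounds what patch classification alone yields at tile resolution,
  not the state of the art.
- Kappa on 52 clips has a wide sampling distribution; differences of
  ±0.1 between supervision modes are within noise, which is why the
  individual-vs-consensus comparison is asserted only as a tendency
  across seeds.
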