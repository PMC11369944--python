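# Methods

`weedssl` is a desk-scale, fully testable implementation of teacher-student
semi-supervised object detection for multi-class weed scenes. Everything —
data, detectors, training, evaluation — runs from a single CPU in minutes,
so the semi-supervised machinery itself (not GPU plumbing) is what gets
exercised and tested.

## The semi-supervised model

Self-training with a mean teacher. A detector is first trained on the
labeled subset alone (*burn-in*). The trained model is duplicated into a
teacher/student pair; from then on, each iteration:

1. the teacher runs on weakly augmented views of a half-batch of unlabeled
   images and emits **pseudo-labels**: post-NMS boxes whose classification
   score is at least a confidence threshold τ;
2. the student is optimized on the supervised loss of a labeled half-batch
   plus λ_u times two unsupervised terms computed on strongly augmented
   views of the same unlabeled images (same geometry, photometric
   perturbation only, so pseudo-box coordinates transfer unchanged);
3. the teacher tracks the student through an exponential moving average,
   θ_t ← α·θ_t + (1−α)·θ_s, with α = 0.99. α = 1 would freeze the teacher
   and α = 0 would copy the student each step.

Only the teacher is retained for inference. The EMA teacher is a temporal
ensemble of students; its variance reduction is, at this scale, the most
reliable part of the semi-supervised gain.

Pseudo-labels are ranked **by classification score only**. The centerness
branch has no supervision that suppresses its output on background, so its
score is unreliable for ranking teacher proposals; it still participates in
supervised inference scoring.

The **unsupervised classification loss** builds hard one-hot targets from
the pseudo-boxes with the standard all-inside-box assignment and applies
the same IoU-weighted focal loss as the supervised classification
component. The **unsupervised regression loss** is gated per
pseudo-instance: instance *i* contributes ‖d̃_t − d̃_s‖₁ (the L1 distance
between teacher and student regression predictions at the pseudo-box's
source location) only when δ_t + σ ≤ δ_s, i.e. when the teacher's
localization uncertainty undercuts the student's by at least the margin σ.
The boundary case passes; the gate-pass count is non-increasing in σ.

**Localization uncertainty δ** is the mean of the four per-side Laplace
scales predicted by the uncertainty branch, normalized by the box
diagonal. The branch is trained with the per-side Laplace negative log
likelihood |d − d̂|/ŝ + log ŝ against detached regression residuals.

**Empty pseudo-label sets are skipped.** An unlabeled image in which the
teacher found nothing above τ contributes no unsupervised term. Applying
the all-background classification push on such images drives a weak
teacher's confidence down, which removes the remaining pseudo-labels and
collapses self-training entirely; skipping them keeps the pseudo-label
supply alive. (The loss *operation* still defines the empty case as a
background-only loss; the training loop just does not apply it.)

## The detectors

Both variants share a single-level feature grid (stride 8; cell (i, j)
maps to image point ((j+0.5)·8, (i+0.5)·8)) and a two-part network:

- a **fixed feature stem**: per-cell RGB mean and standard deviation pooled
  over the stride window, concatenated over 5×5 cell neighborhoods at
  dilations 1 and 3 (300 features per location, receptive field ±48 px);
- a **learned per-location MLP trunk** (default two hidden layers of width
  128, shared across locations — equivalently 1×1 convolutions) feeding
  linear heads. All gradients are written by hand; no autodiff framework
  is involved.

The **anchor-free** head predicts per-class sigmoid scores, a centerness
logit, four nonnegative side distances (softplus × stride) and four
Laplace log-scales. Targets: every location strictly inside a box is
foreground, assigned to the smallest-area containing box (ties to the
lowest box index), no center sampling. Centerness target
√(min(l,r)/max(l,r) · min(t,b)/max(t,b)). Losses: sigmoid focal
(γ = 2, α = 0.25, background = all-zero one-hot), GIoU on decoded boxes
(analytic gradient, verified against finite differences in the tests),
binary cross-entropy on centerness, Laplace NLL on the scales; all
normalized by the positive-location count.

The **anchor-based** variant is a minimal single-stage head (3 scales ×
3 aspect ratios per cell, IoU ≥ 0.5 positive, < 0.4 negative, band
ignored, each ground-truth box claims its best anchor) standing in for a
two-stage detector, which would be out of proportion at this scale.

The classification term of each positive location is weighted by the
detached IoU between its decoded predicted box and its assigned box,
floored at 0.3: with no floor the classification branch receives almost
no positive gradient before the regression branch has warmed up, and the
detector never starts firing. An exactly-correct box still has weight 1.

Inference: score = max class probability, × centerness probability in
anchor-free supervised scoring only; score floor 0.05; greedy class-wise
NMS at IoU 0.6 (ties broken by input index, so the result is independent
of input order); at most 100 detections per image.

## Synthetic scenes

The generator emulates the statistical structure of small cotton-weed
detection datasets: 3- or 12-class presets, 1–10 boxes per image with a
rare crowded tail (truncated-geometric bulk, mean ≈ 1.8 boxes per image;
1% of images draw 11–25 boxes), geometric-decay class imbalance, and a
cluttered earthy background (low-frequency color field, speckle, dull
clutter blobs). Each class is a parametric shape motif (lobed rosette,
ellipse, star, blade, polygon, cross ...) with a class hue plus
per-instance jitter in hue, saturation, scale (log-uniform 8–22% of the
short side), rotation and texture. Boxes are the tight extents of the
rendered mask, clipped to the image. Identical config + seed reproduces
the dataset byte for byte.

What this emulates: multi-scale colored plants against natural clutter,
class imbalance, crowding. What it does not: perspective, occlusion by
crop canopy, illumination fields, label noise, intra-class morphological
variation of real weeds. Passing tests therefore demonstrate that the
*algorithms* behave as specified and that the semi-supervised mechanism
extracts signal from unlabeled data under controlled conditions — not
that any particular accuracy transfers to field imagery.

Splits use ceil on the validation and test shares with the remainder to
train: |test| = ⌈0.15·n⌉, |val| = ⌈0.20·n⌉, |train| = n − |val| − |test| —
the unique simple convention that yields (550, 170, 128) at n = 848 and
(3670, 1130, 848) at n = 5648. Label fractions use ⌈p/100 · n_train⌉ with
a single seed-determined ordering shared across fractions, so labeled
sets are nested in p.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| α (EMA) | 0.99 | teacher momentum; the reported optimum |
| τ (pseudo threshold) | 0.7 | minimum classification score of a pseudo-box |
| σ (uncertainty margin) | 0.1 | gate margin in δ's normalized units; σ = 0 admits ties |
| λ_u | 1.0 | weight of the unsupervised losses |
| batch | 2 labeled + 2 unlabeled | desk-scale version of the 4+4 field preset |
| iterations | 2000 (burn-in 400 = 20%) | the desk model needs ~2k SGD steps to approach its plateau; 20% burn-in mirrors the usual self-training split |
| SGD | lr 0.02, momentum 0.9 | tuned for this numpy MLP architecture; gradients are globally norm-clipped at 5 |
| image size | 128×128 | desk scale (real data is 10-megapixel) |
| weak resize range | [96, 160] | desk version of the shorter-side [400, 1200] range |

The supervised baseline in the label-fraction study is trained with the
same schedule and the same labeled batch size as the semi-supervised
student's labeled half-batch (2), so the two arms see an identical
labeled stream and differ only in the use of unlabeled data — the
standard ablation for isolating the semi-supervised contribution.

## Evaluation

COCO-style: class-wise greedy matching in descending score order (each
ground-truth box matched at most once, IoU ties to the lower index),
pooled over images; 101-point interpolated AP per class per IoU
threshold; mAP = unweighted class mean; mAP@[0.5:0.95] = mean over
thresholds 0.50–0.95 in steps of 0.05. Classes with no ground truth in
the test set are excluded from the means and logged. The 101-point
routine is verified to 1e−9 against a brute-force prefix-enumeration
oracle on randomized instances. Relative performance is
100 · mAP_semi / mAP_sup-100%, rounded to two decimals.

## Numerical choices

- Softplus maps regression logits to distances (strictly positive,
  smooth); uncertainty log-scales are clamped to ±6 before
  exponentiation, with gradients zeroed outside the clamp.
- Focal probabilities are clipped at 1e−12 inside logs.
- GIoU gradients use subgradient 0 at min/max ties and empty
  intersections.
- Classification head bias initialized to the focal prior logit
  (π = 0.01); regression bias to 1 (≈10 px initial distances).
- Determinism: every random choice flows through `numpy.random.Generator`
  seeded from the config; identical config + seed reproduces datasets,
  training trajectories and result tables exactly.
- Degenerate inputs: empty box lists give all-background targets; images
  whose sides are not stride multiples raise a shape error; NaN in any
  loss aborts the step with a diagnostic.

## Study sizes

The default desk study uses 300 generated 3-class images
(195 train / 60 val / 15%→45 test), label fractions {5, 10, 20, 50, 100},
three seeds, and the schedule above; a single supervised or
semi-supervised run takes roughly half a minute to two minutes on one
CPU. Validation mAP@[0.5:0.95] is evaluated every 100 iterations and the
best checkpoint is retained (the final model would otherwise be a noisy
draw from the tail of the trajectory).

## Known limitations

- The feature stem is color/contrast based; motifs are separable mostly
  by hue and local texture, so the detector would not transfer to
  grayscale scenes.
- One feature level only: objects far larger than the stem's receptive
  field (±48 px) get poor regression targets at their centers.
- δ is a per-detection scalar; per-side gating is not implemented.
- At desk scale the pseudo-label supply above τ = 0.7 is thin
  (roughly 0.5–1.5 boxes per unlabeled image against ≈1.9 true boxes),
  so the measured semi-supervised gain is modest and seed-variable; the
  EMA ensemble provides the steadiest part of it.
- The anchor-based variant exists for the anchor-free/anchor-based
  comparison and trains, but the semi-supervised regression gate is only
  wired for the anchor-free head (the anchor-based unsupervised path
  uses the classification term alone).
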