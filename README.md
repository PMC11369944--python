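# weedssl

Semi-supervised **teacher–student object detection** for multi-class weed
scenes, at desk scale: a synthetic annotated-scene generator, a miniature
dense detector in anchor-free (FCOS-style) and anchor-based variants, the
full mean-teacher self-training engine (burn-in, pseudo-labeling, EMA,
weak/strong augmentation, uncertainty-gated unsupervised regression), and
COCO-style mAP@[0.5:0.95] evaluation — all in numpy, reproducible on one
CPU in minutes.

## Who this is for

Researchers and students who want to study *label-efficient* detection —
"how much of the fully-supervised performance can I keep with 5–50% of
the labels?" — without GPUs or external datasets. Precision weed
management is the motivating application: annotating field imagery of
weeds is expensive, while unlabeled imagery is abundant, so
semi-supervised detection directly reduces labeling cost.

## The method

A detector is first trained on the labeled subset (*burn-in*), then
duplicated into a teacher/student pair. Each subsequent step:

1. the **teacher** pseudo-labels weakly augmented unlabeled images; boxes
   are ranked **by classification score only** (the centerness branch has
   no background supervision, so its score is unreliable for ranking) and
   kept when score ≥ τ (default 0.7);
2. the **student** minimizes the supervised loss on a labeled half-batch
   plus λ_u × (unsupervised classification + unsupervised regression) on
   strongly augmented views of the unlabeled half-batch. The unsupervised
   regression term is gated per instance: it contributes
   ‖d̃_t − d̃_s‖₁ only when the teacher's localization uncertainty
   undercuts the student's by a margin σ, i.e. δ_t + σ ≤ δ_s;
3. the teacher tracks the student by an exponential moving average
   θ_teacher ← α·θ_teacher + (1−α)·θ_student, with α = 0.99.

Only the teacher is kept for inference. Evaluation is COCO-style:
per-class 101-point interpolated AP, averaged over classes (mAP) and over
IoU thresholds 0.50–0.95 (mAP@[0.5:0.95]). See `docs/methods.md` for the
full model description, parameter table and limitations.

## Worked example

```python
from weedssl import (SceneConfig, generate_dataset, split_dataset,
                     subsample_labeled, DetectorConfig, infer,
                     evaluate_detections, relative_performance)
from weedssl.teacher_student import (TrainSchedule, train_supervised,
                                     train_semi_supervised)

scene = SceneConfig(num_classes=3, seed=7)          # 3-class weed scenes
data = generate_dataset(scene, 300)                 # 300 images, 128x128
by_id = {im.image_id: im for im in data}
split = split_dataset([im.image_id for im in data], seed=0)
print(len(split.train_ids), len(split.val_ids), len(split.test_ids))
# -> 195 60 45    (the 65/20/15 ceil-on-val/test convention)

part = subsample_labeled(split.train_ids, 10, seed=0)   # 10% labels
labeled = [by_id[i] for i in part.labeled_ids]          # 20 images
unlabeled = [by_id[i] for i in part.unlabeled_ids]      # 175 images
val = [by_id[i] for i in split.val_ids]
test = [by_id[i] for i in split.test_ids]

config, sched = DetectorConfig(num_classes=3), TrainSchedule()
sup = train_supervised(labeled, sched, config, seed=0,
                       batch_size=sched.n_labeled, val_images=val)
semi, _ = train_semi_supervised(labeled, unlabeled, sched, config,
                                seed=0, val_images=val)

def test_map(model):
    dets = {im.image_id: infer(model, im.pixels) for im in test}
    gts = {im.image_id: im.annotations for im in test}
    return evaluate_detections(dets, gts, 3).map_50_95

print(f"supervised-10%      mAP@[0.5:0.95] = {100*test_map(sup):.2f}")
print(f"semi-supervised-10% mAP@[0.5:0.95] = {100*test_map(semi):.2f}")
# -> supervised-10%      mAP@[0.5:0.95] = 31.18
# -> semi-supervised-10% mAP@[0.5:0.95] = 31.45
```

With only 10% of the training annotations, the semi-supervised teacher
matches or exceeds the supervised baseline trained on the same labeled
subset — the qualitative behavior that motivates semi-supervised
detection. `relative_performance(semi_map, sup100_map)` expresses any
cell as a percentage of the fully-supervised run (e.g.
`relative_performance(49.20, 56.75)` → `86.70`).

The same study runs from the shell:

```bash
weedssl study --config configs/desk.yaml --out runs/desk
weedssl generate --config configs/desk.yaml --out data/scenes
weedssl evaluate --data data/scenes/dataset.json \
                 --checkpoint runs/desk/checkpoints/anchor_free_semi_10pct_seed0.npz \
                 --out report.json
```

(Any YAML mirroring `ExperimentConfig` works; see
`weedssl.experiments.load_experiment_config`.)

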