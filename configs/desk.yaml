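# Default desk-scale label-fraction study: 3-class synthetic weed scenes,
# 300 images split 65/20/15, supervised vs semi-supervised at each label
# fraction, 3 training seeds.
scene:
  num_classes: 3
  image_size: [128, 128]
  seed: 7
n_images: 300
variants: [anchor_free]
fractions: [5, 10, 20, 50, 100]
seeds: [0, 1, 2]
split_seed: 0
schedule:
  burn_in_iters: 400
  total_iters: 2000
  n_labeled: 2
  n_unlabeled: 2
  lr: 0.02
  momentum: 0.9
  lambda_u: 1.0
  tau: 0.7
  sigma: 0.1
  alpha: 0.99
  eval_interval: 100
  weak_scale_range: [96, 160]
detector:
  variant: anchor_free
  num_classes: 3
  stride: 8
  backbone_depth: 2
  backbone_width: 128
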