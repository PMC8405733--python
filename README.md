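# pointseg

Point-supervised fish segmentation with pairwise-affinity random-walk
refinement, for people who need segmentation, counts and locations of fish
in monitoring imagery but can only afford one click per fish instead of
full masks (a click takes ~1 s to annotate; a mask ~2 min per fish).

## The method

A fully convolutional backbone feeds two heads.  The **activation branch**
(one 1×1 convolution, 2 channels) scores every cell of the deepest feature
grid as background/fish, `f_act`.  The **affinity branch** maps three
backbone depths through 1×1 convolutions (64/128/256 channels), resamples
them to the deepest grid and merges them into d = 448 affinity features
`f_aff`.  Local pairwise affinities

    W_ij = exp(−‖f_aff(i) − f_aff(j)‖₁),   ‖(i,j)‖ ≤ γ on the grid,

become a random-walk transition operator via a Hadamard power and row
normalisation,

    T = D⁻¹ W^β,   D_ii = Σ_j W_ij^β,

and the refined scores are `f_ref = Tᵗ f_act` per class channel, upsampled
bilinearly and softmaxed into per-pixel probabilities S.  Training needs
only the clicks, through the four-term blob-counting loss

    L = L_I + L_P + L_S + L_F

(image-level, point-level, watershed split-level, false-positive), which
drives the model towards exactly one 8-connected blob per annotated fish —
so blob counting doubles as fish counting.  The whole pipeline, walk
included, is differentiable and trains end-to-end.  Optionally, the trained
model's argmax masks on its own training images become pseudo ground truth
for a fully supervised student (`a_lcfcn_pm` mode), which typically
sharpens boundaries.

Evaluation uses pooled per-class IoU/mIoU, counting MAE, and GAME(L)
(counting error within 4^L grid cells; GAME(0) = MAE).

There is no deep-learning framework dependency: the network and the sparse
differentiable walk run on a compact reverse-mode autodiff engine over
numpy/scipy included in the package (see `docs/methods.md`).

## Worked example

Generate a synthetic dataset (high-contrast preset), train the affinity
model at the desk-scale configuration, and evaluate it:

```bash
cat > demo.yaml <<'YAML'
model:
  backbone_name: fine
  affinity_channels: [16, 32, 64]
  merged_channels: 112
  affinity_init_gain: 0.003
affinity:
  radius: 2
  iterations: 4
YAML
pointseg synth --root data/demo --preset easy --n-train 60 --n-val 15 \
    --n-test 15 --seed 7
pointseg train --root data/demo --config demo.yaml --method a_lcfcn \
    --max-epochs 36 --patience 36 --lr 1e-3 --seed 0 \
    --checkpoint runs/demo.npz
pointseg evaluate --root data/demo --config demo.yaml \
    --checkpoint runs/demo.npz --split test
```

which prints (numbers from this exact command sequence; the training step
takes about 40 s on one CPU):

```
wrote 90 scenes under data/demo
best lr 0.001, epoch 35, val score 0.9120 -> runs/demo.npz
{
  "tp": [133208, 4164],
  "fp": [618, 250],
  "fn": [250, 618],
  "iou_background": 0.9935260598466541,
  "iou_foreground": 0.8275039745627981,
  "miou": 0.910515017204726,
  "mae": 0.0,
  "game": {"0": 0.0, "1": 0.0, "2": 0.26666666666666666, "4": 0.8}
}
```

Read it as: background/foreground IoU of 0.99/0.83 (mIoU 0.91) from point
labels alone on a tiny 60-image budget, the predicted blob count is exact
on every test image (MAE 0), and the small GAME values say those counts
also land in the right part of the image (GAME(4) scores counts within
each of 256 grid cells).

The library surface mirrors the CLI: `pointseg.synthetic.generate_split`,
`pointseg.train.train / run_method`, `pointseg.train.evaluate`,
`pointseg.distill.generate_pseudo_masks`, `pointseg.metrics.evaluate_set`.

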