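# mammofusion

Patch-based mammographic ROI classification with multi-scale deep feature
fusion and majority voting.

The pipeline: MIAS-style mammograms (8-bit PGM + plain-text annotation
file) are median-filtered and CLAHE-enhanced; 120×120 ROIs are extracted
around annotated abnormality centers (random breast-interior centers for
normals), dark non-breast bands are cropped and the result is rescaled;
random 72×72 patches of each ROI (centralized per patch) train a fusion
head over a frozen convolutional backbone; each ROI is finally classified
by majority voting over 25 freshly sampled patch predictions.

Two fusion heads are provided:

* **fusion1** — global average pooling of each selected backbone block,
  concatenated into one vector.
* **fusion2** — per block: BN → 2×2 average pool → 1×1 convolution
  (channel bottleneck, ReLU) → global average pooling, then concatenated.

Both feed BN → FC1 → FC2 → softmax. Backbone convolutions are always
frozen; only the head (and, for fusion2, the per-branch BN/1×1-conv
layers) trains.

No deep-learning framework is required: the backbone forward pass and the
head's backpropagation are implemented in NumPy (`mammofusion._nn`). The
`tiny_test` backbone (5 random frozen conv blocks, widths 8/16/32/32/32)
runs the entire pipeline in minutes on one CPU; `vgg16`/`vgg19`
architectures are available, with pretrained weights loadable through
`build_model(..., backbone_weights=...)` when a weight mapping is
supplied (none are bundled).

A synthetic phantom generator (`mammofusion.phantom`) emits MIAS-format
datasets — breast-shaped textured images with annotated bright lesions
and impulse noise — so everything trains and evaluates with no download.

## CLI

```bash
# synthesize a dataset
mammofusion phantom --n-normal 40 --n-abnormal 40 --side 256 --seed 7 --out data/

# preprocess + extract ROIs (writes PNGs + rois.csv manifest with splits)
mammofusion extract-rois --data data/ --out rois/ --seed 7

# train a fusion head over the frozen backbone
mammofusion train --rois rois/ --out ckpt --backbone tiny_test \
    --mode fusion2 --patches-normal 50 --patches-tumor 200 --epochs 12 --seed 7

# majority-vote evaluation on the test split (report + ROC/PR points)
mammofusion evaluate --rois rois/ --checkpoint ckpt --out eval/ --seed 7

# classify a single ROI image
mammofusion predict --checkpoint ckpt --image rois/roi00000.png
```

## Layout

| module | contents |
|---|---|
| `mias_io` | PGM (P2/P5) reader/writer, annotation-file parser/writer |
| `preprocess` | median filter, CLAHE, breast mask, ROI extraction chain |
| `patch_sampling` | stratified 60/20/20 ROI split, patch sampling, centralization, augmentation |
| `fusion_models` | FusionSpec, backbone + head assembly, dimension accounting, checkpoints |
| `train_vote_eval` | head training, majority voting, metrics, ROC/PR curves |
| `phantom` | synthetic MIAS-format dataset generator |
| `cli` | `mammofusion` console entry point |
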