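# pancseg

Coarse-to-fine segmentation of small, low-contrast organs in 3D volumes
with a 2.5D attention U-net — built for the pancreas-in-abdominal-CT
setting, where the target occupies under 2% of the volume, varies wildly
in shape, and blends into its surroundings.

The package is aimed at researchers who want a fully inspectable,
CPU-only reference implementation of the method: every stage — phantom
data generation, preprocessing, 2.5D slicing, the network, training, the
multi-view cascade and evaluation — is plain Python on numpy, testable
end-to-end without downloading any dataset.

## Method

- **2.5D inputs.** A volume is cut into slices along the sagittal,
  coronal and axial planes; the input for slice *i* is the 3-channel
  image `(S_{i−1}, S_i, S_{i+1})` (boundary slices replicated), giving a
  2D network through-plane context at a fraction of 3D cost.
- **Network.** A U-shaped encoder-decoder of dense blocks (6 convolution
  layers with dense skip connectivity + 1×1 transition). The first
  encoder blocks convolve the 3-slice stack volumetrically (3×3×3) before
  depth is folded into channels. Skip connections carry a hybrid
  attention gate combining a spatial branch `X·σ(conv(f(X,Y)))` with a
  channel branch driven by global average + max pooling, where Y is the
  next-deeper encoder feature.
- **Loss / metric.** Soft Dice loss `1 − 2Σyŷ/(Σy+Σŷ)` (ε-smoothed) for
  training; volume-level `DSC = 2|A∩B|/(|A|+|B|)` for evaluation.
- **Cascade.** Three per-view coarse models are fused per voxel by
  majority vote (≥ 2 of 3 views); a margin-framed bounding box around the
  fused mask crops the volume; three fine models re-segment the crop and
  the result is stitched back.
- **Numerics.** The network runs on the package's own reverse-mode
  autodiff engine (`pancseg.autograd`) — conv2d/conv3d, pooling, bilinear
  upsampling, instance norm, Adam — with every gradient verified against
  finite differences in the test suite.

See `docs/methods.md` for the full model description, parameter defaults
and design decisions.

## Worked example

Train the full cascade on synthetic phantoms (64×64×48 volumes with a
deformed-ellipsoid "organ" under 2% volume fraction, organ-like
distractors and noise) and score it on held-out phantoms:

```python
from pancseg.experiment import run_miniature_experiment

res = run_miniature_experiment(seed=0)   # ~5 min on one CPU core
print(f"coarse fused mean DSC: {res['coarse'].mean:.3f}")
print(f"fine   fused mean DSC: {res['fine'].mean:.3f}")
print(f"threshold baseline:    {res['threshold_baseline'].mean:.3f}")
```

```
coarse fused mean DSC: 0.913
fine   fused mean DSC: 0.929
threshold baseline:    0.366
```

Reading: the three-view coarse stage already localises and segments the
organ well (DSC 0.913 over 4 held-out phantoms); cropping to the organ
region and re-segmenting lifts it to 0.929 — the coarse-to-fine
improvement the cascade exists for.  The best *global intensity
threshold* manages only 0.366 on the same volumes, confirming the
phantoms cannot be solved without spatial context.

The same workflow is available from the shell:

```bash
pancseg generate --n 16 --seed 0 --out phantoms/
pancseg train --data-dir phantoms/ --axis axial   --stage coarse --out models/coarse/axial
# ... one model per {sagittal,coronal,axial} × {coarse,fine}
pancseg pipeline --input phantoms/case_012_image.nii.gz \
    --coarse-dir models/coarse --fine-dir models/fine --output pred.nii.gz
pancseg evaluate --pred pred.nii.gz --truth phantoms/case_012_mask.nii.gz
```

Real data in NIfTI (`.nii`/`.nii.gz`) is read the same way; apply
`pancseg.window_and_rescale` (clip to [−100, 240] HU, rescale to
[0, 255]) before training on CT.

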