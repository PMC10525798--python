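# adverseg

Adversarial multi-organ segmentation of chest-radiograph-like images at desk
scale: an SE-gated residual U-Net generator trained against a convolutional
Wasserstein critic with gradient penalty (WGAN-GP), plus a synthetic phantom
generator with exact ground truth so the entire pipeline runs and is tested
offline on one CPU.

## What is in the box

| module | purpose |
| --- | --- |
| `adverseg.phantom` | synthetic torso phantoms (two lung ellipses + occluding heart) with pixel-exact masks |
| `adverseg.dataio` | PNG image/mask I/O, color-coded label schemes (blue/green/red = left lung/right lung/heart), manifests, seeded train/test splits |
| `adverseg.preprocess` | CLAHE enhancement, bilinear/nearest resizing, paired affine augmentation, Gaussian noise injection |
| `adverseg.generator` | the U-shaped generator: per level 2×(3×3 conv) → squeeze-and-excitation gate → residual 1×1 shortcut, 2×2 max-pool down / 2× nearest-neighbor up, skip concatenations, softmax head |
| `adverseg.critic` | the WGAN critic: stages of 2×(conv + norm + leaky ReLU) → max-pool, then one unbounded fully connected score (no sigmoid, no log) |
| `adverseg.training` | WGAN-GP losses, gradient penalty, supervised Dice+CE segmentation loss, optional standard-GAN variant, the alternating training loop, prediction, checkpoints, exact 1-D Wasserstein oracle |
| `adverseg.metrics` | Dice / IoU / recall / precision / F1 from one-vs-rest pixel confusion counts, micro- or macro-averaged |
| `adverseg.cli` | `adverseg synth | train | predict | evaluate` |

The networks run on numpy via [autograd](https://github.com/HIPS/autograd);
the gradient penalty needs a gradient of a gradient norm, and the heavy
convolution/pooling operations are custom autograd primitives whose vector-
Jacobian products are expressed through the same primitives, so arbitrary-order
derivatives stay matmul-bound.

## CLI quick start

```bash
# 1. synthesize a phantom dataset with exact color-coded ground truth
adverseg synth --n 200 --out data/phantoms --seed 0 --resolution 64 --jitter 0.2

# 2. train (70/30 split, WGAN-GP defaults; see --set for dotted overrides)
adverseg train --manifest data/phantoms/manifest.csv --out runs/demo \
    --epochs 5 --resolution 64 --base-filters 16 --seed 0

# 3. predict color-coded masks with the trained generator
adverseg predict --checkpoint runs/demo/generator \
    --manifest runs/demo/val_manifest.csv --out runs/demo/preds

# 4. score predictions (columns: label,dice,iou,recall,precision,f1)
adverseg evaluate --preds runs/demo/preds --truths data/phantoms/masks \
    --out runs/demo/report.csv
```

Every run writes `resolved_config.yaml`, `history.csv`
(`step,critic_loss,gen_loss,gp,w_estimate,seg_loss` — `w_estimate` is the
empirical Wasserstein training-progress indicator), and `.npz` + `.json`
checkpoints. All randomness derives from the single `--seed`.

## Notes

* Default configuration is desk-scale (64×64, 16 base filters). The paper-
  scale convention (512×512 inputs, wider nets) is reachable through
  `GeneratorConfig` / `CriticConfig` / `--resolution`, but is not CPU-friendly.
* Weight clipping is intentionally unsupported; the Lipschitz constraint is
  enforced solely by the gradient penalty (`lambda_gp`).
* Masks decode strictly: every pixel must match a scheme color exactly.
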