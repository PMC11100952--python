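# fetseg

Tooling for **multi-class fetal-head ultrasound segmentation** under severe
class imbalance. Second- and third-trimester head planes contain four
classes of wildly different size — background, fetal brain, the cavum
septum pellucidum (CSP) and the lateral ventricles (LV); the two internal
structures occupy only a handful of pixels, yet their delineation is what
drives gestational-age and growth biometry. This package implements the
computational machinery such a pipeline needs, independent of any
particular network backbone:

* **Synthetic phantoms** (`fetseg.phantom`) — seeded generator of
  fetal-head-like image/label pairs (bright speckled ellipse + two small
  internal rectangles) so everything is testable without clinical data,
  plus the 60/20/20 floor-remainder dataset splitter.
* **9-fold augmentation** (`fetseg.augment`) — nine named strategies
  (resize, random crop, flips, rotation, a combined chain, random resized
  crop, pad+crop, and a brightness/elastic/noise/blur set), applied jointly
  to image and label map; 2,299 training pairs become exactly 20,691.
* **Inverse-frequency class weights** (`fetseg.class_weights`) — pixel
  tallies → inverse frequency → min-max smoothing into `[0.1, 0.9]`,
  yielding the characteristic small/small/large/medium weight shape.
* **Weighted losses** (`fetseg.losses`) —

  `L = α·L_Dice + β·L_Lovász`, with α = β = 0.5 by default, where

  `L_Dice = 1 − 2·Σᵢ yᵢ pᵢ wᵢ / Σᵢ (yᵢ + pᵢ) wᵢ`

  over all (class, pixel) entries, and `L_Lovász` is the Lovász extension
  of the Jaccard loss (direct IoU optimisation), combined across classes
  as a weight-weighted mean. Analytic gradients are included.
* **Prompt bounding boxes** (`fetseg.prompt_boxes`) — per-class
  `[x_min, y_min, x_max, y_max]` prompts from a one-hot mask with
  threshold, symmetric offset expansion and `[0,0,0,0]` sentinels, for
  promptable segmenters.
* **Evaluation** (`fetseg.metrics`) — per-class and mean DSC, Hausdorff
  distance and average surface distance on border point sets, plus the
  standard report-table layout.
* **Training harness** (`fetseg.harness`) — AdamW (lr = wd = 1e-4),
  multi-step schedule (epochs 10/20/30, γ = 0.7), early stopping
  (patience 5) around a pluggable segmenter interface, with a CPU-sized
  surrogate model and prompt-offset / loss-variant ablations.

## Worked example

```python
import numpy as np
import fetseg as F

phantoms = F.generate_dataset(50, F.PhantomParams(height=64, width=64, seed=3))
train, val = phantoms[:30], phantoms[30:40]

weights = F.compute_weights(F.count_classes([s.label_map for s in train], 4))
print("class weights:", np.round(weights.as_array(), 3))

cfg = F.TrainConfig(loss=F.LossConfig(weights), seed=3, max_epochs=30, batch_size=4)
model = F.LinearSoftmaxSegmenter(4, seed=3)
result = F.train(model, train, val, cfg)
print(f"epoch 0 val loss {result.log[0]['val_loss']:.4f} -> "
      f"best {result.best_val_loss:.4f} (epoch {result.best_epoch})")

report = F.evaluate_segmenter(model, val)
for name, (d, h, a) in report.per_class.items():
    print(f"{name:>10}  DSC {d:.5f}  HD {h:.5f}  ASD {a:.5f}")
print(f"{'mean':>10}  DSC {report.mean[0]:.5f}  HD {report.mean[1]:.5f}  ASD {report.mean[2]:.5f}")
```

prints

```
class weights: [0.1   0.102 0.9   0.621]
epoch 0 val loss 0.8077 -> best 0.2738 (epoch 29)
background  DSC 0.97079  HD 13.73466  ASD 1.76168
     brain  DSC 0.86232  HD 8.14909  ASD 2.72479
       CSP  DSC 1.00000  HD 0.00000  ASD 0.00000
        LV  DSC 1.00000  HD 0.00000  ASD 0.00000
      mean  DSC 0.95828  HD 5.47094  ASD 1.12162
```

The weight vector puts ≈0.9 on the rarest class (CSP) and ≈0.1 on the
dominant ones; thirty epochs of the combined weighted loss cut the
validation loss from 0.81 to 0.27, and the trained surrogate segments the
two tiny prompted structures perfectly while the brain/background boundary
(fuzzy under speckle) accounts for the residual surface distances.

The same pipeline is scriptable from a shell:

```
fetseg phantom --n 50 --out data --seed 7
fetseg augment --in data --out data_aug --seed 7
fetseg weights --masks data
fetseg boxes --masks data --offset 0 --out boxes.json
fetseg pipeline --n 50 --out run --seed 7
fetseg ablate --mode prompts --data data --out ablation.csv
```

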