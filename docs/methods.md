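# Methods

This note records the models, conventions and numerical choices the
package implements, and what its synthetic experiments do and do not show.

## Label model and conventions

Segmentation state is a 4-class per-pixel labelling (background, fetal
brain, CSP, LV; index 0 is always background) carried in three equivalent
forms: an `H×W` integer label map, its `C×H×W` one-hot expansion, and a
`C×H×W` probability map. All arrays are channel-first and row-major;
coordinates are 0-based with `y` down the rows and `x` across the columns,
and bounding boxes use *inclusive* pixel indices. Probability maps are
collapsed by argmax with ties broken toward the lowest class index — a
deterministic rule under which background wins exact ties, which is the
conservative choice for tiny foreground structures. On disk a dataset is
`images/*.png` (8-bit grayscale) plus `masks/*.png` (8-bit indexed, pixel
value = class index), paired by stem.

## Synthetic phantom

The phantom emulates the *class geometry* of trans-thalamic /
trans-ventricular head planes, not their physics: an axis-aligned bright
ellipse (brain) over a dark background, a small midline rectangle (CSP),
a slightly larger lateral rectangle (LV), and multiplicative Gaussian
speckle `I ← I·(1 + σ·N(0,1))` with variance 0.05 by default — the classic
first-order speckle approximation. Default geometry at 256×256 (scaled
linearly for other sizes): brain semi-axes 56–88 px (x) and 44–68 px (y)
with ±4 % centre jitter; CSP side 5–9 px placed within 0.12 semi-axes of
the midline; LV side 7–12 px at 0.3–0.55 semi-axes laterally. Rectangles
must fit inside a 0.7-shrunken ellipse and not overlap (bounded retries,
then a generation error). These sizes guarantee the count ordering
background > brain > each small structure and produce inverse-frequency
weights of the characteristic small/small/large/medium shape with CSP at
the range maximum. By default 20 % of a generated dataset omits CSP and LV,
mirroring first-trimester planes where the structures are not yet visible.
Everything is bit-deterministic in `(seed, index)`.

Not emulated: beam physics (shadowing, attenuation, anisotropic point
spread), skull echoes, probe orientation variability, and annotation
noise. Tests passing on phantoms therefore validate the *machinery*
(losses, weights, boxes, metrics, training loop), not clinical accuracy.

## Dataset split

`split_dataset` uses floor-then-remainder rounding with the remainder
assigned to the test split: train = ⌊0.6 n⌋, val = ⌊0.2 n⌋, test = the
rest. This is the unique simple rule reproducing the published
(2299, 766, 767) triple at n = 3832; the val/test asymmetry at odd
remainders is a consequence, not a choice. Assignment of concrete stems is
by a seeded shuffle.

## Augmentation

Nine strategies, each emitting exactly one output per input (forced by the
9× dataset arithmetic); probabilistic sub-transforms may no-op but the
strategy still emits its resized output. Constants: crop 128×128 (then
resize back), flip probability 0.3, rotation limit ±30°, random-resized
crop scale 1.2–1.4, advanced-set probability 0.5, elastic α = 1 / σ = 50,
Gaussian-noise variance 10–50 on the 8-bit scale, blur kernel 3–7.
Decisions where a convention had to be fixed:

* labels are resampled nearest-neighbour, images bilinearly; geometric
  border fill is background (0) — preserves label validity;
* the combined chain applies crop, vertical flip, horizontal flip,
  rotation in that order with the same constants;
* the random-resized crop upscales from the working size then crops back
  to it (scale-then-crop reading);
* pad+crop pads 32 px per side (reflection) at 256 — an eighth of the
  side, scaled with the target size; the pad magnitude is a package
  convention;
* blur σ is derived from the kernel size by the usual
  `0.3·((k−1)/2 − 1) + 0.8` rule.

Strategy constants that are lengths (crop, pad) scale proportionally when
a non-default working size is requested; the 9× count is size-invariant.
Validation data is never routed through this module, and the pipeline
command refuses a configuration that tries.

## Class weights

Pixel tallies per class over the training masks (zero tallies replaced by
one so the inverse exists), inverse frequency normalised to sum to one,
then min-max rescaled into `[min_weight, max_weight]` = `[0.1, 0.9]` by
default. The "smoothing" step is the identity on the normalised weights —
the simplest reading under which the rescale is well-defined; this is the
central interpretation risk of the procedure and is deliberately isolated
in one function. Equal counts make the rescale degenerate; every class
then receives the range midpoint. The map is anti-monotone in counts and
invariant to scaling all counts.

## Losses

* **Weighted Dice** (default, "entry" mode): one scalar over all
  (class, pixel) entries of the one-hot truth and predicted
  probabilities, each entry weighted by its class weight. `ε = 1e-6`
  stabilises the ratio (the value is exactly 0 only in the ε → 0 limit at
  perfect predictions; tests use a 1e-5 tolerance). A per-class-Dice
  weighted-average variant is available (`dice_mode="per_class"`) because
  the entry-weighted and per-class readings cannot be distinguished from
  the formula alone.
* **Weighted Lovász**: per class, the Lovász extension of the Jaccard
  loss on the error vector `|y_c − p_c|` via the sorted-gradient
  construction (descending stable sort; increments of the prefix Jaccard
  loss), combined across classes as `Σ w_c ℓ_c / Σ w_c`. At hard {0,1}
  predictions each class term equals `1 − IoU` exactly. Classes absent
  from the truth contribute their maximum predicted error under the
  default `penalty` policy — the convention that remains vertex-consistent
  (an absent-but-predicted class has IoU 0, loss 1); `skip` excludes them
  from numerator and denominator instead.
* **Combined**: `α·Dice + β·Lovász`, α = β = 0.5 by default.

Analytic gradients: the Dice part by the quotient rule; the Lovász part
holds the sorting permutation fixed (the standard piecewise-linear
subgradient) with `d|y−p|/dp = sign(p−y)`; softmax backpropagation is
`dL/dz_c = p_c (g_c − Σ_k g_k p_k)`.

## Prompt boxes

Per class: threshold the channel (default 0.5 — any value in (0,1) is
equivalent for binary one-hot channels), take the min/max activated row
and column indices, expand symmetrically outward by `offset` pixels and
clamp to the image. "Apply offset" is read as outward expansion because
the prompt-size ablation treats growing offsets as loosening prompts, and
degradation with offset is only coherent under that reading. Classes with
no activated pixel get the `[0,0,0,0]` sentinel, and the result always
covers every class index.

## Metrics

DSC on class pixel sets; Hausdorff and average surface distance on border
point sets (a class pixel is border iff a 4-neighbour is outside the class
or it lies on the image edge), Euclidean pixel units, nearest neighbours
via a k-d tree. ASD is *directed* (prediction → truth), following the
printed formula; a symmetric variant is a flag. Empty-set conventions
(needed for absent CSP/LV): both empty → DSC 1, HD 0, ASD 0; exactly one
empty → DSC 0 and HD = ASD = the image diagonal, a finite monotone-safe
penalty. Report means are unweighted arithmetic means over all classes
*including background* — the convention forced by the published tables,
whose printed per-class rows reproduce their printed means only under it.
Report tables round half-even to 5 decimals.

## Training harness

The optimisation recipe: AdamW (β₁ = 0.9, β₂ = 0.999, decoupled weight
decay), learning rate and weight decay 1e-4, multi-step schedule dropping
by γ = 0.7 at epochs 10/20/30, early stopping on validation combined loss
with patience 5. "Improvement" is a strict decrease by more than
`min_delta` (default 0); the best-epoch state is restored. Batch size
defaults to 8 (4 in the smoke runs); both are configuration, not doctrine.

The trainable surrogate is a per-pixel softmax *linear* model over a small
feature stack: bias, intensity, intensity², one rendered indicator channel
per class prompt box, and normalised coordinates. Features carry a fixed
gain of 100 so that 1e-4-sized AdamW steps move logits appreciably within
a few hundred updates — a property of the surrogate's parameterisation,
chosen so the full recipe is exercisable at CPU scale. Prompt boxes are
fed to the surrogate as binary channels; a foundation-model mask decoder
with a learned prompt encoder would slot in behind the same
`predict(image, boxes)` interface. Because offset-0 boxes of the
axis-aligned phantom rectangles coincide exactly with the structures, the
surrogate's CSP/LV channels are near-oracle features — which is precisely
why prompts help, and why the smoke runs segment those classes perfectly.

Ablations: `ablate_prompts` re-derives boxes at each offset (0/10/20 by
convention) for a fixed segmenter; the bundled box-fill oracle (paints
each foreground class across its whole box, smaller boxes on top) makes
prompt looseness the *only* error source, exhibiting the expected monotone
DSC degradation. `ablate_losses` retrains one surrogate per mix
(Dice-only, Lovász-only, combined) under a shared seed.

## Problem sizes

Tests and the acceptance script run phantoms at 64×64 (48×48 for purely
geometric checks) and smoke-train on 50 samples for ≤30 epochs; the
9-fold augmentation count is recomputed on a full 2,299-phantom split at
64×64 via the streaming iterator. These sizes were chosen as the smallest
at which every contract (count ordering, weight shape, box nesting,
training improvement) is comfortably exercised; all counts and identities
checked are size-invariant.

## Known limitations

Phantom realism is deliberately minimal (see above). The surrogate is
linear and box-driven, so its absolute scores say nothing about any real
segmenter; only the machinery around it is validated. The directed-ASD
and entry-weighted-Dice readings, the identity smoothing of the weight
procedure, and the outward offset expansion are documented conventions
where the underlying procedure admits more than one reading; each has a
configurable alternative or an isolated implementation point.
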