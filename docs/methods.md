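# Methods

This note records the scientific and numerical choices behind `histofuse`:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Problem setting

Two-class classification of H&E-stained histopathology images
(1 = normal tissue, 2 = malignant). The package couples a learned
multi-scale representation (a dual-branch cross-attention vision
transformer) with three classical descriptors that target the two axes a
pathologist reads first: stain colour distribution and tissue texture. A
feed-forward network classifies the fused representation.

## Synthetic image generator

Real OSCC slide collections cannot be bundled, so the generator emulates the
*statistical structure* the pipeline consumes: an eosin-pink background
(HSV hue ≈ 330°, saturation 0.30, value 0.92) carrying a smooth
multiplicative texture field (Gaussian-filtered white noise, correlation
length `texture_grain` px, amplitude 6 % of value), scattered
haematoxylin-purple nucleus-like blobs (anti-aliased filled ellipses, hue
272°, per-axis radii drawn from N(mean, sd) and clipped at 1.2 px), and
per-channel Gaussian sensor noise (sd 3 of 255). Hue blending at blob edges
is circular (shortest arc). Blob count is the rounded expectation
`density · H · W / 10⁴`, so renders are deterministic in count; positions,
radii and orientations are drawn from `numpy.random.Generator(PCG64)`.
Per-image seeds derive from `SeedSequence((master_seed, image_index))`.

Presets (chosen once as a plausible normal-vs-malignant contrast):

| parameter | easy: normal | easy: malignant | hard: malignant |
| --- | --- | --- | --- |
| background hue (°) | 330 | 290 | 320 |
| nucleus density (/10⁴ px²) | 10 | 22 | 14 |
| nucleus radius (px) | 4 ± 1 | 5.5 ± 1.5 | 4.5 ± 1.2 |
| texture grain (px) | 8 | 2.5 | 6 |

What the generator does **not** emulate: realistic nuclear morphology and
chromatin texture, stain deconvolution physics, tile-boundary artefacts,
scanner-to-scanner colour shifts, class-conditional context (gland
architecture). Passing the end-to-end tests therefore demonstrates that the
pipeline carries colour/texture class signal through every stage — not that
it reaches any particular accuracy on real slides.

## Handcrafted descriptors

* **Fuzzy colour histogram (768).** HSV grid of 12 hue × 8 saturation × 8
  value bins; triangular memberships peak at bin centres and overlap the two
  nearest bins per axis (hue wraps circularly; saturation/value clamp at the
  range ends so mass is conserved). Each pixel distributes exactly unit mass
  over ≤ 8 bins; the histogram is normalised by pixel count. Fuzzy binning
  bounds the histogram's sensitivity to a small colour shift δ by ~2Kδ per
  axis, whereas crisp binning can move the entire mass when pixels sit at a
  bin edge; this is the stain-shift robustness the descriptor exists for.
  Note the per-image inequality "fuzzy L1 ≤ crisp L1" is not a theorem — for
  generic images either side can win — so the tests pin the boundary case.
* **LBP (26).** Rotation-invariant uniform patterns, P = 24 neighbours at
  R = 3, bilinear neighbour interpolation, comparator neighbour ≥ centre;
  26 bins = bit-counts 0..24 of uniform patterns plus one non-uniform
  catch-all. Codes are collected from interior pixels only (3 px border
  cropped). Implementation detail that matters: sampling offsets are rounded
  to 8 decimals so the ring is exactly symmetric under quarter turns, and the
  comparator carries 1e-6 slack; without these, floating-point near-ties flip
  codes and break 90° rotation invariance at the 1e-6 level.
* **GLCM (24).** Luminance (0.299/0.587/0.114, round-half-to-even) quantised
  to 64 levels; symmetric normalised co-occurrence matrices at distance 1,
  angles 0/45/90/135° (offsets (round(sin a), round(cos a))); per angle, in
  order: contrast, dissimilarity, homogeneity, energy, correlation, entropy.
  Energy is the angular second moment Σp²; entropy uses natural log with
  0·log 0 = 0; correlation is defined as 0 when either marginal standard
  deviation vanishes (a constant image thus reports correlation 0, not 1).

The 818-vector layout is FCH[0:768] ‖ LBP[768:794] ‖ GLCM[794:818], fixed.

## Backbone

Two presets:

| | image | patches | dims | depth | heads | MLP ratio | cross rounds |
| --- | --- | --- | --- | --- | --- | --- | --- |
| `paper` | 240 | 12 / 16 | 384 / 768 | 2 | 6 | 4 | 1 |
| `tiny` | 64 | 8 / 16 | 32 / 64 | 2 | 2 | 2 | 1 |

The full-width preset fixes the branch widths at 384/768 so the fused
vectors measure 1,202/1,586; its image size is 240 because the input must be
divisible by both patch sizes (240 = 20·12 = 15·16, the standard pairing for
12/16 patches). Encoder depth, head count and the number of cross rounds are
not dictated by the architecture's width contract; the defaults above are
deliberate, CPU-sensible choices and are fully configurable.

Numerical contract: all computation is float64; layer-norm eps 1e-6;
attention logits are max-subtracted before exponentiation; positional
encodings and all weights initialise from N(0, 0.02²) with a seeded PCG64;
inference is dropout-free, so identical inputs give identical features.
Cross-attention applies no feed-forward block after its residual; the
back-projection g returns the attended CLS to its branch width, and both
directions of a round read the pre-round states (simultaneous exchange).
The forward pass is pinned, token for token, against a loop-written
reference implementation in the test suite (1e-5), and every autodiff
primitive against central finite differences (1e-7).

Pretrained weights load by tensor name from `.npz` archives; name matches
with shape conflicts raise (naming the tensor), unmatched names on either
side are reported. No pretraining is bundled: at synthetic desk scale the
backbone is used either randomly initialised (as a fixed feature extractor,
the default for the fused system) or briefly trained on the run's own
training split (the backbone-only system, and the gradient-flow test which
halves one-batch loss within 200 Adam steps).

## Fusion classifier

One hidden layer (default 128 units, He-scaled init), ReLU, 2-class softmax,
minibatch Adam (lr 1e-3, batch 32), max 100 epochs, early stopping with
patience 20 on validation cross-entropy; the returned model is the
best-validation-epoch snapshot, and the history records both loss curves.
Per-feature standardisation is fitted on the training split only and reused
verbatim for validation/test (no leakage; zero-variance features get unit
scale). Whether the ANN should see the two branch-fused vectors jointly or
separately is ambiguous on its face; the default is a single ANN on the
combined 2,788-dim vector (the simplest reading), with
`branch_mode: separate` training one ANN per branch and averaging their
softmax outputs. Exact probability ties predict class 1.

## Evaluation

Positive class is 2 (malignant), configurable. Zero-denominator conventions
(all flagged with warnings in the report): precision/sensitivity/specificity
0 when their denominator is 0, F1 0 when precision+sensitivity = 0, κ 0 when
p_e = 1. The ROC sweep groups tied scores; with trapezoidal integration this
equals the half-tie Mann-Whitney concordance exactly, which the tests assert
to 1e-9 against an all-pairs oracle.

## Partition and augmentation

Split sizes use floor-then-largest-remainder rounding (ties broken in
train/val/test order): 1,000 items at 70/15/15 give exactly 700/150/150; 10
items give 7/2/1. Stratified mode applies the rule per class, holding each
split's class share within one item. Augmentation draws, in documented
order: horizontal flip, vertical flip, rotation angle uniform in ±15°
(bilinear, reflect padding, cropped to input size — the resampling scheme is
a declared choice), then multiplicative brightness, contrast about the image
mean, and saturation about the luminance, each within ±10 % by default. A
zero-strength spec is the pixelwise identity (zero-angle rotation and
unit-factor colour ops are skipped rather than resampled).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
and script each finish in well under a minute of CPU: end-to-end runs use
100 images per class at 64×64 with the tiny backbone (held-out n = 30);
oracle comparisons use ≤ 16×16 images and ≤ 3-token sequences; the
dimensionality audit runs the full-width preset on a single 240×240 image.

## Known limitations

* The synthetic generator's simplifications mean reported synthetic metrics
  (typically 1.0 on the easy preset) say nothing about real-slide accuracy.
* The FCH/LBP/GLCM configurations are declared reconstructions constrained
  by their output widths (768/26/24); other parameterisations of the same
  families exist and are out of scope as defaults.
* Binary classification only; no calibration, confidence intervals or
  multi-class extension.
* The autodiff engine is deliberately minimal (no GPU, no dropout in the
  graph, float64 only); it is sized for desk-scale experiments, not for
  ImageNet-scale pretraining.
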