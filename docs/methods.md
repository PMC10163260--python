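# Methods

This note documents the models and procedures the package implements, the
assumptions behind the synthetic benchmark, and the numerical and design
choices a maintainer would want to know about.

## Problem setting

Fluorescence microscopy of stained proteins yields four-channel images
(nucleus, protein of interest, microtubules, endoplasmic reticulum)
containing many cells. The task is multi-label classification of the
protein's subcellular localisation *per cell*, under weak supervision: the
only labels available at training time are image-level label sets, defined
as the union of the (unobserved) per-cell labels. Propagating an image's
label set to each of its cells produces weak cell labels whose positives
are partly wrong — a cell need not express every pattern present somewhere
in its image.

## Synthetic data generator

The generator produces datasets with known per-cell ground truth so that
every downstream stage is testable without external downloads. It emulates
the *statistical* structure of the real problem, not its appearance:

* **Hierarchical labels.** Each image draws a small label set (one to
  three classes by default) from an imbalanced class-frequency vector;
  each cell expresses a nonempty subset of that set (each class kept with
  probability 0.6, counts clipped to a configurable range). Every image
  class is assigned to at least one cell, so the image label is the union
  of the cell labels by construction. Image sets are drawn by systematic
  probability-proportional-to-size sampling, which makes the marginal
  frequency of each class in cell labels exactly proportional to the
  configured frequencies (provided the largest frequency does not exceed
  one over the maximal set size; the default profile respects this bound).
  Because cells within an image share a label set, cell labels are
  *clustered*; frequency-convergence checks therefore use independently
  generated units rather than cells pooled across one dataset.
* **Rendering.** Cells are non-overlapping ellipses placed by rejection
  sampling (an explicit error is raised when the requested density is
  unplaceable); border-truncated cells are allowed deliberately. Each
  class renders a distinct spatial pattern of the protein channel relative
  to the nucleus (nuclear fill, nuclear rim, cytoplasmic fill, puncta,
  perinuclear blob, cell rim, radial filaments, nucleolar dots), so
  classes are learnable by a small model. Nucleus, microtubule and ER
  channels carry class-independent structure; Gaussian intensity noise is
  added throughout (s.d. 8 on the 8-bit scale).
* **Capture defects.** With a configurable rate, a contiguous angular
  sector of a cell is removed before rendering, mimicking occlusion and
  segmentation failures. The recorded *captured fraction* of every cell
  compounds border truncation with the simulated defect, because both
  reduce the visible part of the cell body.

What the generator does **not** emulate: realistic textures and stain
chemistry, cell-line morphology differences, 3D-to-2D projection
ambiguity, and segmentation errors other than missing area. Passing the
benchmarks here shows the algorithms behave as designed on data with the
right label and defect structure; it does not certify performance on real
micrographs.

The **reference benchmark conditions** used throughout tests and the
reproduction script are 200 images of 12 cells each, six classes with
frequencies (0.32, 0.24, 0.17, 0.12, 0.09, 0.06), one or two labels per
cell, 128 px images, and a 25% image-level validation hold-out. These
sizes keep a full pipeline run in minutes on one CPU core while leaving
~2,000 cells for training.

## Weibull activation pooling

The aggregation path shared by all classifiers transforms the rectified
final convolutional tensor `R` elementwise by the Weibull function

    T_i = (R_i / lambda)^(zeta - 1) * exp(-(R_i / gamma)^eta),

averages `T` over the spatial grid (GAP) and power-normalises each
descriptor entry as `alpha * s^beta`. All six scalars are learnable; the
transform dampens weak responses while equalising a learnable share of
strong ones, and the power normalisation rebalances the resulting scale.
Choices:

* Parameters are stored as logarithms, so unconstrained gradient steps
  preserve positivity.
* The four Weibull scalars are shared across feature channels by default
  (a per-channel option exists); the sources describing the layer do not
  fix this, and sharing adds the fewest parameters.
* Initialisation `lambda = gamma = 1, zeta = 2, eta = 1` and
  `alpha = 1, beta = 0.5`: a smooth start near identity-scale behaviour.
* Inputs are clamped at `1e-8` before fractional powers so gradients stay
  finite at zero activations; an exact zero input with `zeta > 1` still
  maps to exactly zero.
* Analytic gradients with respect to the input and all four parameters are
  verified against central finite differences (relative error below 1e-4
  at 100 random positive points).

## Model families

All trunks are small stride-2 convolution stacks behind one `BackboneSpec`
interface (desk scale: three blocks, 32-d features on 32 px crops; the
default spec is four blocks, 128-d on 128 px). Crops are masked to their
cell, resized, and scaled to [0, 1]. The networks, their losses and Adam
with cosine-annealed learning rate are implemented in numpy with explicit
forward/backward passes; batch composition, augmentation and
initialisation are all seeded, so training is reproducible to the last
bit on one machine.

* **DSA (dual-stream).** Each cell of an image is embedded by the shared
  trunk + Weibull pooling; the image stream max-pools the bag of
  descriptors feature-wise and classifies the population, the cell stream
  classifies each descriptor. The loss is `L_f = W1 * L_image + W2 *
  L_cell` with `(1, 0.2)` in round 1 (weak cell labels deserve little
  trust) and `(1, 1)` in round 2 (refined labels). Bags are sampled
  without replacement when an image has more cells than the bag size and
  with replacement when it has fewer.
* **CLA (cell-level actnet).** Trunk -> Weibull pooling -> logistic head.
* **CLH (cell-level hybrid).** The CLA trunk with two hybrid-fusion
  blocks (after the first and second downsampling stages) that inject
  wavelet-scattering coefficients of the input: the coefficient stack is
  resampled to the trunk grid, projected to the trunk width by a
  learnable 1x1 convolution, concatenated, reduced back by a second 1x1
  convolution and added residually. Zeroing the projection reduces the
  block to a function of the deep features alone, and disabling fusion
  yields a model weight-compatible with the plain trunk (the ablation
  path).

Heads are elementwise logistic rather than softmax: the training loss is
binary cross-entropy on multi-label (and, after refinement, continuous)
targets, which requires independent per-class probabilities. A softmax
head exists for genuinely single-label tasks (the capture-ratio model).

Losses: class-weighted BCE with weights proportional to inverse class
frequency, normalised to mean one and capped at 100x the median weight
(rare/zero classes must not explode); plus a standard focal term
`(1 - p_t)^gamma` with `gamma = 2`, added at ratio 1:1. Augmentation:
random flips, quarter rotations, small shifts and cutout with
configurable probabilities (heavier crop/scale augmentation is available
through the same config but off by default at desk scale, where crops are
already tight).

The scattering transform is computed with a Morlet filter bank in the
Fourier domain (2 scales, 4 orientations, order 2 restricted to
decreasing-frequency paths). Band-pass filters have their DC bin zeroed
(constants map to exactly zero), convolutions are periodic (circular
shifts by the subsampling stride shift coefficients exactly), and the
filter bank is Littlewood-Paley normalised so the transform never
increases energy.

## Label refinement (CRA)

Weak positives are re-scored, never re-created: an ensemble of three
differently seeded cell-level models is trained on the current labels,
their per-cell confidences are averaged, power-normalised as `c^beta`,
and the result replaces each positive weak label; entries that are weakly
negative stay exactly zero (a class absent from the image cannot appear
in a cell). The process iterates (two rounds by default); refined labels
then train the round-2 models. `beta = 0.5` by default: a value below one
inflates mid-range confidences, shifting the label mass of true positives
away from zero, which is the intended qualitative effect; ranking-based
quality measures are invariant to this monotone transform, so `beta`
shapes the *loss geometry* of the next round rather than the label
ordering.

## Visual integrity (VID)

Two per-cell weights multiply the final probabilities:

* `W_1 = 1 - P(bad)` from an XGBoost classifier over eight geometric
  features (bounding-box height, width, aspect ratio and area, mask area
  and perimeter, largest dimension, and a stain flag), trained with
  five-fold cross-validation. The stain flag is 1 when fewer than 5% of
  crop pixels exceed intensity 10 (8-bit) in the nucleus or protein
  channel — the description of this feature in the source material is not
  operational, so this explicit rule is our choice, with both constants
  configurable. The mask perimeter counts mask pixels with a 4-neighbour
  outside the mask or on the raster border — simple and exactly testable.
  Training labels follow the half-captured convention: cells retaining
  more than ~55% of their body are good, cells below ~45% are bad.
* `W_2` from a four-class CNN predicting the captured fraction of the
  cell body, binned `[0, 0.3) -> 1`, `[0.3, 0.5) -> 2`, `[0.5, 0.8) -> 3`,
  `[0.8, 1] -> 4` and mapped to `0.1, 0.5, 1, 1`. The bins are read as the
  fraction *captured* (remaining), the reading consistent with the
  monotone weights. Training examples are generated by corrupting cells
  towards target fractions in each bin, compounding any truncation a cell
  already carries.

`W_v = W_1 * W_2` scales every class probability of the cell, so applying
VID can only shrink probabilities (a contraction).

## Evaluation

Predicted cells are greedily matched to ground-truth cells in descending
confidence at mask IoU strictly above 0.6; each matched prediction is a
true positive for the classes its ground-truth cell carries. Per-class AP
is the all-point (non-interpolated) area under the precision-recall
curve; the reported score is the unweighted mean over classes. Two
conventions worth noting:

* Classes with no ground-truth positives in the evaluated set are
  excluded from the mean (NaN per-class AP) rather than scored zero, so a
  perfect predictor scores exactly 1 on any manifest.
* On manifests with capture defects, cells below half captured are not
  scorable targets: they are removed from the ground truth while their
  predictions stay in the ranking as unmatchable detections. This mirrors
  the convention that no meaningful localisation call can be made for a
  cell whose majority is missing, and it is the regime in which
  down-weighting low-integrity cells helps rather than discards
  information.

## Fusion and ensembling

Per class, the Pearson correlation `r` between image-stream and
cell-stream probabilities is computed over validation cells whose parent
image carries the class (never on training predictions). Classes with
`r > 0.32` multiply the two streams; the rest keep the cell-stream value —
low correlation flags classes the image stream over-labels. Undefined
correlations (constant streams, fewer than two eligible cells) default to
the conservative cell-only mode. Ensembles select the best-scoring member
per architecture family (ties broken lexicographically), average member
outputs within a family and then across families ("hierarchical"
aggregation; a flat mean is available since the aggregation operator is
an open design point), apply the fusion policy, and finally multiply by
`W_v`.

## Mask post-processing

The reduced-resolution post-processor converts nuclei/cell probability
maps to instance labels: downscale by 0.5, threshold at 0.5, light
morphological opening (radius 1 at the reduced scale), nuclei-seeded
watershed on the cell foreground, nearest-neighbour upscale, and
relabelling to contiguous integers. Halving the resolution makes the
morphology roughly four times cheaper; on well-separated inputs the
instance count matches full-resolution processing exactly, which is the
contract the tests pin down.

## Known limitations

* The numpy network stack runs on one CPU core; desk-scale trunks are
  orders of magnitude smaller than production backbones, so absolute mAP
  values here are not comparable to published leaderboard figures.
* The capture-ratio model is trained on wedge-shaped simulated defects;
  straight-chord border truncations are out of its training family and
  are recognised less reliably (the structural weight carries most of the
  integrity signal in the benchmarks).
* Stream-correlation estimates on a few dozen validation images are
  noisy; with the fixed 0.32 threshold, borderline classes can flip mode
  between seeds.
* The synthetic patterns are linearly or near-linearly separable by
  design; none of the benchmarks probe robustness to the hard visual
  confusions real data contains (for example endoplasmic reticulum vs
  cytosol).
* At desk scale the hybrid model (CLH) trails the plain actnet rather
  than matching it: with 32 px crops and a three-block trunk the
  scattering branch adds little that the convolutions cannot learn, and
  the shared training schedule is not tuned for it. Mean-aggregating such
  a deliberately heterogeneous trio can fall below the best member;
  ensembles of comparably trained members do dominate (the tested
  property).
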