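# Methods

`shrewid` re-implements an image-analysis pipeline for identifying house
shrew (*Suncus murinus*) populations from skull silhouettes: segmentation
of a bright object on a darker field, seven region-based shape
descriptors, and a two-stage feed-forward neural classifier that first
assigns the skull view (dorsal, lateral, jaw) and then the population-sex
class (NM, NF, SM, SF — northern/southern × male/female of Peninsular
Malaysia). The original photographic corpus is not deposited anywhere, so
the package ships a synthetic silhouette generator that reproduces the
statistical structure the pipeline assumes and makes every stage testable
end to end.

## Segmentation

An RGB image is converted to luma grayscale (0.2989 R + 0.5870 G +
0.1140 B, divided by the weight sum so white is exactly 1.0). Edges are
detected by the order-statistic morphological gradient: the difference
between the last-order (maximum) and first-order (minimum) sliding-window
filters over a **10×10 domain** — the one fixed parameter of the original
chain. The gradient image is binarized (default: midpoint of the dynamic
range; Otsu via a 256-bin between-class-variance maximizer is available),
holes are filled (4-connected background flood), border-touching
components are cleared (8-connected objects), and particles smaller than
`min_object_area_frac` of the image area (default 1e-4, expressed as a
fraction so thumbnails and full-resolution photographs behave alike) are
removed. The largest surviving component is the region of interest.

Two numerical choices deserve comment:

* **Zero padding.** The order-statistic filters pad with zeros, which
  inflates the gradient along the image frame. This is harmless because
  frame-touching components are discarded by the border-clearing stage.
* **Gradient-band compensation.** The gradient marks a band roughly half
  the filter domain wide on *each side* of the true object outline, so the
  filled mask is the true object dilated by the (reflected) filter window.
  `extract_roi` therefore ends with a matched erosion — implemented with
  the exactly reflected window offsets, which differ by one pixel from the
  forward window for even domains. Dilation followed by its adjoint
  erosion is the identity on digitally convex regions, so recovery of
  convex silhouettes is exact (IoU 1.0 in the tests); on the concave jaw
  crescent a small closing residue remains at the horn tips (IoU ≈ 0.998).
  The compensation can be disabled in `SegmentationConfig` to obtain the
  raw (dilated) chain output.

## Shape descriptors

All seven descriptors are computed from first principles on 0-based
pixel-center coordinates:

* **area** — foreground pixel count.
* **convex area** — pixels whose centers lie inside or on the convex hull
  of the foreground pixel centers. (scikit-image hulls pixel *corners*
  instead, which is why its `area_convex` is systematically a few pixels
  larger; our choice matches the convention of the environment the
  pipeline originated in.)
* **major/minor axis length** — axes of the ellipse with the region's
  normalized second central moments, including the +1/12 per-pixel
  variance term. Without that term a single pixel would have zero axes,
  which breaks min-max feature normalization downstream.
* **perimeter** — length of the traced 8-connected outer boundary polygon
  through boundary pixel centers (axis step 1, diagonal step √2; isolated
  pixel 4 by convention). The tracer is a Moore-neighbor walk that
  terminates on the first repeated (pixel, backtrack) state, which handles
  one-pixel-wide spurs. The chain convention was chosen for transparency
  over bias-corrected weighted estimators; it overestimates smooth
  perimeters by about 5% (measured +5.3% on a digital circle of radius
  100, bounded at 6% in the tests).
* **equivalent diameter** — √(4·area/π).
* **extent** — area over the tight bounding-box area.

Feature order is frozen (`FEATURE_NAMES`) so serialized networks remain
portable.

## Classifier

Both stages use the same architecture: 7 inputs → tanh hidden layer
(default 10 units; the original hidden size is unrecorded, so this is a
configurable default) → softmax outputs (3 for the view stage, 4 per-view,
12 in the flat variant). Features are min-max normalized to [−1, 1] with
parameters fitted on the training split only; out-of-range values at
prediction time pass through unclipped.

Training minimizes multiclass cross-entropy on one-hot targets by
full-batch gradient descent with an adaptive step: a step is accepted only
if the training loss does not increase (backtracking halves the step,
acceptance grows it by 1.2), so the training trajectory is monotone.
Early stopping restores the best-validation-cross-entropy weights after
`max_fail = 6` epochs without improvement. The procedure restarts
`n_restarts` times (default 10) from independent initializations and keeps
the restart with the lowest validation cross-entropy — never the test
loss, to avoid selection leakage. All randomness flows from one integer
seed; identical inputs give bit-identical networks.

Splits are stratified per class at 70/15/15 by default. Counts use
largest-remainder rounding with ties resolved in declared set order
(train, val, test): 30 per class yields exactly 21/5/4. If a split leaves
the validation set empty (possible at extreme sweep shares), stopping and
restart selection fall back to the training loss.

## Evaluation

The headline accuracy is the *diagonal average*: the mean of per-class
correct fractions of a confusion matrix. With balanced classes it equals
trace/total; both are always computed, and the worked-example matrices in
`shrewid.reference` reproduce their published per-class and overall
percentages exactly (100% views; 72.5% dorsal; 87.5% lateral; 80.0% jaw).
`averaged_confusion` repeats a full split/train/identify cycle with
derived seeds and averages the matrices element-wise; `training_size_sweep`
grows the training share through 50…90% by prefix of one fixed per-class
shuffle, so each training set is nested in the next, with the remainder
split equally into test and validation.

## Synthetic data

The generator renders one bright silhouette (default levels 0.85 on 0.15)
per scene on a 512×384 canvas — deliberately smaller than the 4288×2848
source photographs; every area threshold is relative to image area, so the
scale is immaterial. Archetypes are: dorsal, two fused ellipses (a rounded
teardrop); lateral, a linearly tapered wedge; jaw, an open crescent whose
cavity guarantees convex area > area. Nuisance structure mirrors the
acquisition problems the original chain had to survive: a linear
illumination ramp, i.i.d. Gaussian pixel noise (default σ = 0.02, clipped
to [0, 1] and quantized to 8 bits), up to `n_clutter` small bright discs
kept at least one filter domain away from the object, an optional
border-touching component, boundary roughness from low-order random
Fourier modes (default amplitude 1.5 px), ±5° rotation and ±8 px center
jitter.

Class structure: within-class variability multiplies each semi-axis by
1 + N(0, 0.02); class k shifts the major semi-axis scale by
k · separation · 0.02, so `separation` is the between-class distance in
within-class standard deviations (the minor axis and taper shift by 0.6×
and 0.3× that step). The real populations' morphological effect sizes are
unknown — separation is an explicit experimental knob, not an estimate.
The default corpus for classifier experiments is 30 images per class per
view (the size of the original training corpus per class); "moderate
overlap" experiments use separation 2.5, which places hierarchical
accuracy in the 70–90% band the original study reported, and
well-separated experiments use 4.0.

What the generator does **not** emulate: photographic texture inside the
skull silhouette, specular highlights, shadows, perspective and lens
distortion, and any correlation between views of the same specimen (each
image is independent). Passing tests therefore demonstrate correctness of
the measurement and learning machinery under the stated statistical
structure, not performance on real museum photographs.

Determinism: per-image seeds are SHA-256 hashes of (master seed, view,
class, index), so datasets are byte-identical across runs and extensible
without reshuffling existing images.

## Problem sizes in tests and scripts

Feature-oracle checks run on ≤ 20×20 random masks against brute-force
oracles (gift-wrapping hull + point-in-polygon scan, explicit moment
summation, neighborhood sorting, exhaustive threshold enumeration).
Classifier-level experiments (separable recovery, chance level, monotone
degradation over separations {4, 2, 1, 0.5} × 10 seeds, hierarchical vs
flat over 20 seeds) run on truth-mask feature tables of 30 images per
class, which exercise the rasterizer and descriptors but skip image IO and
segmentation; the full render → segment → extract → identify path is
exercised end to end on smaller image counts. Training in these sweeps
uses 3 restarts; single-experiment checks use the 5-restart default.

## Known limitations

* The crescent archetype's truth recovery is bounded by the morphological
  closing residue (~0.2% of area); exact IoU 1.0 holds only for convex
  silhouettes.
* The chain perimeter estimator's ~5% smooth-shape bias is inherited by
  design; comparisons with other tools' perimeters must account for the
  convention.
* Absolute accuracies on synthetic data are functions of the separation
  knob and are not estimates of the published accuracies on real
  specimens; only the worked-example matrices reproduce those numbers.
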