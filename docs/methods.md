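# Methods

This note records the models implemented in `fieldseg`, the parameters
that matter, and the design choices made where the design was genuinely
open.  Notation: masks hold class indices {0 = Background, 1 = Crop,
2 = Soil}; image coordinates are x = column, y = row, 0-based at the
top-left pixel center, y increasing downward.

## Segmentation network

The network is an encoder–decoder DeeplabV3+ with a MobileNetV2 backbone
(width 1.0, inverted residual grid (t,c,n,s) = (1,16,1,1), (6,24,2,2),
(6,32,3,2), (6,64,4,2), (6,96,3,1), (6,160,3,2), (6,320,1,1)), run at
output stride 16: strides beyond 16 become dilation 2 in the depthwise
convolutions, which changes no parameter count.  The stride-4 24-channel
feature is the decoder's low-level input; the final 320-channel map
feeds the context head.  All convolutions that precede a batch norm are
bias-free; batch-norm affine weights count as trainable parameters.

**CBAM** (variants `attention_only`, `full`): one module on the final
320-channel backbone map.  Channel gate: global average- and max-pooled
descriptors pass a shared bias-free bottleneck 320 → 40 → 320
(reduction 8), are summed, then squashed by a sigmoid.  Spatial gate:
channel-wise mean and max maps stacked 2×H×W, one 7×7 convolution (with
bias) to a single channel, sigmoid.  The gates multiply the feature map
sequentially (channel first), so for any input |F″| ≤ |F| elementwise.

**ASPP**: five parallel branches on the 320-channel map — 1×1, three
3×3 atrous at rates (6, 12, 18), and global-average image pooling —
each to 256 channels, concatenated and projected 1×1 to 256.  Variants
`aspp_only`/`full` add a sixth, strip-pooling branch: 1×1 reduce to a
112-channel bottleneck, mean-pool along rows (H×1) and columns (1×W),
refine each strip with a 1-D convolution of length D = 3 (+BN),
broadcast both back to H×W and sum, then 1×1 (+BN) + sigmoid to a
320-channel gate that multiplies the branch input.  The gated 320-channel
map joins the concatenation, so the projection widens to 1600 → 256.

**Decoder**: low-level 24 → 48 (1×1+BN+ReLU); ASPP output bilinearly
upsampled 4×, concatenated (304 channels), refined by 3×3 convolutions
to 256 then 257 channels, classified 1×1 to 3 classes (with bias), and
upsampled 4× to input resolution.  Bilinear resizing uses half-pixel
centers throughout.

### Width calibration

The published record of this architecture family fixes the four
variants' complexity — 5.814 / 5.839 / 6.044 / 6.070 M trainable
parameters — but not the strip-pooling bottleneck or decoder widths.
Those widths were therefore calibrated once by exhaustive parameter
counting and frozen as the defaults above.  The exact counts are:

| variant          | parameters | increment |
|------------------|-----------:|----------:|
| baseline         |  5,813,736 |         — |
| attention_only   |  5,839,435 |   +25,699 |
| aspp_only        |  6,043,912 |  +230,176 |
| full             |  6,069,611 |      both |

All four round to the published 3-decimal figures, and the CBAM and
strip-pooling increments are exactly equal across variants (the printed
table's apparent inconsistency — +0.025 vs +0.026 for the same CBAM —
is a rounding artifact of exactly these counts).  Changing
`decoder_widths` (48, 256, 257) or `spl_mid_channels` (112) moves the
counts; they are configuration constants, not tuning knobs.

## Training

Loss: multi-class Dice, the unweighted mean over the 3 classes of
1 − 2Σpg/(Σp² + Σg²), with p the softmax probabilities and g the
one-hot truth.  The single-class form is the textbook Dice loss; the
mean-over-classes extension keeps the [0, 1] range and the
imbalance-robustness that motivates Dice for field scenes dominated by
one class.  A class empty in both p and g is a perfect match and is
excluded from the mean (the differentiable training path adds ε = 10⁻⁵
to the denominator, which softmax keeps positive anyway).

Optimizer: Adam with β₁ = 0.9 ("momentum 0.9" is read as β₁), β₂ =
0.999, no weight decay, batch size 8.  Learning rate: cosine annealing
per epoch, 5·10⁻⁴ → 5·10⁻⁶, no warm restarts.  All shuffling and
initialization randomness derives from a single seed; single-threaded
runs are bitwise reproducible.

**Batch-norm recalibration.** After short runs (tens of optimizer
steps) the exponential running estimates of the batch-norm statistics
lag far behind the trained weights, so eval-mode predictions
underperform train-mode ones.  `train_epochs` therefore ends (and
precedes each validation pass) with the standard precise-BN sweep:
one forward pass over the training set replacing the running statistics
with cumulative batch averages.  It changes no trainable weight and is
switchable off (`TrainConfig.bn_recalibrate`).

## Segmentation metrics

From the (k+1)×(k+1) confusion matrix (entry (i, j): truth i, predicted
j): global PA = trace/total; per-class PA = row-normalized diagonal;
IoU_i = p_ii/(row_i + col_i − p_ii); mPA and mIoU are unweighted means.
The IoU numerator is the diagonal p_ii — intersection over union as the
definition demands.  Classes with no truth pixels (no union, for IoU)
are excluded from the means rather than scored 0 or 1, which would
otherwise dominate small synthetic scenes.  For every matrix,
mIoU ≤ mPA (classwise IoU ≤ recall).

## Boundary extraction

Binarization selects the target classes on the label raster directly
(no luminance conversion is needed when the input is already a class
mask).  Cleaning is one morphological opening — erosion then dilation
with a square 3×3 element by default — which removes speckle without
growing foreground.  Regions are 8-connected components (background
4-connected, the standard duality); components smaller than `min_area`
(default 0.1 % of the image, configurable) are dropped as likely
misclassifications, and labels are renumbered in row-major order of
first appearance.

Contours are traced by Moore-neighbor tracing with Jacob's stopping
criterion, clockwise on screen, starting at the region's
uppermost-then-leftmost pixel.  Interior holes are traced on request by
starting the same walk on the region pixel directly above each hole's
top-left pixel; the union of outer and hole contours equals exactly the
brute-force border set (region pixels with a 4-neighbor outside the
region or on the image frame) — this equality is property-tested over
hundreds of random masks.

## Line fitting

A traced path's points are split into horizontal and vertical candidate
pools by the direction of travel.  Because consecutive traced points
are 8-adjacent, a per-step threshold on |Δy| is trivially satisfied;
the implementation instead classifies each point by the path
displacement across a ±3-step window (mostly-x ⇒ horizontal, mostly-y ⇒
vertical, diagonal ⇒ both, so corner points may join both pools), which
smooths over the single diagonal steps of a rasterized sloped edge.
Each pool is clustered on the perpendicular coordinate: a jump larger
than the rule threshold (50 px at the 1024-px reference tile size,
scaled linearly to the image; the smaller of `delta_threshold` and
`gap_threshold`) starts a new line set, and sets with fewer than 4
points are dropped.  Finally `end_trim` (3 px) is shaved off each set's
parallel extremes, where corner staircases contaminate the segment.

Horizontal sets are fitted as y = θ₀ + θ₁x, vertical sets as
x = θ₀ + θ₁y (axis swap keeps |θ₁| < 1 and the design matrix well
conditioned).  Least squares minimizes S = Σ(f(uᵢ) − vᵢ)²; the residual
scale is the standard regression estimator S_e = √(S/(m − (n+1))), and
points with standardized residual |eᵢ|/S_e > 3 are removed and the line
refitted, iterating to a fixed point (≤ 5 rounds; one round reproduces
a single screening pass).  A perfect fit (S_e = 0) removes nothing.

The pipeline applies a half-pixel intercept correction by default:
the fit runs through boundary *pixel centers*, which sit on average
half a pixel inside the geometric field edge, so the line is shifted
0.5 px away from the region side (judged at the region centroid).

**Errors.**  Angular error: |arctan θ₁ᵗ − arctan θ₁ᶠ| in degrees, in
the lines' common (possibly swapped) frame.  Vertical error:
|θ₀ᵗ − θ₀ᶠ| at coordinate 0, normalized by the image height
(horizontal lines) or width (vertical lines, the swapped-frame analog).
For evaluation, each true line is matched to the fitted line of the
same orientation minimizing the mean absolute deviation over the true
line's span — matching on the intercept alone confuses parallel
boundaries of neighbouring plots whose intercepts nearly coincide.

### Quantization limits of least squares on rasterized edges

A rasterized edge whose true slope is below one pixel per span length
shows at most one staircase transition; least squares on a step
function estimates slope ≈ 1.5/L (L the span in pixels) regardless of
the true value.  Two consequences shape the test conditions:

- angular error ≤ 0.5° requires L ≳ 170 px;
- the vertical error is read at coordinate 0, so a span centered a
  distance d from the origin inflates a slope error by d; with the
  1.5/L worst case this costs ≈ 1.5·d/L pixels against a 2 px budget.

Single-plot scenes (edge length ≈ 0.76 of the frame, d ≤ L) satisfy
both bounds with margin at any frame size — measured worst case over
50 seeded 256-px scenes: 0.39° and 0.0030 vertical error against the
0.5° / 0.0078 bounds.  Grid layouts with 3–4 plots put some edges at
d ≈ 2L, where the worst-case vertical error (~2.2 px) exceeds the
budget at any resolution; such scenes are therefore exercised through
mean-error checks rather than per-line worst-case bounds.

## Synthetic scenes

`generate_scene` emulates the label structure of aerial farmland tiles:
1–4 convex quadrilateral plots (jittered from axis-aligned rectangles,
edge tilt ≤ 0.3 by default so the horizontal/vertical dichotomy
applies), placed in disjoint grid cells with ≥ 8 px separation, each
labelled Crop or Soil on a Background canvas.  Masks are rasterized
exactly (pixel center inside the closed polygon), so every analytic
edge line coincides with a mask transition within one pixel.  Textures
are per-class base colors plus i.i.d. Gaussian noise (σ = 10 digital
numbers) and a periodic row-stripe modulation for Crop — enough
structure for a small network to learn, with no claim to photorealism.
One seed sequence per scene is split into geometry / texture / noise
substreams, so adding noise never changes geometry.

`perturb_mask` emulates imperfect segmentation output: smooth
boundary-displacement jitter (Gaussian field, σ in pixels), independent
per-pixel label flips, and circular dropout blobs.  Zero noise is the
identity.

What the generator does **not** emulate: perspective and lens
distortion, shadows and illumination gradients, curved or ragged field
edges, within-class texture variety, and inter-class color ambiguity.
Passing tests therefore demonstrate the correctness of the geometry
pipeline and the trainability of the network, not field-ready accuracy
on real UAV imagery.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale conditions: the training smoke
run uses 32 scenes of 128×128 px (plus a 2-scene held-out pair) for
5 epochs of the `full` variant; line-recovery checks use 50 single-plot
256-px scenes; the tracing oracle uses 200 random 32×32 masks.  The
whole suite runs in a few minutes on one CPU core.

## Known limitations

- The network trains and infers on CPU via the bundled numpy autograd;
  it is suitable for experiments at the scales above, not for training
  on thousands of 1024-px tiles.
- Order-1 fitting is the default; higher polynomial orders are exposed
  but the error metrics are defined for straight lines only.
- Edges tilted beyond ~45° defeat the horizontal/vertical split rule by
  construction; the generator's `max_edge_slope` flag can produce such
  stress cases, which the fitting stage is not designed to handle.
- Sub-pixel edge estimators (digital-straight-segment recognition,
  grey-level interpolation) would beat the least-squares staircase
  limits above, but plain least squares is the method implemented.
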