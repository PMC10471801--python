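# fieldseg

Farmland boundary extraction from aerial RGB orthoimagery, for
agricultural-robotics and remote-sensing work that needs machine-readable
field edges (path planning for autonomous machinery, parcel mapping).

The method has two separable stages:

1. **Semantic segmentation.** A lightweight DeeplabV3+ encoder–decoder
   labels every pixel as *Background*, *Crop* (cropped farmland) or
   *Soil* (bare farmland).  The encoder is a MobileNetV2
   inverted-residual backbone at output stride 16, optionally augmented
   with a convolutional block attention module (CBAM) on its final
   320-channel feature map and a strip-pooling branch inside the atrous
   spatial pyramid pooling (ASPP) head.  Strip pooling averages features
   over 1×W and H×1 kernels, which suits the long, thin, straight
   structures (field edges, paths, ditches) that square pooling windows
   dilute.  Training minimizes the multi-class Dice loss
   `L = mean_c [ 1 − 2·Σ p·g / (Σ p² + Σ g²) ]`
   with Adam (β₁ = 0.9), batch 8, and a cosine-annealed learning rate
   `lr(t) = lr_min + ½(lr₀ − lr_min)(1 + cos(πt/T))` from 5·10⁻⁴ down to
   5·10⁻⁶.

2. **Boundary-line fitting.** The class mask is binarized, cleaned by a
   morphological opening, and split into 8-connected regions (tiny
   regions are discarded as misclassifications).  Each region's contour
   is traced with Moore-neighbor tracing (Jacob's stopping criterion),
   the ordered boundary points are partitioned into horizontal
   (y = θ₀ + θ₁x) and vertical (x = θ₀ + θ₁y) line sets, outliers with
   standardized residual |eᵢ|/S_e > 3 are removed, and each set is fitted
   by least squares.  Fits are scored by the angular error (degrees
   between true and fitted line) and the vertical error (intercept gap at
   coordinate 0, normalized by the image extent).

Since aerial survey data of this kind is rarely redistributable, the
package ships a seeded synthetic-scene generator (convex quadrilateral
plots with known analytic edge lines, textured renderings, exact masks,
and controllable corruption) that every stage is tested against.

The network stack runs on a small tape-based numpy autograd engine
included in `fieldseg.nn` (im2col convolutions, fused batch norm,
bilinear resizing); there is no GPU or deep-learning-framework
dependency.

## Worked example

Generate a two-plot synthetic scene, extract its boundary lines from the
mask, and score them against the generator's ground truth:

```sh
$ fieldseg synth --out demo --count 1 --size 256 --plots 2 --seed 5
wrote 1 scenes to demo
$ fieldseg extract --mask demo/masks/scene_0000.png --out demo/lines.json
8 line(s) -> demo/lines.json
$ fieldseg eval-lines --lines demo/lines.json \
      --truth demo/truth/scene_0000.lines.json --height 256
matched 8 line pair(s)
mean angular error  0.041 deg
mean vertical error 0.0005
```

Two quadrilateral plots have eight edges; all eight are recovered, on
average within 0.041° of the true direction and with an intercept gap of
0.05 % of the image height.

The four network variants and their trainable-parameter complexity:

```sh
$ fieldseg params
variant          params (M)
baseline              5.814
attention_only        5.839
aspp_only             6.044
full                  6.070
```

`baseline` is plain MobileNetV2-DeeplabV3+; `attention_only` adds the
CBAM (+0.026 M), `aspp_only` adds the strip-pooling branch (+0.230 M),
and `full` combines both.

Other subcommands: `train` (Dice + cosine schedule on a dataset
directory), `predict` (mask from a checkpoint), `fit` (traced boundary
coordinates), `eval-seg` (PA / mPA / mIoU over mask directories).

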