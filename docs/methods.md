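# Methods

## Problem and model

The package estimates how much food was eaten from a plate using a single
top-down RGB-D camera, the acquisition style used for food-and-fluid intake
charting in long-term-care and hospital settings. Two acquisitions drive
every estimate: a *calibration* shot of the empty plate and a *plate* shot
with food, each a burst of depth frames plus an RGB image. The plate itself
is the metric reference: its known physical diameter `d` (259 mm by
default) and detected pixel radius `r̂` give the lateral scale
`Δx = d / (2 r̂)` in mm/px.

The processing chain is:

1. **Plate detection.** Canny edges on the luminance channel (Gaussian
   σ = 3, hysteresis 10/50 in 8-bit units) followed by a circle Hough
   transform over the expected radius range. The highest-vote circle wins;
   exact ties break toward the smaller radius so the detector prefers the
   rim over its outer shadow.
2. **Height map.** Depth bursts are averaged per pixel (10 frames by
   default), the calibration map is translated by
   `T = (x_P − x_C, y_P − y_C)` so the plate centers coincide, and food
   height is the per-pixel difference `h_i = d_C,i − d_P,i` (mm). A
   row-wise planar correction then pins the table strips left and right of
   the plate to 0 mm, and a 5×5 median filter suppresses spurious values at
   the plate rim.
3. **Initial segmentation.** Either a colour-distance baseline (pixels
   chromatically far from the estimated plate colour), a seeded graph cut
   (the semi-automatic comparator), or the encoder–decoder network.
   All masks are clipped to the plate interior.
4. **Depth refinement.** The RGB image is decomposed into ~250 SLIC
   superpixels (compactness 20, σ = 2); any superpixel whose 0.75-quantile
   of pixel heights is below τ = 2 mm is removed from the mask. This
   deletes visually salient but volumetrically negligible regions — the
   *visual-volume discordance* fix. Pixels are only removed, never added.
5. **Volumetrics.** `V = Σ_{i∈F} (Δx)² h_i`, mm³ → mL by ÷1000. Intake is
   full-portion volume minus current volume; percent intake is that
   difference relative to the full portion.

## Key parameters

| parameter | default | unit | role |
|---|---|---|---|
| plate diameter `d` | 259 | mm | metric reference; sets Δx |
| Canny σ / hysteresis | 3 / 10, 50 | px / 8-bit | edge detection for Hough |
| Hough radius range | 0.25–0.48 × min dim | px | expected plate radii |
| burst length | 10 | frames | depth-noise averaging |
| median window | 5×5 | px | rim artefact suppression |
| superpixel count / compactness / σ | 250 / 20 / 2 | — | refinement units |
| quantile p / threshold τ | 0.75 / 2 | — / mm | removal rule `Q(p) < τ` |

τ = 2 mm reflects depth measurement error along a flat table: superpixels
whose height distribution is statistically indistinguishable from an empty
table carry no credible volume.

The Hough radius range is wider at the low end than a tight "plate
framing" prior because the canonical acquisition geometry (259 mm plate at
1 mm/px in a 480-row frame) puts the plate radius at 0.27 × the image
height.

## Tilt correction

The calibration translation handles in-plane shifts but not tilt changes
between acquisitions. For each row we take the valid off-plate pixels as
left and right table strips, compute each strip's mean column and mean
height, and subtract the straight line through those two anchor points.
This is exact for planar tilt (the correction line coincides with the
row's restriction of the plane) and idempotent: after one pass both strip
means are zero, so a second pass subtracts nothing. A weighting linear in
the distance to the image borders was considered and rejected: it leaves
ramp residuals of the same order as the tilt on rows where the strips are
asymmetric, and it is not a projection. Rows fully covered by the plate
inherit the nearest row's strip statistics — planar tilt varies slowly, so
borrowing across a few rows is safe.

Negative heights are retained by default (zero-mean depth noise cancels in
volume sums); a clamp-at-zero flag exists for reflective surfaces.
Registration rounds to whole pixels — depth texture is smooth at plate
scale, and interpolation would smear the step edge at the rim; pixels
shifted out of frame become NaN and are excluded from strips and volume
sums.

## Quantile convention

Removal decisions near τ depend on the quantile definition, so it is fixed:
linear interpolation between order statistics (NumPy's default, the
"type 7" estimator). The quantile is computed over *all* pixels of the
superpixel; a masked-only mode exists behind a flag. The two modes agree
whenever mask boundaries follow superpixel boundaries, since removing
pixels that are not in the mask is a no-op.

## The segmentation network

The network maps a 120×160 RGB input to a two-class per-pixel score map.
The encoder is the stem and first residual block of a pre-activation
residual classifier: 7×7/stride-2 convolution (64 kernels), 3×3/stride-2
max pool, then three bottleneck units (1×1×64, 3×3×64, 1×1×256 with a skip
around each), the last 3×3 with stride 2 — 256 feature maps at 15×20, 1/8
scale. The decoder max-pools these features into 1×1, 2×2, 3×3 and 6×6
bins, reduces each to 64 channels with a 1×1 convolution (a conventional
pyramid-pooling reduction), upsamples back to 15×20, concatenates with the
encoder maps and applies a 1×1 two-class head; logits are bilinearly
upsampled to 120×160 before the softmax cross-entropy loss.

The implementation is plain NumPy — im2col convolutions forward, manual
gradients for the decoder backward. Only the decoder trains (RMSProp,
batch 32, learning rate 1e-4, decay 0.995, up to 200 epochs, 80/20 seeded
split, best-validation checkpoint); the encoder is frozen. ImageNet
pretrained weights for the spliced encoder are an initialisation this
package does not ship; with random encoder weights the frozen-feature
pipeline still trains to the architectural contract, which is what the
tests assert. "Decay 0.995" is read as the RMSProp moving-average
coefficient; a per-epoch learning-rate schedule reading is available under
`decay_mode="lr_schedule"`. The RMSProp cache warm-starts at the first
gradient's square, avoiding the cold-cache step spike. Background
augmentation rotates the hue of non-food pixels by a uniform angle over
the full hue circle, leaving food pixels bitwise unchanged.

Masks produced at 120×160 are upsampled nearest-neighbour to the native
depth resolution before volumetrics; nearest-neighbour at an integer
factor preserves the food-area ratio.

## Graph cut

The comparator follows the interactive seeded formulation: per-label RGB
Gaussian mixtures (3 components) fit to stroke pixels give unary costs,
4-connected pairwise terms are contrast-sensitive exponentials
`λ exp(−β‖c_i − c_j‖²)` with β defaulting to `1/(2⟨‖c_i−c_j‖²⟩)`, and
stroke pixels are hard-constrained. The min-cut is solved exactly on
integer-scaled capacities (scale 100); the returned labelling is checked
against exhaustive enumeration on toy lattices in the tests. Batch runs
synthesise seeds mimicking the manual protocol: one straight stroke through
each item's centroid, one background polyline along the top and right
margins.

## Synthetic scenes

The generator renders what the acquisition protocol produces: a circular
plate of known diameter on a table plane, parametric food items with
closed-form volumes (spherical-cap domes, cylinder mounds, sub-2-mm
smears), optional planar tilt applied to the plate shot, plate translation,
and per-frame Gaussian depth noise. Depth is camera-to-surface distance:
table at 600 mm, plate surface 4 mm shallower, food subtracting its height.
The rendered rim ring is kept below the Canny hysteresis band so the only
circular edge is the plate–table boundary at the true radius. Intake
series scale each item's rendered height field by (1 − fraction), which
scales the analytic volume exactly linearly (rescaling a dome's peak
parameter instead would reshape the cap and break linearity — the test
suite caught exactly this).

What the generator does *not* emulate: real food texture and colour
variation, specular/reflective surfaces that defeat depth sensors,
non-planar tilt, lens distortion, plate wells, occlusion, and mixed or
touching foods with ambiguous boundaries. Passing tests therefore
demonstrate the correctness of the geometry, calibration, refinement and
accounting machinery under the stated acquisition model — not segmentation
quality on real plates, which depends on a trained network and real data.

## Experiment sizes

The reference experiments run at the native acquisition geometry, 480×640
at 1 mm/px: a 30 mm hemispherical dome for volume recovery (56.5 mL closed
form), an empty plate with ≤5 mm tilt and ≤10 px translation for
calibration robustness, σ = 1 mm / 10-frame bursts for noise handling, a
15 mL dome vs 15 mL smear pair (the tablespoon example) and a 5-portion
series with a persistent 1 mm smear for the discordance reproduction, and
a 5-portion dome series for intake monotonicity. The metric oracle check
uses 1000 random 16×16 mask pairs against per-pixel Python counting.

## Known limitations

* The colour baseline assumes food is chromatically distinct from the
  plate and the annulus at 0.5–0.8 r̂ is mostly food-free; it is a fixture
  segmenter, not a food model.
* Refinement can remove boundary superpixels that mix food with plate,
  slightly under-segmenting tall items — the same behaviour reported for
  depth-refined methods on real data (negative volume bias); the package
  reproduces and reports it rather than correcting it.
* Percent intake is undefined for an empty reference portion and raises.
* Single-plate scenes only; ellipse fitting for off-axis cameras is out of
  scope.
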