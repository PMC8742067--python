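# depthplate

Depth-refined food segmentation and volumetric intake estimation from
top-down RGB-D plate images.

Monitoring food intake in long-term care and hospital settings is done by
eye and chart, which is slow and subjective. Given two acquisitions from a
single overhead RGB-D camera — an empty *calibration* plate and the *plate*
with food — this package computes a food height map, a depth-refined food
mask, the food volume in mL, and the intake (volume and percent) relative
to a full reference portion, plus the full segmentation/intake evaluation
metric suite.

The core ideas:

* **Plate-anchored metric calibration.** The plate's known diameter `d`
  (259 mm) and Hough-detected pixel radius `r̂` give the scale
  `Δx = d / (2r̂)` mm/px — no checkerboards or fiducials.
* **Height by calibrated subtraction.** Depth bursts are averaged, the
  calibration map translated by `T = (x_P − x_C, y_P − y_C)` to align plate
  centers, and food height is `h_i = d_C,i − d_P,i`, tilt-corrected
  row-wise against the table and median-filtered (5×5).
* **Superpixel depth refinement.** The image is split into ~250 SLIC
  superpixels; any superpixel whose 0.75-quantile of heights falls below
  τ = 2 mm is deleted from the food mask. This removes *visually* salient
  but volumetrically negligible regions (a 1 mm sauce smear covering a
  quarter of the plate), the "visual-volume discordance" that makes
  pixel-count intake estimates unreliable for minced and pureed foods.
* **Volume integration.** `V = Σ_{i∈F} (Δx)² h_i` (mm³ → mL), intake
  `= V_full − V_current`, percent intake relative to `V_full`.

Initial masks come from a colour-distance baseline, a seeded graph cut
(the semi-automatic comparator), or a pyramid-pooling encoder–decoder
segmentation network (NumPy implementation, decoder-only training).
A synthetic RGB-D scene generator with closed-form ground-truth volumes
(spherical-cap domes, cylinder mounds, thin smears, tilt, translation,
depth noise, P1–P5 intake series) makes every stage testable without
hardware or downloads.

## Worked example

Simulate a five-portion intake series (40 mm dome, progressively eaten)
and run the full pipeline with the colour baseline and depth refinement:

```python
from depthplate import FoodItem, SceneSpec, generate_intake_series
from depthplate import PipelineConfig, run_series

dome = FoodItem("dome", radius_mm=40.0, peak_height_mm=30.0)
scenes = generate_intake_series(SceneSpec(items=(dome,), seed=0))
series = run_series(scenes, PipelineConfig(segmenter="color", refine=True))
for rep, s in zip(series.reports, scenes):
    print(f"{rep.portion}  {rep.plate_volume_ml:6.1f} mL   "
          f"intake {rep.intake_ml:6.1f} mL ({rep.intake_percent:5.1f}%)   "
          f"analytic {s.truth.volume_ml:.1f} mL")
```

prints

```
P1    90.1 mL   intake    0.0 mL (  0.0%)   analytic 89.5 mL
P2    67.6 mL   intake   22.5 mL ( 25.0%)   analytic 67.2 mL
P3    45.0 mL   intake   45.0 mL ( 50.0%)   analytic 44.8 mL
P4    22.5 mL   intake   67.6 mL ( 75.0%)   analytic 22.4 mL
P5     0.0 mL   intake   90.1 mL (100.0%)   analytic 0.0 mL
```

P1 is the full reference portion; each later portion's volume tracks the
analytic truth to within ~1%, and percent intake recovers the simulated
25% consumption steps.

The same pipeline is scriptable from a shell:

```
depthplate simulate --seed 3 --out fixtures/
depthplate detect fixtures/scene_calib_rgb.png
depthplate volume fixtures/
depthplate run --batch batch.yaml --out out/
```

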