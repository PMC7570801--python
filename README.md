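# slicevol

Single top-view volume, mass and size-class estimation for slender
axi-symmetric produce (carrots, cucumbers and similar), using a
frustum-slice decomposition of the object's binary silhouette.

Given one calibrated top-view image, the pipeline:

1. extracts the object silhouette with an HSV (or Otsu-on-saturation)
   threshold, morphological cleanup, largest-component selection and hole
   filling;
2. fits the minimum-area rotated bounding box, which makes the measurement
   rotation-invariant;
3. measures cross-widths at `n + 1` equally spaced stations perpendicular
   to the box's length axis;
4. models the two end slices as elliptical caps (`pi*d1*d2*h/6`) and every
   mid slice as a frustum (`h/3 * (B + B' + sqrt(B*B'))`) with elliptical
   cross-sections, where the unseen depth diameter is the visible width
   divided by the product's width/height aspect ratio;
5. converts volume to mass with the product's average density and assigns a
   commercial size class.

Also included:

- **Baselines** — the classic one-pixel disk method (one- and two-view) and
  multiple linear regression on length plus five parallel widths.
- **Evaluation** — mean absolute percentage error, Bland–Altman limits of
  agreement, squared Pearson correlation, paired t-test, confusion-matrix
  accuracy and method-comparison tables.
- **Synthetic fixtures** — a renderer for parametric solids (cylinder,
  cone, ellipsoid, spindle, tapered-carrot, bent-spindle) with closed-form
  volumes, used throughout the test suite as analytic ground truth.

## CLI

```bash
# generate a synthetic calibrated dataset with ground truth
slicevol simulate --product carrot --n 50 --seed 1 --px-per-cm 70 --out data/carrots

# estimate volume/mass/class for images (batch CSV + optional per-image JSON)
slicevol estimate data/carrots/*.png --px-per-cm 70 --product carrot \
    --out results/batch.csv --debug-overlay results/overlays

# compare methods against ground truth, with a slice-count sweep
slicevol benchmark --dataset data/carrots --product carrot \
    --methods proposed,disk1,mlr --sweep 3:15 --out results/bench

# fit the MLR baseline
slicevol fit-mlr --dataset data/carrots --out results/mlr.json
```

The calibration factor (`--px-per-cm`) is always supplied explicitly, never
inferred from image metadata. A YAML config file (`--config`) can hold
`px_per_cm`, `product`, `n_slices`, `threshold` settings and custom product
profiles (`name`, `aspect_ratio`, `density_g_per_ml`, `classes`,
`n_slices`); command-line flags override file values.

Built-in product profiles: `carrot` (aspect ratio 0.9531, density
1.0987 g/mL, classes S/M/L/2L) and `cucumber` (0.9677, 1.019 g/mL,
S/M/L/XL). The default slice count is 8 for both.

## Notes

- The cap formula `pi*d1*d2*h/6` equals a semi-ellipsoid (it is twice the
  volume of an elliptical cone); it is implemented exactly as printed in
  the source method.
- Size classes use half-open `[low, high)` intervals with shared endpoints
  assigned to the upper class; the cucumber 200 g boundary belongs to L and
  XL is open above 200 g.
- Strongly bent objects (the `bent-spindle` fixture) degrade the estimate
  because the straight box axis no longer tracks the centerline; no bending
  correction is attempted.
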