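# redoxtrack

Automated analysis of **wide-field one-photon redox imaging** of patient-derived
cancer organoids (PCOs). Label-free autofluorescence of the metabolic
co-enzymes NAD(P)H and FAD is acquired as two-channel image time series per
well; `redoxtrack` turns those image stacks into per-organoid longitudinal
measurements of metabolism and morphology, and fits the statistics needed to
call treatment response.

The pipeline:

1. **Registration** — rigid XY alignment of every frame to the pretreatment
   frame by maximizing normalized cross-correlation of the NAD(P)H channel;
   identical shifts applied to the FAD channel; all frames cropped to the
   common overlap.
2. **Optical redox ratio** — per pixel,
   `ORR = NAD(P)H / (FAD + NAD(P)H)`, a map of cellular oxidation–reduction
   state, computed on raw registered intensities (no background subtraction).
3. **Segmentation** — a 12-step edge-enhancement algorithm (median filter,
   Gaussian background subtraction, local-standard-deviation edge image,
   3-class Otsu, hole filling, erosion, Chan–Vese active contours, h-minima
   watershed splitting, edge smoothing, area > 1000 px and circularity > 0.4
   selection), designed for the low signal-to-background ratio (≈2–3) of
   wide-field autofluorescence.
4. **Tracking** — LAP-style two-pass linking of organoid centroids across
   frames (200 px max link distance, 200 px gap-closing distance, 2-frame max
   gap), giving each organoid a persistent identity over 48 h.
5. **Quantification** — 24 variables per organoid per time point: mean / min /
   max / sd of ORR, NAD(P)H and FAD intensity (12 metabolic), plus area,
   perimeter, solidity, extent, eccentricity, circularity, min/max Feret
   diameter, minor/major axis, convex area and equivalent diameter
   (12 morphological). Border-touching organoids are excluded.
6. **Longitudinal statistics** — pretreatment normalization (per organoid or
   per well), the random-intercept linear mixed model
   `Y ~ time + treatment + treatment:time + (1 | organoid)` with AR(1)
   within-organoid residual correlation (REML), least-squares means with
   Tukey-HSD pairwise treatment contrasts per time point, bivariate
   regressions and the 24×24 pretreatment correlation matrix.
7. **Multivariate analysis** — PCA with within-timepoint standardization,
   loadings fit on pretreatment data, out-of-sample projection of 24/48-h
   data, top-12 loading report and 95% bivariate-normal ellipses per
   subpopulation.

A built-in **phantom generator** renders two-channel organoid image series
with known ground truth (masks, tracks, per-organoid area and ORR
trajectories, solid/hollow phenotypes, treatment-dependent dynamics, stage
drift, camera noise), so every stage is validated quantitatively without any
real microscope data.

## Worked example

```python
from redoxtrack.phantom import PhantomConfig, generate_phantom_series
from redoxtrack.pipeline import process_well
from redoxtrack import stats as rstats
from redoxtrack.segmentation import dice

cfg = PhantomConfig(seed=42, n_organoids=8, drift_px=(2, 2), treatment="control")
series, truth = generate_phantom_series(cfg)

result = process_well(series)          # register -> ORR -> segment -> track -> quantify
print([(s.dy, s.dx) for s in result.shifts])

y0, y1, x0, x1 = result.region         # crop truth to the registered field
print(dice(result.masks[0] > 0, truth.masks[0][y0:y1, x0:x1] > 0))

norm = rstats.normalize(result.features, "area", rstats.ORGANOID_LEVEL)
print(norm.query("time_h == 48.0")["Y"].mean())
```

prints

```
[(0, 0), (-2, -2), (-4, -4), (-6, -6), (-8, -8), (-11, -10)]
0.9991139580064868
1.1009983183233416
```

The recovered shifts mirror the 2 px/frame stage drift written into the
phantom (the last frame differs by one pixel because the organoids grew
between frames, so the frame is not a pure translation of the reference).
Segmentation overlaps ground truth with Dice 0.999, and the mean
organoid-level-normalized area at 48 h is 1.10: the pipeline recovers the
configured +10% control growth to within 0.1 percentage points.

A full multi-well run (phantom plate with all five treatment groups —
control, cyanide, 2-deoxy-glucose, cisplatin, paclitaxel) is one command:

```sh
redoxtrack all --phantom-plate --seed 7 --out run7
```

which writes per-well ORR/mask TIFFs and tracks, the pooled feature table,
least-squares-means contrast tables for mean ORR and area, PCA scores and
loadings, and a JSON-lines run log recording every exclusion.

## Feature table schema

`features.csv` is long-format: one row per (organoid, time point), keyed by
`organoid_id, well, treatment, time_h, border_touching`, followed by the 12
metabolic columns (`mean_orr, min_orr, max_orr, std_orr`, same for `nadh`
and `fad`) and 12 morphological columns (`area, perimeter, solidity, extent,
eccentricity, circularity, feret_min, feret_max, minor_axis, major_axis,
convex_area, equivalent_diameter`), in pixel units (1 px = 1.625 µm at the
acquisition scale).

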