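# Methods

This note documents the models, algorithms and numerical choices in
`redoxtrack`, what the phantom generator does and does not emulate, and the
known limitations.

## Imaging model and the optical redox ratio

Wide-field one-photon epifluorescence imaging of organoids records two
channels per time point: NAD(P)H (DAPI filter cube) and FAD (GFP filter
cube). The per-pixel optical redox ratio

    ORR(i, j) = NADH(i, j) / (FAD(i, j) + NADH(i, j))

lies in [0, 1] whenever either channel is positive, with higher values
indicating a more reduced metabolic state. Intensities are used exactly as
recorded: no exposure normalization between channels and no background
subtraction, because variations in medium autofluorescence would otherwise
leak into the quantification. Pixels that are zero in both channels are
carried as NaN ("undefined") rather than 0, so they cannot bias minimum or
mean statistics; they are excluded from all downstream ORR statistics.

## Registration

Stage repositioning between time points produces a global integer-pixel XY
translation. `estimate_shift` computes the exact windowed normalized
cross-correlation for every integer offset via FFT running sums (all five
overlap sums — Σr, Σm, Σr², Σm², Σrm — are correlations with constant
arrays), which is algebraically identical to brute-force NCC at every
offset. Ties are broken by smaller shift magnitude, then lexicographically.
Offsets are constrained to at least 25% frame overlap, and a peak NCC below
0.2 (configurable) flags the estimate as low confidence.

Design choices: integer-pixel registration only (drift originates from
stage repositioning and all features are organoid-scale); the pretreatment
frame is the reference (it anchors pretreatment normalization); shifts are
estimated on NAD(P)H only and applied unchanged to the paired FAD frame;
all frames are cropped to the intersection of the shifted frames. Rotation
and scaling are out of scope. Note that when organoids grow between frames
the frame is no longer a pure translation of the reference and the NCC
maximizer can legitimately differ by ±1 px from the stage truth.

## Segmentation

Intensity thresholding is unreliable at signal-to-background ratios of
2–3, so segmentation works on an edge-enhanced image. The 12 steps, in
order: median filter (25×25), Gaussian background estimate (450×450)
subtracted, local standard-deviation filter (13×13), 3-class Otsu of the
edge image with the lowest class discarded (the two upper classes are
merged into foreground), removal of regions < 100 px, hole filling, erosion
with a disk of radius 9, Chan–Vese active-contour refinement (200
iterations, contraction bias −0.6), h-minima watershed splitting of
touching organoids, hole filling, Gaussian edge smoothing (5×5, binary mask
blurred and re-thresholded at 0.5), and a final morphology filter keeping
regions with area > 1000 px and circularity > 0.4.

Numerical choices:

* Gaussian "kernel size k" is interpreted as a filter of size k with
  σ = k/4 (the standard 2σ truncation).
* The active contour is the morphological Chan–Vese scheme, initialized
  from the eroded mask of step 7 and evolved on the background-subtracted
  image of step 2. The negative contraction bias (contour tends to grow
  back to the organoid boundary after the erosion) is implemented by
  down-weighting the inside-region energy term: λ_inside = 1 + bias = 0.4,
  λ_outside = 1.
* The watershed runs on the negated Euclidean distance transform after
  suppressing minima shallower than `hmin_depth` (default 5 px, exposed in
  `SegmentationParams`; the depth is not dictated by the procedure itself
  and 5 px suppresses spurious minima at the organoid scale used here).
  Split labels exactly partition the input foreground.
* Circularity is 4πA/P² clipped to ≤ 1, with the perimeter P measured as
  the length of the convex hull of the region's pixel corner points. This
  estimator is exact for convex shapes (a 10×10 square gives P = 40 and
  circularity π/4; a 2×50 bar gives P = 104 and circularity ≈ 0.116; a
  rasterized disk tends to 1) and is insensitive to single-pixel boundary
  noise, so results are bit-stable across runs. For strongly concave
  regions it underestimates the true boundary length; segmented organoids
  are near-convex by construction of the morphology filter.
* Connectivity is 8-connected throughout.
* A final contrast guard requires each retained region to be brighter than
  the background by at least `min_region_contrast` (default 1.0) robust
  standard deviations of the background-subtracted image. Otsu
  thresholding is scale-free, so a frame containing no organoids at all
  would otherwise segment percolating noise structure; real organoids
  exceed this floor by two orders of magnitude at SBR 2–3.
* Kernel sizes refer to the 2048-px acquisition frame. In the default
  `scaled` mode the spatial kernels shrink proportionally for smaller
  images (with a log line) while the area/circularity selection thresholds
  stay fixed; `strict` mode refuses images smaller than the background
  kernel. The working scale used throughout the tests is 512×512 with
  organoid radii 25–60 px, a 4× downscale that keeps full-pipeline tests
  in minutes on one CPU while organoid areas (≈2000–11000 px) remain well
  above the 1000 px selection threshold.

Validation: mean Sørensen–Dice coefficient against ground truth over 20
seeded phantoms at SBR ∈ [2, 3] is computed by the acceptance script; the
per-frame organoid count error is at most 1.

## Tracking

Segmented organoids are reduced to unweighted centroids per labeled region
and linked by a two-pass linear-assignment approach: (1) frame-to-frame
matching minimizing total squared displacement, where each unlinked
detection costs `max_link_dist²` (the standard augmented-matrix LAP
construction, solved exactly), so a link forms only if it is cheaper than
abandoning both endpoints; (2) gap closing joins track ends to later track
starts within `max_gap_dist` and at most `max_gap_frames` skipped frames,
by a second assignment pass. Defaults: 200 px / 200 px / 2 frames.

Rendering centroids as Gaussian blobs and re-detecting them with a
difference-of-Gaussian detector — a device used when feeding an external
tracker — is lossless for synthetic blobs placed at their own centers, so
the linker consumes centroids directly. Cost is squared Euclidean distance;
ties are broken by smaller distance, then smaller source label, making the
output deterministic. Splits and merges are not modelled (a merge in the
data shows up as a lost identity in the truth-matching metric, not as a
branched track). No motion model is used; organoid drift is slow relative
to spacing.

On instances small enough to enumerate (≤ 6 detections/frame), the
assignment equals the exhaustive minimum-cost matching; this is asserted in
the test suite against a brute-force oracle.

## Quantification

Each (track, frame) node yields exactly 24 variables. Intensity statistics
are computed over the raw registered pixels inside the mask. Morphology
uses standard region-property conventions: solidity = area / convex area;
extent = area / bounding-box area; eccentricity and axis lengths from the
same-second-moment ellipse; equivalent diameter = √(4A/π); Feret diameters
by rotating calipers on the convex hull of pixel corner points (so a 5×20
rectangle has max Feret √(20² + 5²) ≈ 20.6 and min Feret 5; corner-based
calipers can exceed the ideal continuous value by up to ~√2 px for curved
shapes). Units are pixels; the acquisition pixel pitch (1.625 µm/px) is
provided as a constant for optional physical conversion.

Border rule: an organoid whose mask touches the common-crop border at
*any* time point is excluded entirely — the longitudinal models need
complete per-organoid series, and a clipped frame corrupts both area and
intensity statistics. Exclusions are logged with reason codes.

## Longitudinal statistics

Two normalizations: organoid-level, Y = X_post / X_pre(organoid), which
requires tracking and makes every organoid its own control (pretreatment
value ≡ 1); and well-level, Y = X_post / mean_well(X_pre), which mimics
pooled analysis without tracking. Pretreatment rows are excluded from
modelling (their variance is spent by the normalization); the first
modelled time point is 20 min (0.33 h).

The organoid-level model is

    Y ~ time + treatment + treatment:time + (1 | organoid),  AR(1) errors

with time categorical (no linearity assumption across the unequal 0.33 →
12 → 24 → 36 → 48 h spacing) and the AR(1) correlation applied to the
ordered within-organoid time *index* (the convention of standard
mixed-model implementations for categorical time). The marginal covariance
of one organoid's series is σ_b² J + σ² R(ρ) with R_jk = ρ^|j−k|. The fit
maximizes the REML likelihood over (log γ, atanh ρ), γ = σ_b²/σ², with σ²
profiled out in closed form; blocks are solved by Cholesky factorization
with caching over repeated time patterns, and the optimizer is Nelder–Mead
(xatol 1e-8). This estimator is implemented in-package because the random
intercept and AR(1) residuals must be combined in one marginal covariance;
it is cross-checked in the test suite against an independent reference
implementation (R nlme) and agrees to ≤ 1e-4 on fixed effects and variance
components. The pooled model is the identical machinery with σ_b² fixed at
zero (GLS with AR(1) errors).

Inference: least-squares means per treatment × time cell (for this
saturated two-way design they equal the model's cell predictions); all
pairwise treatment differences within each time point, with Tukey HSD
adjustment via the studentized-range distribution with k = number of
groups. The Tukey family is the set of pairwise comparisons within one
time point; multiplicity across time points is not adjusted, matching the
per-time readout of the contrast heatmaps. Degrees of freedom for
treatment contrasts use the containment-style count n_organoids −
n_groups, since treatment is a between-organoid factor. Percent
differences are differences of normalized means × 100. Simulation
calibration at the study scale (15 organoids/group, intercept sd 0.1,
ρ = 0.5, σ = 0.05) shows effect-estimate bias below 10% of the effect,
confidence-interval coverage within [90%, 99%], and type-I error
consistent with the nominal 5% (asserted in the acceptance tests).

Bivariate relationships (e.g. area vs mean ORR pretreatment) use OLS with
Pearson r and the two-sided slope p-value. The 24×24 pretreatment
correlation matrix reports pairwise Pearson r with an unadjusted p < 0.05
significance mask; constant columns are masked and logged.

## Multivariate analysis

Variables are z-scored within each time point (each time point uses its
own mean and sd — including at 24/48 h — while the loadings stay
pretreatment; this composition is fixed). Loadings come from the SVD of
the centered standardized pretreatment matrix, i.e. eigenvectors of the
sample correlation structure; the retained component count is
min(rows − 1, variables); the sign convention makes each component's
largest-magnitude entry positive. Post-treatment data are projected
through the pretreatment loadings. The top-12 report ranks variables by
the L2 norm of their (PC1, PC2) loadings, ties broken by name. Group
ellipses are mean + sample covariance at the χ²(2 df, 0.95) radius; groups
with fewer than 3 points are skipped. The biplot scale factor is
max|loading| / max|score|.

## Phantom generator

The generator emulates the study conditions: 512×512 two-channel frames
(a 4× downscaled stand-in for the 2048×2048 camera frame), six time points
at {0, 0.33, 12, 24, 36, 48} h, 6–10 organoids per well with radii
25–60 px placed without overlap (largest first, rejection sampling), SBR
drawn per organoid from U[2, 3], a global integer stage drift per frame
(default 2 px/step), and per-pixel noise with a Gaussian read component
(σ = 5 AU on a background of 100 AU) plus an intensity-proportional shot
term (variance = intensity), a realistic sCMOS-like model; only the SBR is
a controlled quantity, as the noise of the real instrument is not
characterized beyond that ratio.

Organoid outlines are disks perturbed by radial Fourier harmonics k = 2–4
with amplitudes ≤ 7% (irregular but blobby; circularity stays well above
0.4). Two phenotypes reproduce the solid/hollow dichotomy of colorectal
organoid cultures: solid organoids have a flavin-rich core (core ORR 0.5 <
rim ORR 0.7), hollow organoids the reverse (core 0.78 > rim 0.60) plus a
15% brighter NAD(P)H-driven total intensity; the default hollow fraction
is 19%. Channel intensities are constructed so the noise-free pixel ORR
equals the target profile exactly, and the truth table stores the
per-organoid mean of that profile.

Treatment trajectories multiply the baseline ORR and area per time point:
control has ORR multiplier ≡ 1 and area reaching +10% at 48 h (the
reported control growth); cyanide shows the transient ORR spike at 20 min
characteristic of electron-transport-chain inhibition, then declines below
1; 2DG declines from 12 h; cisplatin responds late (ORR and area deficits
only at 48 h); paclitaxel keeps growing to 24 h before falling behind
control. Both trajectories can be overridden per config
(`growth_model` / `orr_model`).

What the phantom does **not** emulate: optical point-spread/scattering
blur, 3D structure and defocus, Matrigel autofluorescence texture (the
background is flat), organoid birth/death/merging, intra-organoid texture
beyond the radial core/rim profile, and sub-pixel drift. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under controlled conditions — not performance on real microscope data,
where background structure and touching organoids are harsher.

## Problem sizes and determinism

All simulations are seeded (`numpy.random.default_rng`); identical config
and seed reproduce bit-identical images, truth tables and CSV outputs. The
test suite and acceptance script use 512×512 phantoms (20 frames for the
segmentation benchmark), 200 replicate fits for mixed-model bias/coverage,
500 for the null type-I check, and 50 replicates for the
sensitivity-ordering comparison — sizes chosen to keep Monte-Carlo error
well below the margins being asserted while running in minutes on one CPU.

## Known limitations

* Integer-pixel registration; sub-pixel drift aliases into a ±1 px shift.
* The circularity/perimeter estimator is convex-hull based and lenient for
  concave regions.
* The mixed model assumes equal AR(1) index spacing despite the unequal
  hour spacing of the schedule; this follows the cited convention but is a
  modelling choice.
* Contrast degrees of freedom are containment-style, not Satterthwaite or
  Kenward–Roger; at very small group counts the Tukey adjustment is
  approximate.
* Track merges/splits are not modelled; merged segmentations surface as
  identity errors in the truth-matching metric.
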