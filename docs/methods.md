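# Methods

## The measurement problem

Cytoplasmic lipid droplets stained with a lipophilic fluorophore (Nile Red)
appear as bright, near-circular blobs on a dark background, 0.5–8 µm in
diameter. Peak staining intensity increases with droplet size — a larger
droplet is more hydrophobic and takes up more dye — so any analysis that
fixes a single global brightness/contrast window trades the small class
against the large class: a window bright enough to keep dim sub-2-µm
droplets causes neighbouring large droplets to merge into single saturated
regions, and a window that keeps large droplets separated drops the small
ones below threshold. Nuclei (DAPI) are diffuse elliptical blobs, one per
cell, used to normalise droplet counts per cell.

## Droplet pipeline

**Normalisation.** Images are converted to greyscale (BT.709 luminance for
RGB) and divided by the container's nominal maximum (255 or 65535), never by
the observed maximum, so intensities are comparable across images of an
experiment. Calibration (µm/px) is a required user input; size classes are
physical, so it is never guessed from metadata.

**CLAHE.** Contrast-limited adaptive histogram equalization with clip limit
0.03 (fraction of per-tile histogram mass) on an 8×8 tile grid, tile
mappings interpolated bilinearly (`skimage.exposure.equalize_adapthist`).
The local equalization is what removes the size–brightness coupling: each
droplet is stretched against its own neighbourhood rather than the global
range. The tile grid is configurable; 8×8 is the common default for this
clip-limit convention.

**Detection.** Multi-scale Laplacian of Gaussian on the equalized image.
The scale-normalised response −σ²∇²(G_σ∗I) of a bright disk of radius R
peaks at σ = R/√2. Scales are spaced geometrically over the configured
diameter range (default 0.4–10 µm, 10 scales); 3-D local maxima of the
(scale, row, col) response cube above `response_threshold` become
candidates, with the scale refined by parabolic interpolation in log σ.
Because CLAHE amplifies background noise up to its slope bound
(clip_limit × n_bins ≈ 7.7), the input is pre-smoothed with a σ = 1 px
Gaussian before the cube is built, and the recovered scale is corrected by
subtracting that σ in quadrature — otherwise pixel-scale noise dominates
the finest scales. Duplicates are resolved greedily by descending response
(ties to the larger diameter): a candidate is suppressed when its centre
lies within `overlap_suppression` × (sum of radii) of a kept detection
(default 0.5).

**Response threshold.** Default 0.13. On equalized synthetic scenes at the
validation noise level (σ = 0.02) the two response populations are cleanly
separated: residual noise maxima stay below ≈ 0.12 while the dimmest true
droplets respond above ≈ 0.14. The threshold sits between them; it is
configurable for material with different noise.

**Diameter measurement.** The LoG scale seeds the diameter, but the
reported value is by default re-measured on the *pre-equalization* image as
the half-amplitude radial crossing: annular mean intensity profiles are
computed in 0.5 px bins around the detected centre, and the first radius at
which the profile falls below (peak + background)/2 is the droplet radius
(sub-bin linear interpolation). For a step edge blurred by any symmetric
kernel the half-amplitude point sits exactly at the original edge, so this
measurement is insensitive to focus blur — and, critically, to CLAHE's
nonlinear tone mapping, which amplifies the toe of each edge ramp and would
otherwise dilate apparent diameters by about +2 px at every size.
`refine_diameters=False` restores pure scale-based diameters
(d = 2√2·σ_best).

**Size classes and summary.** Small < 2 µm, large > 3 µm, medium in the
closed band between (boundaries to medium, so the three percentages
partition 100%). Summaries use the sample SD (n−1) and CV% = 100·SD/mean;
aggregates of an empty detection list are undefined (`None`), not zero, as
is the SD of a single droplet. Border-touching droplets are retained.

**Baseline.** `global_contrast_baseline` emulates the manual single-window
workflow: linear stretch of [low, high] to [0, 1] with clipping, a fixed
mid-range threshold, connected-component labeling, equivalent diameters.
It exists to demonstrate the bias, not to analyse data.

## Nuclei pipeline

Gaussian blur (default σ = 2 px) → threshold → external contours
(connected components) → discard components below `min_area_px`
(default 20 px) → one bounding box per survivor, sorted by (row, col).
The original workflow's fixed threshold is unpublished, so the default is
Otsu's method with a numeric override. Touching nuclei merge into one
contour and count once — inherent to contour counting and documented rather
than patched with watershed splitting. A blank (constant) image has no
foreground under the automatic threshold; near-blank noisy images are
outside the counter's design envelope, since Otsu then bisects the noise.

## Synthetic scenes

The generator emulates exactly the features the pipelines key on, with
everything else idealised:

- dark background (default 0.05) with additive Gaussian noise
  (default σ = 0.02) — read noise, not photon statistics;
- droplets as anti-aliased hard disks blurred by a Gaussian
  (`droplet_edge_softness_px`, default 1.0 px, an idealised PSF), peak
  intensity following the affine law base + gain × diameter
  (defaults 0.25 + 0.09/µm, clipped at 1), which encodes the
  brightness–size coupling;
- nuclei as rotated anisotropic Gaussian blobs (σ 8 px, axis ratio ≤ 1.5,
  peak 0.8).

Placement is rejection sampling (10 000 attempts per object before a
diagnostic error) with pairwise droplet separation ≥ sum of radii + 2 px.
Two deliberate extensions of plain random placement:

- `pair_large_gap_px` places large-class droplets in near-touching pairs at
  the minimum legal separation. Clustered large droplets are the
  configuration in which single-window analysis actually loses them
  (merging), so the bias scene family sets this to 2 px; random placement
  at the enforced separations would never merge.
- Nuclei are separated by ≥ 2·(σᵢ + σⱼ) + 4 px, which keeps their
  mid-threshold supports (≈ 1.6 σ, plus counting blur) disjoint — the
  "non-overlapping blobs" condition of the counting benchmark made precise.

What the generator does **not** model: Poisson noise, out-of-focus light,
photobleaching, droplet overlap in depth, irregular droplet shapes, and
cell-shaped spatial organisation. Passing the synthetic benchmarks
demonstrates correctness of the algorithms under the stated image model,
not performance on arbitrary real micrographs; on real data the detection
threshold and nuclei threshold may need adjustment.

## Scoring

Detections are matched to ground truth greedily by ascending centre
distance, one-to-one, within `tol_px` (default 3 px, well under the
enforced separations). Greedy matching equals the optimal assignment on
small instances (checked exhaustively in the tests against
`scipy.optimize.linear_sum_assignment`) and is near-optimal at the enforced
separations generally. Per-class recall is computed on true diameters.

## Validation problem sizes

The validation harnesses in `lipidquant.benchmark` use: 50 scenes of
1–200 droplets at 1024² px for parameter recovery (uniform 0.5–8 µm
diameters, 0.2 µm/px, noise σ 0.02); 20 images of 3–10 binary disks
(6–36 px) at 512² for oracle equivalence and mask round-trip; 100 scenes of
1–30 nuclei at 512² for counting; 4 bimodal paired scenes at 512² swept
with 20 contrast windows (width 0.35, lower bounds 0–0.6) for the bias
study. All are deterministic in the provided seed; derived per-scene seeds
stay below 2³¹.

## Numerical choices and edge cases

- Constant images: CLAHE returns them unchanged; Otsu yields an empty
  foreground.
- Gaussian blur uses reflective boundaries (flux-conserving); σ = 0 is the
  identity.
- Thresholding is strict (`> threshold`).
- Diameters from parabolic interpolation are clamped to the configured
  search range; refinement failures (no half-amplitude crossing) fall back
  to the scale estimate.
- The droplet diameter floor in the generator is 2 px at the scene's
  calibration; the detector rejects configured minima finer than 1 px as
  undetectable.
- CSV values are written with 4 decimals; undefined values are empty
  fields, and re-running a batch on identical inputs is byte-identical.

## Known limitations

Touching nuclei undercount (no watershed). Diameters of droplets near the
2-px floor carry the largest relative error (the half-amplitude profile has
few annuli to average). The LoG detector assumes bright-on-dark circular
objects; elongated or ring-shaped lipid structures are out of scope. The
images-per-minute figure in batch logs is hardware-bound and is reported
but never asserted.
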