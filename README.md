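# lipidquant

Automated quantification of intracellular **lipid droplets** and **cell
nuclei** in two-channel fluorescence micrographs of mammary epithelial cells
(or any comparable cell culture stained with a lipophilic dye such as Nile
Red plus a nuclear stain such as DAPI).

## The problem

Intracellular lipid droplets span roughly 0.5–8 µm in diameter, and their
Nile Red staining intensity *grows with size*: larger droplets are more
hydrophobic and absorb more dye. Under a single global brightness/contrast
setting this couples detectability to size — decrease the contrast and the
dim small droplets vanish; increase it and clustered large droplets merge
into unmeasurable blobs. Manual measurement (adjust contrast, click each
droplet) is therefore both slow and biased toward one end of the size
spectrum.

`lipidquant` replaces the manual workflow with a deterministic pipeline:

1. **Droplet channel** — normalise to [0, 1], apply contrast-limited
   adaptive histogram equalization (CLAHE, clip limit 0.03, 8×8 tiles), then
   detect bright circular blobs with a multi-scale Laplacian-of-Gaussian
   (LoG) filter over a configured diameter range. A blob of radius *R*
   maximises the scale-normalised response −σ²∇²(G_σ∗I) at σ = R/√2; the
   best scale is refined by parabolic interpolation, and each diameter is
   then measured as the half-amplitude radial crossing on the
   *pre-equalization* image (the half-height of a blurred edge sits exactly
   at the true boundary, so the measurement is independent of blur and of
   CLAHE's nonlinear tone mapping).
2. **Size classes** — small < 2 µm, large > 3 µm, medium in between;
   per-image summary with mean diameter, sample SD and
   CV% = 100·SD/mean.
3. **Nuclei channel** — Gaussian blur, threshold (Otsu by default),
   external-contour counting with a small area filter; one bounding box per
   nucleus.
4. **Report** — droplets per cell (image-level ratio n_droplets / n_cells),
   size-class percentages, CSV export, detection-mask and annotated-image
   rendering, batch driver with images-per-minute logging.

A seeded synthetic-scene generator reproduces the size–brightness confound
with known ground truth, and `lipidquant.benchmark` scores the pipeline
against it (precision/recall by greedy centre matching, diameter error,
per-class recall).

## Worked example

```python
from lipidquant import (
    SceneSpec, UniformDiameters, generate_scene, analyze_pair,
)

spec = SceneSpec(
    height_px=384, width_px=384, microns_per_pixel=0.2,
    n_droplets=10, n_nuclei=2,
    diameter_distribution=UniformDiameters(1.0, 6.0),
    noise_sd=0.0, seed=1,
)
droplet_img, nuclei_img, truth = generate_scene(spec)
report = analyze_pair(droplet_img, nuclei_img, image_id="demo")
print(report.n_droplets, report.n_cells, report.droplets_per_cell)
print(f"mean diameter {report.mean_diameter_um:.2f} um, "
      f"CV {report.cv_percent:.1f}%, "
      f"{report.pct_small:.0f}% small / {report.pct_large:.0f}% large")
```

prints

```
10 2 5.0
mean diameter 3.51 um, CV 45.9%, 20% small / 70% large
```

— all 10 generated droplets and both nuclei were found (5 droplets per
cell), and the detected size distribution matches the generating range.

The same pipeline is available from the shell:

```bash
lipidquant simulate --out scenes --seed 1 --n-droplets 50
lipidquant analyze scenes --microns-per-pixel 0.2 --out report.csv
lipidquant count-nuclei scenes/scene_nuclei.tif --annotated-out marked.png
```

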