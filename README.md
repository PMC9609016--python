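# speckleflow

Adaptive analysis-window processing for **Laser Speckle Contrast Imaging
(LSCI)**: contrast estimators, blood-vessel segmentation, and
segmentation-guided contrast recalculation, together with a raw-speckle
phantom simulator so the whole pipeline can be exercised and validated
without access to an imaging setup.

## Who this is for

LSCI visualizes microvascular blood flow with nothing more than a laser
and a camera: moving scatterers blur the speckle pattern during the
exposure, and the local contrast `K = σ/μ` of the raw speckle image maps
that blur — `K ≈ 1` in static tissue, `K → 1/√n` where flow averages `n`
independent speckle realizations. The catch is the analysis window: a
small window (5×5) is noisy, a large one (11×11) mixes vessel and tissue
pixels and destroys the spatial resolution exactly where it matters, at
the vessel boundary. This package is for researchers who want windows
that are *large but pure*: per-pixel analysis windows of variable shape
that only admit pixels from the same statistical population.

## What it implements

* **Traditional estimators** — spatial contrast `sK` (population σ/μ
  over a d×d window), temporal contrast `tK` (one pixel along n frames),
  averaged spatial contrast `asK` (per-pixel mean of `sK` over frames),
  plus affine intensity normalization.
* **Adaptive-window contrast `awK`** — the contrast image is clustered
  by intensity (1-D k-means, k=3: vessel / transition / static); each
  pixel's analysis window keeps only the window pixels connected to it
  through its own cluster (region growing, 8-connectivity).
* **Spatially adaptive `sawK`** — an SLIC-style superpixel reference:
  centers seeded on a regular grid, nudged to the lowest 3×3 gradient,
  iterated assignment with the combined distance `D = dₛ + (M/S)·d_c`
  (contrast difference plus weighted Euclidean proximity). A candidate
  pixel enters the analysis window only if its combined distance to the
  anchor beats its distance to every cluster center. Size maps
  `Zₚ = |Sₚᵈ|` record the pixels each window used.
* **Segmentation** — per-pixel features (sum, max, min, mean, range,
  population std, 32-bin Shannon entropy) over the selected window
  pixels feed a distance-weighted k-NN classifier with stratified
  10-fold cross-validation; segmentations are scored with the Jaccard
  index `JI = TP/(TP+FP+FN)`, optionally restricted to a band around the
  true vessel boundary (the *periphery*, where resolution differences
  show).
* **Contrast recalculation** — a cleaned segmentation (disk-1 closing,
  <25-px area filter, four-direction reconnection) becomes the selection
  reference for a second contrast pass `rK_d`; the multi-scale
  combination `msrK` takes the per-pixel minimum over window sizes
  inside vessels and the maximum in tissue.
* **Phantom simulator** — straight or bifurcated vessels in fully
  developed speckle (iid unit-mean exponential intensities, contrast 1);
  flow modeled as averaging `n_eff` speckle realizations (contrast
  `1/√n_eff`), depth as Gaussian mixing of the dynamic and static fields
  (sigma calibrated to depths 0–1000 μm), with known ground truth.

## Worked example

Segment a deep simulated vessel (depth-blur sigma 8 px ≈ 1000 μm) with
traditional and adaptive feature extraction:

```python
from speckleflow import PhantomSpec, evaluate_phantom

spec = PhantomSpec(height=64, width=64, vessel_width_px=16, n_eff=16,
                   depth_blur_sigma=8.0, n_frames=15, seed=1)
runs = evaluate_phantom(spec, ("traditional", "sawK"),
                        use_anchor_contrast=False)
for name, run in runs.items():
    r = run.report
    print(f"{name:12s} mean CV JI={r.mean_ji:.3f}  periphery JI={r.periphery_ji:.3f}")
print(f"improvement: {runs['sawK'].report.improvement_pct:.1f}%")
```

prints

```
traditional  mean CV JI=0.850  periphery JI=0.772
sawK         mean CV JI=0.885  periphery JI=0.826
improvement: 6.9%
```

i.e. on this phantom the cross-validated Jaccard index in the vessel
periphery rises from 0.77 to 0.83 (a 6.9% relative improvement) when the
seven window statistics are computed over sawK-selected pixels instead
of fixed 5×5 squares.

The same pipeline is available from the shell:

```sh
speckleflow simulate --geometry straight --width-px 16 --depth-sigma 8 \
    --n-eff 16 --frames 15 --seed 1 -o out/
speckleflow segment out/stack.tif out/ground_truth.png \
    --provider sawK -o out/seg.png --report out/report.json
speckleflow recalc out/stack.tif out/seg.png -o out/msrk.tif
speckleflow evaluate out/seg.png out/ground_truth.png --band 5
```

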