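# Methods

This note records the models, parameter choices, and numerical decisions
behind `speckleflow`, and what the simulation-based tests do and do not
demonstrate.

## Speckle model and the phantom simulator

Static tissue is modeled as fully developed, polarized speckle: pixel
intensities are iid unit-mean exponential, so the population contrast
σ/μ is exactly 1. Pixels are statistically independent; real optics
impose a finite speckle/pixel ratio (spatial correlation), but the
algorithms under test operate on window statistics for which the
independent-pixel model keeps every oracle closed-form. Flow is modeled
through `n_eff`, the effective number of independent speckle
realizations averaged during one exposure: a dynamic pixel is the mean
of `n_eff` iid exponentials (a scaled Gamma variate) with population
contrast `1/√n_eff`. `n_eff` is a joint proxy for exposure time and
flow speed; individual exposure times are not separately emulated.

Depth is modeled as diffusion of the dynamic signal through the
overlying layer: the binary vessel mask is Gaussian-blurred with
`depth_blur_sigma` into a weight map `w ∈ [0, 1]` and each pixel
observes `w·dynamic + (1−w)·static`. The calibration used for phantom
depths is

| depth (μm) | 0 | 190 | 310 | 510 | 1000 |
|---|---|---|---|---|---|
| sigma (px) | 0 | 1 | 2 | 4 | 8 |

This is a proxy for scattering, not radiative transport: it reproduces
the operationally relevant effect (vessel contrast converging to tissue
contrast with depth, boundary washout) without modeling photon
migration. Pixel pitch is not fixed, so vessel diameter is specified in
pixels (`vessel_width_px`) rather than μm.

Frames are quantized to 8/12/16 bits with the unit-mean field scaled so
the mean gray level is `mean_gray_fraction` of full range (default
1/8), then rounded and clipped; the clipping rate is stored in the
stack metadata. The default gain is deliberately conservative: because
σ = μ for exponential speckle, a half-range mean would saturate
e⁻² ≈ 13.5% of static pixels and visibly depress the measured static
contrast (to ≈ 0.74), whereas an eighth-range mean keeps the clipping
rate near 3·10⁻⁴ and the unit-contrast law intact — matching how
acquisition gain is set in practice to avoid saturation.

Frames are mutually independent given the seed stream, including the
static background (it is redrawn per frame). Consequently the temporal
contrast of a static pixel is ≈ 1 in this simulator, unlike a real
static speckle field, which is frozen in time and has near-zero temporal
contrast. Temporal-contrast behavior on real data is therefore *not*
validated by these phantoms; spatial and adaptive-window estimators are
unaffected by this simplification.

### Finite-sample estimator bias

All contrast estimators use the population divisor (d², resp. n), as
printed in their defining equations. The window estimator
`K̂ = σ̂/μ̂` is biased low for small samples: for 7×7 windows of
exponential intensities `E[K̂] ≈ 0.970`, and for 15-frame temporal
series ≈ 0.91. Statistical tests of the simulator therefore compare
the empirical mean window contrast against the finite-sample
expectation of the *same estimator*, computed by an independent
Monte-Carlo oracle (fresh RNG, direct iid draws), within three standard
errors — not against the asymptotic population value, which no unbiased
simulator could match at these window sizes. The population values 1
and `1/√n_eff` are additionally asserted at a 5% tolerance consistent
with the known bias.

## Contrast estimators

* Window sizes must be odd; `r = (d−1)/2`. Default border handling is
  reflect padding (output shape = input shape, required for per-pixel
  classification); `valid` mode returns the cropped interior instead.
* Zero-mean windows define `K = 0` (no signal carries no blur
  information; avoids NaN propagation) and are counted in the log.
* Contrast images are clipped to [0, 1] at the end; every estimator
  accepts `clip=False` to expose raw values for statistical work.
* Temporal contrast uses the first `n` frames of the stack.

## Adaptive windowing

* **awK reference**: unsupervised k-means (k = 3 by default: vessel,
  transition, static) on the 1-D contrast values; labels are renumbered
  by ascending cluster-mean contrast so label 0 is reproducibly the most
  dynamic group. Degenerate inputs (fewer distinct values than
  clusters) produce a warning and value-rank labels.
* **sawK reference**: SLIC-style clustering with grid spacing
  `S = √(N/k)` and search window `2S` (regular seeding requires a
  length, not an area). The seed-perturbation gradient is the summed
  squared difference to the four neighbours — unlike a central
  difference it is nonzero on a single-pixel spike, which is precisely
  what the perturbation must avoid. Centers move only on a strict
  gradient decrease. Pixels outside every search region are attached to
  the nearest center by the combined distance. The distance weight is
  `w = M/S` with compactness `M` (default 0.1, scaled to contrast
  values in [0, 1]; the classical SLIC default m ≈ 10 assumes
  color ranges of ~100).
* **Selection rules**: awK selects same-label pixels 8-connected to the
  anchor within the window (diagonal vessel continuity at small
  scales); sawK includes a candidate iff its combined distance to the
  anchor is ≤ its distance to the nearest cluster center, with ties
  included (favours sample size). The two published readings of the
  three-distance rule (own center + nearest other center, or the two
  nearest centers regardless of assignment) yield mathematically the
  same threshold, so both names are accepted.
* `d_max` defaults to 11, the dominant window size observed in adaptive
  size maps away from boundaries; singleton selections yield `K = 0`
  and are counted so users can raise `d_max`.

## Segmentation

* Features: sum, max, min, mean, range, population std, and Shannon
  entropy (base 2) over a 32-bin equal-width histogram spanning the
  frame's global intensity range — fixed binning keeps entropies
  comparable across selections of different size. Statistics are
  computed on raw first-frame intensities within the selected pixels;
  the anchor pixel's contrast value can be appended as an extra feature
  (`use_anchor_contrast`, on by default for general use).
* Classifier: k-NN with inverse-distance weighting (k = 10), features
  z-scored per training fold, stratified 10-fold cross-validation.
  Per-pixel rows from the same image can land in different folds; the
  reported CV scores are therefore within-image generalization, not
  across-acquisition generalization — an evaluation caveat inherited
  by every per-pixel segmentation study without an image-level split.
* Evaluation: Jaccard index with the empty-union convention JI = 1;
  the periphery variant restricts scoring to
  `dilation(gt, r) ⊕ erosion(gt, r)` with band radius 5 px by default.

### The provider-comparison study

The simulation study behind the acceptance checks compares periphery JI
of traditional 5×5 features against awK/sawK-adaptive features on
64×64, 15-frame phantoms with a 16-px vessel at `n_eff = 16`, ten
replicates alternating straight and bifurcated geometry, at depth-blur
sigma 8 px — the deepest calibrated condition, where adaptive selection
has the most to offer. The comparison uses exactly the seven window
statistics for both providers: adding the shared anchor-contrast
feature makes both classifiers nearly equivalent (it is close to
sufficient on its own) and no longer isolates the feature-extraction
method under study. At intermediate depth (sigma 4) the two feature
sets are statistically indistinguishable on these phantoms — the gain
concentrates in the deep regime, qualitatively matching the depth
dependence reported for adaptive processing on real phantom data.
These problem sizes keep the full study under a minute; the directional
conclusion is unchanged at larger image sizes.

## Contrast recalculation

* Cleanup order: disk-1 closing, then removal of 8-connected foreground
  components under 25 px (fewer samples than a 5×5 window), then the
  reconnection sweep. Reconnection relabels a tissue pixel as vessel
  when at least one vessel pixel lies in each of the four axis
  directions; the search extends along the whole row/column by default
  (an adjacent-only search could never fill multi-pixel holes) and can
  be bounded with `reconnect_radius`. The sweep is iterated to its
  fixed point, making it monotone and idempotent. Background holes are
  handled only by reconnection, not blind hole-filling.
* Recalculated contrast `rK_d` applies the awK selection criterion with
  the cleaned segmentation as the reference image.
* `msrK` takes the per-pixel minimum of `rK_d` over scales at vessel
  pixels and the maximum at tissue pixels (default `vessel_low=True`,
  preserving the low contrast at the vessel center and the noise
  suppression outside; the flag flips the branches for the opposite
  mask encoding).

## Known limitations

* No spatial speckle correlation, no physical optics (coherence,
  polarization, speckle/pixel ratio), no photon transport — depth and
  exposure effects are proxies.
* Static background is redrawn per frame (see above): temporal
  estimators are only validated against the simulator's own law.
* Cross-validation without an image-level split (above).
* Passing the phantom studies demonstrates correctness of the
  estimators and the direction of the adaptive-feature effect under the
  stated speckle model; it does not certify effect sizes on in vivo
  data.
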