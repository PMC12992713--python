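# Methods

`fluorad` re-implements, as a tested and reusable pipeline, a test-retest
repeatability analysis of radiomic features in fluorine-19 (¹⁹F) MRI. The
raw scans of such studies are typically not shareable, so the package pairs
the analysis chain with a synthetic acquisition generator that reproduces the
statistical structure the analysis depends on. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
simulation does and does not show about real data.

## The imaging model

¹⁹F MRI is background-free: tissue contains no measurable fluorine, so the
spin-density-weighted signal of a voxel is directly proportional to the local
concentration of ¹⁹F nuclei. The generator renders noiseless images as

    S(v) = gain × c_F(v) × B(v)

where `c_F` is the ¹⁹F nuclei concentration (mM) of the object covering the
voxel and `B` a smooth multiplicative bias field (coil/B1 profile, mean 1).
Partial volume at object boundaries is handled by 3×3×3 subvoxel
supersampling of the object indicator, so boundary voxels carry fractional
intensities — the mechanism that makes digitized shape measurements sensitive
to repositioning.

Magnitude reconstruction of complex Gaussian receiver noise gives Rician
noise: each voxel is replaced by `sqrt((S + g1)² + g2²)` with `g1, g2`
independent zero-mean Gaussians of SD σ. Background voxels then follow a
Rayleigh law with mean σ√(π/2) ≈ 1.2533 σ and SD σ√(2 − π/2) ≈ 0.655 σ; the
tests check both against the closed forms.

No pulse-sequence physics is modeled (no echo trains, k-space, chemical
shift): the analysis consumes magnitude images, and these are the only
properties it uses.

## Study replica

The default study configuration mirrors the design being analyzed:

* **Phantoms.** Two phantoms ("PFPE-like" and "PFCE-like"), each five
  identical cylindrical agarose tubes in a quincunx: two at 244 mM ¹⁹F
  nuclei, two at 118 mM (the 5.8 / 2.8 mM PFPE equivalents), one unloaded
  control. Tubes share one radius (3 mm) and differ only in fill height and
  seating depth by fractions of a millimeter, as hand-filled tubes do.
* **Acquisition.** 64×64×12 grid at 0.55 × 0.55 × 1.5 mm³ voxels. Default
  gain 0.15 intensity/mM and σ = 1 put the low tubes at SNR ≈ 18 and the
  high tubes at SNR ≈ 37 — the study design requires SNR > 5 for robust
  boundary delineation, and the published protocol does not state the
  achieved SNR, so the default is set comfortably above that floor.
* **Trials.** Intrasession pairs re-use the geometry with fresh noise.
  Intersession pairs redraw, per pair, a repositioning perturbation: rigid
  translation (±1 mm/axis) and rotation (±3°/axis) about the FOV center, a
  bias-field amplitude up to 0.1, a global gain drift of ±5%, and a noise
  drift of ±10%. These magnitudes are not published; they were chosen once
  as plausible for re-seating a phantom in a volume coil across days, and
  the retest is re-rendered analytically from the transformed geometry
  (rather than resampling the test image) so that repositioning changes the
  digitization exactly as a re-acquisition would.
* **In-vivo-like arm** (intrasession only, two subjects): a lobed "liver"
  and an ellipsoidal "tumor" whose uptake tapers smoothly to zero at the
  boundary — organ margins, unlike tube walls, sit near the detection
  threshold — plus a hard-walled reference tube at the 5 mM PFPE
  equivalent (≈ 210 mM ¹⁹F). Organs carry internal texture from a smoothed
  multiplicative log-normal field.
* **Scale.** Default trial counts are 8 intrasession + 8 intersession pairs
  per phantom (64 phantom scans, 268 segments in total) — a desk-scale
  replica; the published per-experiment counts are available through the
  manifest module and any counts can be configured.

Every output is a pure function of the configuration and one master seed,
expanded through `numpy.random.SeedSequence` into per-scan noise seeds.

## Segmentation

Pure-noise acquisitions give the per-slice average noise level `N_average`;
a voxel enters the mask iff its intensity is ≥ k × N_average of its slice
(k = 3, ties kept). For Rayleigh background noise, 3 × mean ≈ 5.7 × SD, so
the k = 3 rule indeed exceeds a five-SD floor — verified for the simulated
noise model; on a scanner this is an empirical claim about the measured
noise. Thresholding is idempotent and anti-monotone in k (property-tested).

The manual delineation step of the original workflow is replaced by
assigning 26-connected mask components to the nearest known region prior
(tube or organ center), dropping speckle components below 5 voxels and
components farther than 6 mm from every prior — the automated stand-in for
an observer excluding artifact voxels. Priors with no matching component are
recorded as missing segments and excluded pairwise downstream, never
imputed. A seeded boundary-jitter operator (`reader_perturb`) simulates
re-delineation for reader-agreement (ICC) harnesses.

## Feature engine

Features follow the standard radiomics reference definitions.

* **Filters** (whole-image, before extraction): original; square,
  square-root, logarithm, exponential with the reference range-normalizing
  constants (documented in `features/filters.py`); gradient magnitude over
  physical spacing; scale-normalized (σ²-weighted) Laplacian-of-Gaussian at
  σ ∈ {1, 2, 3} mm; one-level undecimated separable Haar wavelet, all 8
  L/H subbands. The default bank is 17 filter images. Local-binary-pattern
  filters are out of scope.
* **Discretization:** fixed bin count (32) over the ROI range by default —
  robust for filtered images with shifted ranges; fixed bin width is
  available. A constant ROI collapses to one gray level and is flagged
  degenerate.
* **First order** (18): moments use population (1/n) denominators; kurtosis
  is not excess-corrected; entropy/uniformity use the discretized histogram
  (log₂).
* **Shape** (14, original filter only): mesh volume and surface area come
  from a marching-cubes isosurface honoring the anisotropic spacing. The
  surface is extracted from the signed Euclidean distance field of the mask
  refined 4× by tricubic interpolation: meshing the binary mask directly
  chamfers sharp voxel edges and biases the area of box-like segments low
  by ~3% (a 20³ cube's sphericity lands ~2.8% above the closed form); the
  refined distance field keeps faces in place, tightens the chamfer to
  ~2%, and leaves smooth boundaries essentially unchanged (digitized-ball
  sphericity still approaches 1 from below). Axis lengths use the inertia
  spectrum of the physical voxel centers (length = 4√λ); a single-voxel
  segment falls back to the voxel's own extents. No resampling to isotropic
  voxels anywhere: all physical quantities use the anisotropic spacing.
* **Texture** (75): GLCM (24), GLRLM (16), GLSZM (16), GLDM (14),
  NGTDM (5). GLCM/GLRLM are computed per distance-1 direction over the 13
  unique 3D lattice directions and features are averaged over directions
  (not merged matrices). GLSZM zones are 26-connected; GLDM dependence
  counts the center voxel plus 26-neighbors within level difference α = 0.
  Every matrix builder is verified against an independent brute-force
  enumeration oracle on an exhaustive randomized sweep of small ROIs.

The full default table is 17 × 93 + 14 = 1,595 features per segment, named
`<filter>_<class>_<name>`. The feature count is configuration-dependent by
design; the exact configuration of any one published study (σ levels, bin
settings, excluded features) lives in supplements that are not always
available, so defaults are declared here rather than inferred.

## Agreement statistics

For each feature, test/retest values are paired per segment and pooled
across scans and concentrations within an experiment arm:

* **CCC** `= 2σ₁₂ / (σ₁² + σ₂² + (μ₁ − μ₂)²)` with population moments
  (Lin's sample form, no bias-correction term — matching the printed
  formula). Identical constant vectors score 1; other zero-denominator
  cases are flagged degenerate.
* **NDR** `= 1 − (1/n) Σ |Test − Retest| / (Max − Min)` with Max/Min pooled
  over test ∪ retest. Zero range makes NDR undefined: the feature fails the
  criterion and is flagged, never imputed.
* **Stability:** CCC ≥ 0.85 and NDR ≥ 0.90, boundaries inclusive,
  thresholds configurable; a sensitivity grid over CCC ∈ [0.75, 0.90] ×
  NDR ∈ [0.85, 0.95] is provided and is monotone by construction.
* **Bland–Altman** limits of agreement plus a reference band
  ±1.96·√(2·s̄²·(1 − CCC₀)) — the envelope for differences of an
  equal-variance, zero-bias pair at concordance CCC₀ (under those
  assumptions CCC reduces to the Pearson correlation and
  Var(x−y) = 2σ²(1−ρ)). The literature construction this band follows is
  cited, not printed, in the source study; the equal-variance zero-bias
  reduction is this package's declared choice, Monte-Carlo-checked for 95%
  coverage under its own assumptions.
* **Reader ICC:** two-way random effects, absolute agreement, single
  measurement (ICC(2,1)) — the variant is not stated in the source study,
  so this default is declared; it is cross-checked against pingouin in the
  tests.
* **Histogram normalization check:** Jensen–Shannon divergence (base 2)
  between test/retest intensity histograms per segment, before and after
  per-scan z-standardization, reported as the relative change in mean JSD.
* **Group comparisons:** Shapiro–Wilk normality gate, Kruskal–Wallis across
  strata, class-vs-pool two-sample rank tests with Benjamini–Hochberg
  adjustment over the declared family. The class-vs-overall comparison
  pools overlapping sets (the class is part of the pool); this caveat is
  inherited from the design being reproduced.

Degenerate (zero-range/zero-variance) features are reported and excluded
from medians and IQRs.

## What passing tests do and do not show

The generator reproduces the *mechanisms* the analysis probes — noise-only
intrasession variation; repositioning-driven digitization, bias-field and
gain changes intersession; near-threshold organ boundaries in vivo — and the
simulated study reproduces the qualitative orderings reported for such
designs: intrasession median CCC above intersession overall and per class,
intensity features most repeatable in every phantom arm, shape features
collapsing to zero stable features under repositioning while ≈ 30% of
intensity features stay stable. The headline numeric values of any real
study (e.g. its exact median CCCs or stable-feature counts) depend on
scanner hardware, coil loading, and true trial counts, and are not
reproduced at desk scale; numbers computed here characterize the simulation
only. Real-data effects that are deliberately absent: echo-train blurring,
chemical-shift ghosts of multi-peak agents, motion, sedimentation drift,
observer variability beyond the modeled boundary jitter.

## Numerical notes

* Moments and CCC use 1/n denominators throughout; Bland–Altman SD of
  differences uses n−1 (conventional for limits of agreement).
* Log/entropy terms use log₂ with zero-probability terms dropped.
* Threshold ties: "≥" keeps the voxel. Stability boundaries: "≥" passes.
* Exact-zero voxels are excluded from segmentation masks in the pipeline —
  in a background-free modality a measured magnitude of exactly zero never
  occurs with noise, and this keeps the noiseless (σ = 0) limit well posed.
* GLCM correlation of a single-level matrix is defined as 1; InverseVariance
  sums off-diagonal cells only; MCC takes the square root of the
  second-largest eigenvalue of the level-coupling matrix restricted to
  levels present.
* The detection-limit calibration flags the floor as the smallest
  concentration whose mean ROI intensity exceeds five times the SD of the
  background magnitude noise.
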