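# fluorad

Repeatability analysis of radiomic features in fluorine-19 (¹⁹F) MRI.

¹⁹F MRI is a background-free molecular imaging modality: tissue contains no
measurable fluorine, so the magnitude signal is directly proportional to the
concentration of ¹⁹F nuclei delivered by a perfluorocarbon tracer (PFPE,
PFCE, ...). Before radiomic descriptors of ¹⁹F images — intensity
statistics, 3D shape, gray-level texture — can be used as quantitative
biomarkers, one has to know which of them survive a test-retest: a repeat
scan in the same session (noise only) or days later with repositioning.
`fluorad` implements that analysis end to end, and, because raw scans from
such studies are rarely public, ships a seeded synthetic generator of
phantom, in-vivo-like, and pure-noise acquisitions with the statistical
structure the analysis assumes (signal linear in concentration, Rician
magnitude noise, session perturbations).

The pipeline is:

1. **simulate** — agarose-tube phantoms (two ¹⁹F loads, 244/118 mM nuclei,
   plus an unloaded control) and a liver/tumor/reference-tube scene on a
   64×64 matrix at 0.55 × 0.55 × 1.5 mm³ voxels, with intrasession and
   intersession (repositioning + bias-field/gain/noise drift) retests;
2. **segment** — per-slice noise level *N*<sub>average</sub> from pure-noise
   scans, mask at intensity ≥ 3 × *N*<sub>average</sub>, connected
   components assigned to region priors;
3. **extract** — a from-scratch radiomic engine: 8 filter types, 18
   first-order, 14 shape, and 75 texture features (GLCM, GLRLM, GLSZM,
   GLDM, NGTDM), 1,595 features per segment with the default filter bank;
4. **agree** — per-feature concordance correlation coefficient

   CCC = 2σ₁₂ / (σ₁² + σ₂² + (μ₁ − μ₂)²)

   and normalized dynamic range

   NDR = 1 − (1/n) Σᵢ |Testᵢ − Retestᵢ| / (Max − Min),

   with a feature called **stable** when CCC ≥ 0.85 and NDR ≥ 0.90;
5. **report** — class/filter strata, stable-set intersections across
   experiments, threshold-sensitivity grids, Bland–Altman, reader ICC, and
   Jensen–Shannon histogram checks.

## Worked example

```python
from fluorad import synthdata as sd, segmentation as seg, agreement as ag
from fluorad.features import extract_all, FeatureConfig

spec = sd.default_phantom()                       # 5 tubes: 2×244, 2×118, 1×0 mM
acq = sd.default_acquisition()                    # 64×64×12, sigma=1, gain=0.15
test, retest = sd.simulate_test_retest(spec, acq, "intrasession", seeds=(11, 12))

profile = seg.estimate_noise(sd.acquire_noise_scan(acq, 13))
priors = [seg.RegionPrior(t.center, f"tube{i+1}")
          for i, t in enumerate(spec.tubes) if t.f19_mm > 0]
masks = [seg.delineate_rois(seg.threshold_mask(v, profile), priors, acq.spacing)
         for v in (test, retest)]

cfg = FeatureConfig()                             # original filter only: 107 features
ft, fr = (extract_all(v, m, cfg) for v, m in zip((test, retest), masks))
res = ag.evaluate_features(ft, fr)
print(res.loc[["original_firstorder_Mean", "original_shape_MeshVolume",
               "original_glcm_Contrast"]].round(4))
print("stable:", int(res["stable"].sum()), "/", len(res))
```

prints

```
                              ccc     ndr  stable  n  degenerate
feature
original_firstorder_Mean   1.0000  0.9981    True  4       False
original_shape_MeshVolume  0.9991  0.9858    True  4       False
original_glcm_Contrast     0.9566  0.9265    True  4       False
stable: 75 / 107
```

Mean tube intensity reproduces almost perfectly across the intrasession
retest (CCC = 1.000: the two ¹⁹F loads separate the four tubes far beyond
the noise), mesh volume and GLCM contrast slightly less so, and 75 of the
107 original-filter features meet both stability thresholds in this single
noise-only pair. A full study — both phantoms, intrasession and
intersession arms, the in-vivo-like scene, all filters — runs through
`fluorad.pipeline.run_study` (or `fluorad run-all --out DIR --seed 1` on
the command line, which writes the manifest, per-arm agreement tables,
class-median summaries, stable counts, and intersection report as
CSV/JSON).

In a full run, intersession repeatability drops well below intrasession in
every feature class, intensity features stay the most repeatable arm for
arm, and no shape feature survives the repositioning perturbations at the
default magnitudes — the geometry of small digitized objects is the most
fragile thing on the table.

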