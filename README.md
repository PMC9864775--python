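# radiorobust

Robustness analysis of 3D radiomic features under segmentation variability,
with a synthetic CT phantom cohort.

Radiomic features — shape descriptors, intensity-histogram statistics and
gray-level texture matrices computed over a lesion's 3D region of interest —
are only useful clinically if they survive the operator-dependent step of
drawing that region. `radiorobust` is a tested, reusable pipeline for
quantifying this: it extracts 851 IBSI-style features (107 on the original
image, 93 on each of 8 coiflet-1 wavelet sub-bands) under a factorial grid
of preprocessing parameters (gray-level bin width W ∈ {10, 20, 40}, texture
pixel distance d ∈ {1, 2, 4}, interpolator ∈ {nearest, linear, B-spline},
isotropic resolution ∈ {1, 2, 2.5} mm), and evaluates per-feature agreement
across three segmentation styles of the same lesion — an accurate free-hand
contour, a rough free-hand contour, and a rough per-slice polygon, the
rough ones deliberately including surrounding tissue.

Agreement is measured by the two-way random-effects, absolute-agreement,
single-measure intraclass correlation coefficient,

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

over n patients and k = 3 segmentation styles, with the lower bound of its
95% confidence interval as the robustness statistic (excellent when
> 0.9). Sensitivity of a feature to one preprocessing parameter is the
worst-case range of that lower bound as the parameter varies with the
others fixed (< 0.1 = low). Per-patient dispersion uses the coefficient of
variation CV = SD/mean across the three segmentations, rank-correlated
(Spearman) with lesion volume.

Because real patient CTs cannot ship with a package, a first-class
synthetic module generates a phantom cohort — ellipsoidal lesions with
spatially correlated texture on anisotropic CT-like grids, three
segmentations each — so the entire pipeline is testable end to end from a
single seed. See `docs/methods.md` for the generator's model and its
limits.

## Worked example

```python
from radiorobust import PhantomSpec, SegmentationStyle, generate_phantom, generate_segmentation
from radiorobust.features import extract_all
from radiorobust.preprocessing import ExtractionConfig

spec = PhantomSpec()                      # 64x64x48 grid, 0.75x0.75x1.25 mm
volume = generate_phantom(spec)
mask = generate_segmentation(spec, SegmentationStyle.ACCURATE_FREEHAND, seed=0)
fv = extract_all(volume, mask, ExtractionConfig(bin_width=20, pixel_distance=1,
                                                interpolator="linear", resolution_mm=2.0))
print(len(fv))                            # 851
print(round(fv["original_shape_Sphericity"], 3))      # 0.935
print(round(fv["original_glcm_Contrast"], 3))         # 17.136
```

`original_shape_Sphericity` near 1 says the digitized ellipsoid is nearly
spherical; `original_glcm_Contrast` ≈ 17 reflects the lesion's correlated
texture discretized at bin width 20 (a constant region would give 0).

The same analysis at cohort scale, from the shell:

```bash
radiorobust simulate --n 48 --seed 0 --out cohort/
radiorobust extract --cohort cohort/ --grid 'bin_width=20;pixel_distance=1;interpolator=linear;resolution_mm=2' --out features/
radiorobust analyze --features features/ --out analysis/
# or everything at once from a YAML config:
radiorobust run-all --config experiment.yaml
```

`analysis/icc.csv` then holds one row per (config, feature) with the ICC,
its 95% CI, the ANOVA mean squares and the excellence flag;
`sensitivity.csv` one row per (feature, parameter) with the worst-case
lower-bound range; `cv_correlation.csv` one row per feature with Spearman's
rho of CV against lesion volume.

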