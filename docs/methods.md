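# Methods

`radiorobust` quantifies how robust 3D radiomic features are to the way a
lesion is segmented, and how sensitive that robustness is to the
preprocessing choices made before feature computation. This note records the
models, conventions and numerical choices the package implements, and what
its synthetic cohort does and does not emulate.

## Problem setting

Given a CT-like scalar volume and three binary 3D segmentations of the same
lesion — one drawn as accurately as possible, one rough free-hand contour,
and one rough per-slice polygon, the latter two deliberately including some
surrounding tissue — 851 features are extracted per segmentation under a
factorial grid of preprocessing parameters. Agreement of each feature across
the three segmentation styles is measured by an intraclass correlation
coefficient over the patient cohort; robustness is judged by the lower bound
of its 95% confidence interval.

## Feature set

107 features are computed on the original image and 93 (all but shape) on
each of 8 wavelet sub-bands: 107 + 93 × 8 = 851.

| family      | count | matrix / basis |
|-------------|------:|----------------|
| shape       | 14    | marching-cubes mesh + voxel-coordinate PCA |
| first-order | 18    | raw intensities + fixed-bin-width histogram |
| GLCM        | 24    | symmetric co-occurrence, 13 directions, offset = distance × unit direction |
| GLRLM       | 16    | run lengths, 13 directions |
| GLSZM       | 16    | 26-connected equal-level zones (direction-free) |
| NGTDM       | 5     | neighbourhood gray-tone difference, Chebyshev ball |
| GLDM        | 14    | gray-level dependence, Chebyshev ball, α = 0 |

Feature definitions follow the IBSI-consistent formulations in widespread
use. Directional families compute each feature per direction and average the
feature values (not the matrices); both conventions exist in the literature
and give different numbers, so the choice is fixed here and mirrored by the
brute-force oracles in the test suite.

Conventions that matter for reproducibility:

- **Discretization** is fixed-bin-size, anchored at the in-mask minimum:
  `level = floor((x − min)/W) + 1`. It is therefore invariant to adding a
  constant to all in-mask intensities. Each wavelet sub-band is re-anchored
  at its own in-mask minimum.
- **GLDM dependence index**: the matrix's second index is the number of
  dependent neighbours plus one (the centre voxel depends on itself), so the
  index is ≥ 1 and small-dependence emphasis is always defined.
- **Degenerate regions** (single occupied gray level): GLCM Correlation,
  Imc1, Imc2 and MCC are defined as 1 (perfect-dependence limit); NGTDM
  Coarseness is capped at 1e6 when its denominator vanishes; Busyness and
  Strength are 0 when theirs do; Skewness and Kurtosis of a zero-variance
  region are 0. All features therefore stay numeric, which the downstream
  agreement analysis requires.
- **Kurtosis** is uncorrected (a Gaussian gives ≈ 3); percentiles use linear
  interpolation; first-order Variance is the population variance.
- **Shape**: mesh volume and surface area come from a marching-cubes surface
  at level 0.5 of the binary mask, after Gaussian pre-smoothing with
  σ = 0.5 voxel. Without smoothing the stair-stepped surface of a binary
  mask overestimates area by 7–9% (a digitized sphere's sphericity reads
  ≈ 0.92 instead of ≈ 1); with σ = 0.5 sphericity of a 15 mm digitized
  sphere is ≈ 0.96 while mesh volume stays within a few percent. Axis
  lengths are `4·sqrt(λ)` from the eigenvalues of the covariance of in-mask
  voxel-centre physical coordinates; maximum 2D diameters are per-slice
  maxima of pairwise boundary-voxel-centre distances in each orthogonal
  plane family.

## Preprocessing axes

- **Resolution / interpolator**: volume and mask are resampled to an
  isotropic grid (defaults 1.0, 2.0, 2.5 mm) with nearest-neighbour,
  trilinear, or cubic B-spline (order 3) interpolation. The mask is always
  resampled nearest-neighbour and stays binary. Out-of-domain voxels take
  the volume's minimum (background) intensity; the mask's take 0.
- **Bin width**: defaults 10, 20, 40 intensity units.
- **Pixel distance**: defaults 1, 2, 4 voxels (Chebyshev).
- **Wavelet**: single-level, separable, undecimated coiflet-1 decomposition
  with symmetric (mirror) boundary handling, applied along each axis with
  the low or high decomposition filter in all 2³ combinations. Sub-bands
  keep the input shape, so masks apply without re-registration. The pipeline
  order is resample → wavelet → discretize per sub-band; applying the
  wavelet after resampling keeps sub-band voxel grids identical across the
  resolution axis of the study.

## Agreement statistics

- **ICC model**: two-way random effects, absolute agreement, single measure
  — ICC(A,1) (McGraw & Wong), equivalently ICC(2,1) (Shrout & Fleiss) —
  with segmentation styles as the rater factor:
  `ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`.
  The 95% interval uses the F-based construction with Satterthwaite degrees
  of freedom. Absolute agreement is the stricter, conventional radiomics
  choice; it penalizes consistent offsets between segmentation styles, which
  matters for interpreting the results (see Limitations). The model label is
  recorded in every output row.
- **Excellence**: a feature is "excellent" when the CI lower bound strictly
  exceeds 0.9.
- **Sensitivity**: for each feature and each grid parameter, the range
  (max − min) of the ICC lower bound across that parameter's values is
  computed within every combination of the other three parameters; the
  worst case (maximum) is reported. A range below 0.1 counts as low. The
  worst-case aggregation is a deliberate choice; mean aggregation would be
  milder.
- **CV**: per patient and feature, the sample SD across the three
  segmentations divided by |mean|; records with |mean| below 1e−8 times the
  feature's cohort-level magnitude are excluded as numerically unstable.
  Per-feature Spearman rank correlation (mid-ranked ties) relates CV to
  lesion size (accurate-mask voxel volume); features with fewer than 3
  usable patients or constant CV are skipped.
- No multiple-testing correction is applied anywhere.

## Synthetic cohort

Each "patient" is an ellipsoidal lesion on an anisotropic grid
(64 × 64 × 48 voxels at 0.75 × 0.75 × 1.25 mm; spacings are chosen exactly
representable in float32 so NIfTI headers round-trip bit-exactly).
Per-patient draws (log-uniform radii 4–15 mm per principal axis — tumour
size distributions are right-skewed, and 15 mm is the largest radius the
grid accommodates with margins; lesion mean 20–80 HU over a −800 HU
background; in-lesion texture = Gaussian-smoothed white noise, correlation
length 3 mm, amplitude 20–60 HU; background parenchyma texture amplitude
50–150 HU; i.i.d. noise SD 5–15 HU) are derived from per-patient sub-seeds
of a single master seed, so the cohort is a pure function of
`(n_patients, master_seed, config)`.

The three segmentation styles:

- *accurate free-hand*: the exact digitized ellipsoid;
- *rough free-hand*: each semi-axis enlarged by a margin plus a smooth
  random radial perturbation (sum of Gaussian bumps on the direction
  sphere, normalized to a peak amplitude of half the margin);
- *rough polygon*: per-slice convex polygons (8–12 sides) whose edges are
  tangent to the margin-expanded elliptical cross-section, so every slice
  circumscribes the accurate cross-section.

The cohort generator scales the margin with lesion size (8% of the
geometric-mean radius, floored at 0.3 mm): a radiologist's "rough" contour
of a surgical-size tumour is a thin rim relative to the tumour, and a fixed
absolute margin on desk-scale phantoms would caricature it (a 2 mm rim
doubles the volume of a 1 cm lesion). With these defaults rough masks are
strict supersets of the accurate mask (guaranteed whenever jitter < margin)
with volumes ≈ 1.2–1.4× the accurate volume.

What the generator does **not** emulate: CT physics (beam hardening,
reconstruction kernels, partial-volume blur at the lesion rim), anatomy
(vessels entering the tumour, pleural attachment, lobulated or spiculated
margins), under-segmentation or slice-to-slice operator inconsistency, and
inter-scanner variability. Passing end-to-end tests therefore demonstrates
the pipeline's internal correctness and the qualitative mechanics of
segmentation-robustness analysis, not quantitative agreement with any real
cohort's per-feature ICC values.

## Problem sizes

Unit and oracle tests use regions of at most 6×6×6 voxels (exhaustively
enumerable) and desk-scale phantoms of 32×32×24. End-to-end checks use a
4-patient cohort over a 2×2×2×2 smoke grid and a 48-patient cohort at one
grid point (bin width 20, distance 1, linear, 2 mm); the full 3×3×3×3 × 48
patient experiment runs through the same code paths via the CLI.

## Known limitations

- Under absolute-agreement ICC, a *consistent* over-segmentation margin is
  indistinguishable from a systematic rater bias, and the k·MSC term in the
  CI lower bound caps the reportable robustness of lesion-size features
  (volume, surface area, diameters) even when their point ICC is ≈ 0.9.
  Within the grid-limited size spread of the synthetic cohort this places
  shape features *below* most texture families in lower-bound terms, because
  phantom texture features inherit strong patient identity from the
  per-patient texture parameter draws. A consistency-type ICC (C,1), which
  forgives consistent offsets, would rank shape features at the top; the
  package deliberately ships the stricter absolute-agreement model and
  records the model label in every output row so the two regimes cannot be
  confused.
- GLSZM zone sizes and NGTDM/GLDM neighbourhood sums use box filters and
  connected-component labelling whose costs grow with the number of occupied
  gray levels; very wide intensity ranges at bin width 10 are the slowest
  configurations.
- Mesh-derived shape features of masks only a few voxels across are
  dominated by discretization; single-voxel masks report mesh features as
  NaN by design.
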