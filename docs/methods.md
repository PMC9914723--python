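# Methods

This note documents the models, conventions and design choices behind
mammotex, in the spirit of the methods documentation of mature scientific
packages: what each stage computes, which knobs matter, what the synthetic
data does and does not emulate, and where the design was genuinely open.

## Phantom model

Each phantom emulates a digitised mediolateral-oblique (MLO) screening
mammogram as a composition of four compartments on an 8-bit canvas
(default side 1024 px, gray 0–255):

- **background** near-black (≈5) with faint low-frequency variation and a
  bright (≈250) rectangular label artifact in a background corner,
  mimicking acquisition tags;
- **breast** a half-ellipse attached to the chest-wall edge (semi-axes
  0.55 and 0.45 of the side), base intensity ≈115 plus smooth
  low-frequency texture (coarse Gaussian grid upsampled by cubic splines,
  amplitude 12) and a gentle falloff toward the skin line;
- **pectoral muscle** a wedge from the top chest-wall corner (width
  0.35 of the side at the top edge, tapering to zero at half height),
  ≈50 gray levels brighter than breast tissue;
- **lesion** (optional) benign: a smooth compact disc with profile
  `(1 − (r/R)²)^1.5`; malignant: a smaller core carrying narrow radial
  spicules (`|cos(nθ/2 + φ)|^10` boundary modulation, default n = 9) with
  a jagged edge and a sharper intensity profile. Separability between the
  two is therefore carried by shape and boundary roughness as well as by
  contrast; lesion contrast (intensity offset, default 90) and spicule
  count are the difficulty dials.

Gaussian noise (default σ = 2 gray levels) and salt-and-pepper noise
(per-pixel replacement by 0 or 255 with probability p/2 each, default
p = 0) are applied last. All randomness flows from one integer seed
(`numpy` Generator); the malignant boundary phase uses a dedicated
sub-stream so that a zero-contrast lesion leaves the image bit-identical
to the lesion-free phantom. Truth masks (background/pectoral/breast,
lesion ⊂ breast) are exact by construction.

Cohorts randomise laterality, lesion radius (4–8 % of the side), centre
(within a zone guaranteed inside the breast and clear of the wedge) and
contrast (default range 60–100; the "easy" benchmark cohort used by the
acceptance checks draws 90–120, its stated high-contrast condition).

**What the phantom does not emulate:** X-ray physics (scatter, beam
hardening), microcalcification clusters, parenchymal fibro-glandular
texture statistics, compression artifacts, or inter-patient anatomy
variation. Passing the recovery benchmarks therefore demonstrates that the
pipeline's machinery is correct and sensitive to lesion-driven texture
differences — not that the same AUCs would be obtained on clinical images.

## Pre-processing

Label removal binarises at a threshold (Otsu by default), applies
morphological opening (disk radius 5) to delete small marks, keeps the
largest connected foreground component as the breast mask (holes filled)
and zeroes everything outside it. The label rectangle, disconnected from
the breast, is thereby eliminated; intensities inside the mask are
untouched.

The five enhancement combinations apply their operators in name order —
smooth (MF), then contrast (CLAHE), then sharpen (USM). The order within
the double combinations is implied only by their names; we follow the
names and record the order per run. Operator defaults (none of them
dictated by the study design, all echoed into run reports):

| parameter | default | meaning |
|---|---|---|
| `median_kernel` | 3 | odd window side of the median filter |
| `clahe_clip` | 0.01 | relative clip limit |
| `clahe_tiles` | 8×8 | local-histogram grid |
| `usm_radius` | 2.0 | Gaussian σ of the blur in `img + amount·(img − blur)` |
| `usm_amount` | 1.0 | sharpening weight |
| `morph_radius` | 5 | opening structuring-element radius |

All neighbourhood operators use reflective edge handling and map [0,255]
into [0,255]. CLAHE is delegated to `skimage.exposure.equalize_adapthist`
and the median filter to `scipy.ndimage`; USM is computed from its
defining formula.

## Segmentation and ROIs

Clustering minimises the within-cluster sum of squared distances
`J = Σ_j Σ_i ||x_i^(j) − c_j||²` over scalar pixel intensities (the
minimal feature consistent with pixel clustering; an (intensity, x, y)
extension point is left open). k = 3 yields the natural
background / breast / pectoral partition. Numerical choices:

- *Lloyd iterations* on the ≤256 distinct intensity values with histogram
  weights; tolerance 1e-4 gray levels, max 100 iterations; J is asserted
  non-increasing.
- *Initialisation*: evenly spaced intensity quantiles, plus the centroids
  of the optimal contiguous 1-D partition (computed exactly by a small
  dynamic programme over prefix sums — optimal 1-D clusters are
  intervals), plus two seeded jittered quantile starts; the best-J Lloyd
  fixed point is kept. The DP start makes the result agree with exhaustive
  partition enumeration on tiny toys, where plain single-start Lloyd can
  stall in a local optimum.
- *Ties* in assignment go to the lower cluster index; an emptied cluster
  is re-seeded at the point farthest from its centroid. Cluster indices
  are reported sorted dark → bright.

The pectoral muscle is the non-background cluster whose connected
component touches the top corner on the chest-wall side (a small corner
window is polled to be robust to single-pixel noise); its component is
zeroed. If no such cluster reaches the corner, nothing is removed and a
warning is raised.

ROIs are square patches (default 128 px at full resolution; the 256-px
benchmark uses 64). Abnormal cases centre on the recorded lesion position,
clipped at the frame border. For normal cases no lesion anchor exists; we
take the centroid of the brightest non-background cluster within the
breast (the densest tissue) and, because that centroid can fall close to
the skin line, shift it minimally to the nearest position whose patch fits
entirely inside breast tissue (euclidean distance transform ≥ half the
patch diagonal), falling back to the deepest breast pixel. Neither the ROI
size nor the normal-tissue rule is canonical in the CAD literature; both
are explicit configuration echoed in reports.

## Texture features

Quantization is *range-relative*: the in-mask [min, max] range is binned
uniformly into Ng levels (default 8), so features are invariant to adding
a constant to all pixels; out-of-mask pixels carry a sentinel and never
form pairs or runs. Displacement d = 1 by default. Ng and d are
configurable and recorded.

**GLCM.** Counts of quantized-level pairs at offset (d, θ), accumulated
symmetrically, for θ ∈ {0°, 45°, 90°, 135°}. The 22-feature set is the
extended Haralick family of the MATLAB-era CAD toolboxes:
autocorrelation, contrast, correlation (two estimators), cluster
prominence, cluster shade, dissimilarity, energy, entropy, homogeneity
(two estimators), maximum probability, sum of squares (variance), sum
average, sum variance, sum entropy, difference variance, difference
entropy, the two information measures of correlation, inverse difference
normalized, and inverse difference moment normalized. Conventions: index
weights are 1-based (i, j ∈ 1..Ng, matching those toolboxes and keeping
the low-gray-level analogues finite); logs are base 2 with 0·log 0 = 0;
the information-measure denominator is max(HX, HY) guarded at 1e-12;
correlation-type features are defined as 0 when a marginal is degenerate;
sum variance is taken about the sum average (not the historical
sum-entropy quirk). The two correlation estimators are algebraically
identical here — as in the original toolboxes — so the correlation filter
will always drop one of them; they are kept as separate named columns for
fidelity to the 22-count convention.

**GLRLM.** Maximal constant-level collinear runs per direction;
out-of-mask pixels break runs. The 11 Galloway/Chu features (SRE, LRE,
GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) are normalized by
the run count Nr; RP divides Nr by the pixels considered; gray level and
run length are 1-based in every weight. The conservation identity
Σ_{i,j} j·r(i,j) = Np holds at all four angles and is tested.

Each feature is computed per angle and averaged over the four angles;
because the angle set is closed under 90° rotation, the averaged features
are exactly invariant to rotating an ROI by 90°, which is used as a test.

## Selection

The correlation filter scans columns in the canonical feature order (the
22 GLCM names then the 11 GLRLM names) and drops a feature whose
|Pearson r| with any already-retained feature exceeds 0.90 — keep-first,
deterministic; "above 0.90" is read as the absolute value since
anticorrelated duplicates are equally redundant. Constant columns
(undefined r) are treated as r = 0 and retained with a warning. In
pipeline mode selection is computed on the training split only, to avoid
leakage; the nine-feature reference preset (GLCM autocorrelation,
contrast, cluster prominence, entropy; GLRLM SRE, LRE, GLN, SRLGE, LRLGE)
bypasses data-driven selection entirely. Per-feature screening uses the
midrank Mann–Whitney AUC, reported orientation-free as max(A, 1−A) with a
direction flag.

## Classification and evaluation

Six learners behind one surface (scikit-learn estimators): RBF-kernel SVM
(C = 1, γ = 1/(p·var)), random forest (500 trees), one-hidden-layer
16-unit MLP, 5-NN, Gaussian naive Bayes, and an unpruned CART tree. SVM,
MLP and k-NN are standardized with training-split statistics inside a
pipeline. All are deterministic under a fixed seed.

The study design states both a 70/30 split and LOOCV without relating
them; we implement LOOCV within the training split for model assessment
and report test-split metrics (a pure-LOOCV path is available via
`loocv_scores`), avoiding leakage while honouring both statements. The
split is stratified at the subject level — paired left/right views (ids
differing only in a trailing l/r) never straddle the split. Positive
class: abnormal for the normal/abnormal task, malign for the
benign/malign task (which uses abnormal cases only).

Metrics follow confusion-table algebra; any zero-denominator ratio is
reported as absent (None), never as 0. AUC comes from continuous
classifier scores via the midrank Mann–Whitney statistic, which tests
verify against exhaustive pair counting and `sklearn.roc_auc_score`. No
multiple-testing correction is applied; reports are descriptive.

## Problem sizes and orchestration

The benchmark conditions used throughout the tests and the acceptance
script are a 120-case cohort (60 normal / 30 benign / 30 malignant) at
image side 256 with 64-px ROIs and lesion contrast 90–120 — the package's
chosen desk-scale configuration; the generator's full-resolution default
(1024, 128-px ROIs) is exercised for geometry and round-trip checks. A
single top-level seed derives all per-stage seeds via `SeedSequence`, and
`pipeline.run_all` writes every stage's parameters and a line-per-event
log next to its artifacts; re-running a saved config reproduces the CSVs
bit-for-bit.

## Known limitations

- Phantom realism as discussed above; reported AUCs characterise the
  pipeline under synthetic conditions, not clinical performance.
- Intensity-only clustering cannot separate a pectoral wedge whose gray
  range coincides with dense tissue; the corner-component rule then
  removes only the connected wedge, or nothing.
- Pectoral removal assumes an MLO-like geometry (wedge at a top corner);
  cranio-caudal views are out of scope.
- 16-bit imagery and DICOM are out of scope; PGM (P2/P5, maxval ≤ 255)
  is the only image format.
- The metadata dialect infers laterality from id parity (odd = left),
  a convention of the emulated database layout, and flips the source's
  bottom-left-origin y coordinate on ingest (`y = height − 1 − y_file`).
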