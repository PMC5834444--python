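# Methods

`petavid` implements a whole-body FDG-PET processing chain that turns a raw
activity image into a set of labelled high-uptake regions: SUV quantification,
isotropic resampling, Gaussian smoothing, SUV thresholding, watershed
segmentation, radiomics feature extraction, and random-forest tissue
classification under a per-scan sole-occurrence constraint. A synthetic
phantom generator provides ground-truthed scans so that every stage is
testable without patient data. This note records the model, the parameters
that matter, and the design choices made where the design was genuinely open.

## SUV quantification

Activity `C(x,y,z)` (Bq/mL) is converted to the body-weight standard uptake
value

    SUV = C / 2^(-t / T_half) * W / D        [g/mL]

with body weight `W` in grams, injected dose `D` in Bq, injection-to-scan
time `t` in minutes and half-life `T_half` (default F-18, 109.77 min). The
division by the decay factor corrects the measured activity back to injection
time; the ratio `W/D` normalises by injected dose per gram of tissue. Weight
in kg and dose in MBq are converted at the I/O layer. Lean-body-mass and
body-surface-area SUV variants are out of scope.

## Resampling, smoothing, thresholding

Scanner grids are anisotropic and inconsistent across scans, so volumes are
resampled to an isotropic 5 mm grid with cubic spline interpolation
(voxel-centre convention, physical position = origin + index x spacing;
negative spline overshoot clamped to 0). The SUV image is then smoothed with
a normalised isotropic 3-D Gaussian — sigma = 1 voxel (5 mm), support
truncated at 4 sigma — and thresholded inclusively at SUV >= 3 to produce the
high-uptake mask. The smoothed volume, not the raw one, is the substrate for
thresholding, watershed and feature sampling, keeping all downstream stages
consistent with one another.

The normalised Gaussian (sigma^2 in the exponent, (2 pi)^{3/2} sigma^3
normaliser) is used; an unnormalised kernel would not preserve constants and
could not serve its stated denoising purpose.

## Segmentation

The mask is partitioned by marker-based watershed on the inverted smoothed
SUV. Markers are h-maxima of the smoothed SUV inside the mask (prominence
h >= 1.0 SUV); any 26-connected mask component without a marker receives one
at its SUV argmax, with lexicographic tie-breaks so segmentation is
deterministic. The flood uses 6-connectivity; region identity uses
26-connectivity. Touching organs with distinct peaks (bladder against an
adjacent tumor) split along the SUV ridge line, which plain connected
components cannot do. Each region is then closed with a 1-voxel ball
(cavities filled, no voxel ever removed; contested voxels go to the region
with the higher mean SUV), and regions below 4 mL are dropped — the
detection floor of a 5 mm / SUV-3 thresholding pipeline for small lesions.
A user-supplied label map can replace the automatic stage (the escape hatch
for scans with diffuse abnormal uptake, e.g. super-scans).

## Radiomics features

Each region yields 28 core features — 14 first-order SUV statistics and 14
shape features — optionally extended by 34 texture features (23 GLCM + 11
GLRLM).

*First-order*: energy, entropy, kurtosis, maximum, mean, mean absolute
deviation, median, minimum, range, RMS, skewness, SD, uniformity, variance.
Moments use population (1/N) normalisation; kurtosis is excess kurtosis
(Gaussian -> 0); constant regions take skewness = kurtosis = 0, entropy = 0,
uniformity = 1. Entropy (base 2) and uniformity are computed on a per-region
equal-width discretization.

*Shape*: volume (mL), surface area, surface-to-volume ratio, sphericity,
spherical disproportion, compactness 1 and 2, maximum 3-D diameter, plus six
spatial features: the SUV-weighted centroid as fractions of the scan bounding
box (absolute position is not comparable across scans with different axial
coverage, so only relative location is used) and the unit principal axis of
the voxel-coordinate covariance, sign-fixed to a non-negative z component
("maximum radius vector" is ambiguous; the literal farthest-voxel vector is
available as an alternative reading but the principal axis is stabler).
Surface area comes from a marching-cubes mesh at iso-level 0.5. The binary
mask is anti-aliased with a small Gaussian (sigma 0.8 voxel) before meshing:
a raw binary mesh inflates the staircase surface and biases the sphericity
of a digitised 10-voxel sphere down to ~0.93, while the anti-aliased mesh
recovers ~1.01 at the cost of rounding sharp corners (a cube's measured
compactness 2 sits above the ideal pi/6). Thin regions whose smoothed
maximum falls below the iso-level fall back to the raw mesh. Sphericity,
spherical disproportion and compactness obey their algebraic identities
(compactness2 = sphericity^3) exactly by construction.

*Texture*: symmetric GLCMs at distance 1 and GLRLMs over the 13 unique 3-D
directions; feature values are computed per direction and averaged
(directions without voxel pairs are skipped for the GLCM). The 23 GLCM
statistics are the standard co-occurrence set plus the classic difference
variance — the published catalogues in this family count 22; one was added
to reach the conventional 23 + 11 = 34 split and the exact list is a
documented editorial choice. Degenerate single-level regions emit contrast 0,
energy 1, and correlation 0 with a logged warning.

*Discretization*: equal-width bins over the region's [min, max] SUV, default
16 levels. 32 levels were considered and rejected: on typical PET regions
(10^2–10^3 voxels) a 32-level GLCM is so sparse that texture features become
high-variance noise the forest memorises (its out-of-bag error roughly
doubled). The level count is configurable.

## Classification

A random forest of 50 CART trees (Gini, unlimited depth, sqrt(p) features
per split, bootstrap size n, no class re-weighting — "equally weighted"
features means no scaling or importance priors) is trained on the 28 core
features; the texture variant doubles the ensemble to 100 trees for the 62
features. Class probabilities are the fraction of trees voting each class.
Out-of-bag error is recorded at fit time.

Within one scan each normal tissue (brain, heart, left/right kidney,
bladder) may be assigned at most once; tumor may repeat (primary plus
metastases). The labelling maximises sum log(p + 1e-9) and is solved exactly
as a rectangular linear assignment problem — one column per normal tissue,
one tumor column per region — rather than greedily, so it can be verified
against exhaustive enumeration. The constraint applies at prediction only;
training sees unconstrained rows. Regions of tissues outside the six classes
are nonetheless forced into one of them (an optional reject threshold exists,
off by default).

## Evaluation

Segmentation is scored voxelwise: sensitivity, specificity, precision,
accuracy, Dice, Jaccard. Specificity uses the full field-of-view denominator
(hence its characteristically high values in whole-body PET). Conventions:
both masks empty -> all metrics 1; empty reference with non-empty prediction
-> sensitivity 0 (logged). Automatic-vs-reference volume agreement is an OLS
fit of automatic on reference volumes, reported as slope, intercept and R^2.
Per-feature class discrimination uses Welch t-tests by default (the
pooled-variance variant is a flag); no multiple-testing correction is applied
by default, with Benjamini–Hochberg available. Degenerate zero-variance
comparisons report p = 0 when means differ and p = 1 otherwise, logged.

## Synthetic phantom

The generator emulates the uptake geometry the pipeline assumes, not PET
physics: ellipsoidal organs with mild axis jitter on a 140 x 70 x 340 voxel
grid at 5 mm (x = left-right, y = anterior-posterior, z =
inferior-superior), soft-tissue background SUV 0.5, additive Gaussian voxel
noise with SD 10% of background, and activity back-converted from the drawn
SUV field with a realistic paediatric weight (55 +/- 15 kg, truncated to
26–115 kg) and 5.55 MBq/kg injected dose (clipped to 74–444 MBq), scan at
60 min. Scanner PSF, scatter, Poisson counting statistics and CT are not
modelled; passing tests therefore demonstrate the pipeline's correctness and
internal consistency on idealised uptake geometry, not clinical performance.

Organ volume statistics, visibility rates and partial-uptake patterns follow
the whole-body FDG statistics the pipeline is designed around: brain
1468.37 +/- 266.15 mL (always present), heart 197.59 +/- 125.63 mL (present
in 48% of scans; of those 75% full uptake, 25% apex-only), kidneys
30.70/31.20 +/- ~22.7 mL (present 91%/86%; 30% collecting-system-only),
bladder 118.94 +/- 153.07 mL (always present), tumors log-normal with
arithmetic mean 193.90 and SD 394.46 mL truncated at 1 mL, 0–4 per scan
(25% of scans have none). Apex-only keeps the inferior 45% of the heart's
z-extent; collecting-system keeps an ellipsoidal core at 75% of the organ's
scaled radius (pelvis plus medulla). Placement enforces >= 3 voxels of
background between structures; the right kidney sits lower than the left and
both tilt +/-15 degrees about the y axis (lower poles splayed), which is
anatomically standard and makes left/right distinguishable by more than one
coordinate.

Organ SUV levels are not printed in the source statistics, so they were set
once in the physiological range with two deliberate properties: the bladder
is hottest (7.2 +/- 0.8, excreted tracer) and the myocardium coolest
(4.8 +/- 0.4), with brain 6.0 +/- 0.7, kidneys 6.0 +/- 0.6 and tumors
6.3 +/- 0.9 in between; all truncated above the detection threshold. Means
sit near the balance point of the SUV-3 contour under 1-voxel smoothing so
that full-uptake organs segment with Dice >= 0.9 — organs far hotter or
cooler than the balance point systematically dilate or erode at the
threshold, which is a physical property of threshold segmentation, not of
the generator. Each structure carries intra-organ heterogeneity with
class-specific amplitude and correlation length (uniform urine, fine
myocardial variation, coarse blobby tumor cores ~2.5 voxels), clipped so
avid tissue stays above threshold; this gives texture features genuine but
mild class signal and can legitimately split very heterogeneous tumors at
the watershed stage — evaluation therefore matches each ground-truth tumor
to the union of regions that map to it.

Per-scan seeds derive from a master seed via `SeedSequence`, so cohorts are
reproducible bit-for-bit and two cohorts with different master seeds are
independent. A super-scan stress mode (diffuse midline skeletal uptake) is
available and off by default.

## Validation harness and problem sizes

The two-cohort experiment mirrors the train-on-one-cohort / test-on-the-other
design: 30 training and 30 test scans (~165 regions each), chosen to match
the scale of the clinical cohorts the pipeline is modelled after while
keeping a full run within minutes on one CPU. Segmentation Dice is
summarised per organ as the median across scans, stratified by uptake mode —
partial-uptake organs segment intrinsically worse, which is the phenomenon
the modes model, so the >= 0.90 guarantee applies to full-uptake organs.
Tumor volume concordance pools both cohorts (~70–90 detected tumors).
Uniqueness of normal-tissue labels is enforced structurally and fuzz-tested
against exhaustive enumeration.

## Known limitations

- No PET physics: noise is Gaussian, not Poisson; no PSF, scatter or
  attenuation modelling; no multi-bed stitching.
- Ellipsoids cannot probe shape features against irregular anatomy; the
  shape separability seen on phantoms (e.g. sphericity for heart) is an
  analogue, not a clinical measurement.
- The SUV-3 threshold misses low-uptake tissue by construction (absent-mode
  organs model this); Otsu-style local re-thresholding is not implemented.
- The texture feature list is one defensible reading of the conventional
  catalogues; other packages' lists differ in membership and naming.
- Classification forces every region into one of six classes; thyroid or
  salivary-type regions would be mislabelled unless the optional reject
  threshold is enabled.
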