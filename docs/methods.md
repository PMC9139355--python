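# Methods

This note documents the models implemented in `phymri`, the parameters
that matter, the design choices made where the published formulations of
these methods are ambiguous, and what the synthetic cohort does and does
not establish about real data.

## Biomarker mapping

### Diffusion

ADC is computed as −ln(S_b/S₀)/b and reported in 10⁻³ mm²/s (the map
range [0, 3] refers to that scale). Literal renderings of this formula
sometimes place b inside the logarithm; that form is dimensionally
inconsistent and is not used. Non-positive signals mark a voxel invalid
rather than raising.

### Dynamic susceptibility contrast

ΔR₂(t) = −ln(S(t)/S̄)/TE with S̄ the mean over a baseline window
(default: the first 8 dynamics, preceding the bolus arrival at
dynamic 10). Signals at or below zero are clipped to 10⁻⁶ of the
baseline before the logarithm.

The first-pass window runs from bolus arrival (baseline + 3σ crossing)
to 60 % post-peak recovery; both ends are configurable. Per-voxel
first-pass curves are gamma-variate fitted before the hysteresis
statistics, as a simplified stand-in for dedicated contrast-leakage
corrections (hooks exist to plug those in; they are out of scope). Two
fitting routes are provided: a reference nonlinear least-squares fit of
K·(t−t₀)^α e^{−(t−t₀)/β} per curve (`fit_gamma_variate`), and a
vectorized log-linear fit with the arrival time fixed from the AIF
(`fit_gamma_variate_loglinear`). The log-linear route solves one small
normal-equation system for every voxel simultaneously and is used in
cohort-scale pipelines; both recover noiseless parameters, and the
nonlinear route remains the single-curve reference.

CBV is the AIF-normalized curve integral (κ = 1 by default, i.e. the
maps are calibrated relative to the arterial input). CBF is the maximum
of the residue function from block-circulant SVD deconvolution, with
singular values below 0.1·σ_max discarded. That threshold is the
standard stabilizer for noisy data; it *biases flow low on noiseless
data* (roughly 20–40 % depending on transit time), which is the known
cost of truncated-SVD regularization — the zero-noise recovery test
therefore uses a near-zero threshold. Flow in fraction/s is scaled by
6000 to mL/100 g/min assuming unit tissue density. µCBV is the same
operation applied to the spin-echo series with its own AIF.

### Hysteresis loop, MVD, VSI

The VHL is the closed polygon of (x, y) = ((ΔR₂,SE)^{3/2}, ΔR₂,GE) over
the first-pass window; negative ΔR₂,SE samples are clamped to zero
before the 3/2 power. The MTI is the polygon area signed by rotation:
shoelace area is positive for counter-clockwise traversal, so
MTI = −(shoelace area), making clockwise loops positive.

Qmax defaults to max ΔR₂,GE / (max ΔR₂,SE)^{3/2}. A variant with the
GE curve in the denominator, which appears in some printed renderings
of the definition, is available behind `literal_ge_denominator`; the
SE form is the one consistent with the VHL axes and is the default.

The MVD and VSI groupings are implemented as pure closed-form functions
(`mvd_closed_form`, `vsi_closed_form`) so an alternative reading of the
typeset formulas is a one-line change:

    MVD = Qmax^β (CBV / (24π² ADC R̄⁴))^{1/3}
    VSI = (CBV · ADC · β / (32π Qmax³))^{1/2}

Unit convention for the map-level wrappers: CBV enters as a
dimensionless volume fraction (maps are stored in %, divided by 100
internally), ADC in mm²/s, R̄ in mm; MVD comes out in mm⁻² and VSI is
reported in µm. Keeping CBV as a fraction is also what keeps OEF inside
[0, 1].

### qBOLD

R₂* and R₂ come from per-voxel log-linear fits of the multi-echo
decays. OEF uses the microvascular blood volume (µCBV) as the
susceptibility-carrying compartment. Noise-induced negative R₂*−R₂
differences are clipped at zero. CMRO₂ ≡ Ca·CBF·OEF identically (the
implementation enforces the algebraic identity). The PO₂ expression
P₅₀·(2/OEF − 1)^{1/h} − CMRO₂/L is the standard oxygen-delivery
grouping; printed versions of this formula are typographically
ambiguous, and this reconstruction is verified by its limits
(OEF = 1, CMRO₂ = 0 → PO₂ = P₅₀). The arterial oxygen content constant
is kept at its conventional printed value Ca = 8.68 with a configurable
unit label, acknowledging that the literature is inconsistent about its
units; only products and ratios of these constants enter the maps.

All physical constants live in `PhysioConstants` (frozen defaults,
overridable via construction). Every quantitative map carries a
physiological range; `apply_physiological_threshold` marks out-of-range
voxels invalid, and feature extraction reads only valid voxels. The MTI
range [−1000, 1000] uses the unit label as printed in the source
table ("s^−2/5"), stored but not interpreted.

## Radiomics

Pipeline order: z-score normalization (anatomical CE-T1w/FLAIR only) →
resampling to 1 mm³ (trilinear images, nearest-neighbor masks, via
SimpleITK) → physiological thresholding (quantitative maps) →
fixed-bin-width discretization → extraction. Quantitative maps are
*not* z-normalized: their values are physical.

Discretization: level(v) = floor((v − min)/width) + 1, capped at
ceil((max − min)/width) bins; in-mask values below the range floor get
level 1. The LoG-filtered image (single scale, σ = 1 mm — one filtered
image, matching the 93-feature filtered inventory) is re-discretized
with the parent map's bin count over the filtered value range inside
the mask.

Texture conventions: symmetric GLCM at distance 1 over the 13 unique 3D
directions, features per direction then averaged (directions with empty
matrices are dropped from the average); GLRLM likewise; GLDM with
α = 0 and dependence size = 1 + the number of agreeing 26-neighbors;
GLSZM zones 26-connected; NGTDM over in-mask 26-neighborhoods.
Degenerate conventions: GLCM correlation and MCC are 1 for a
single-level region, information-measure features fall back to 0 when
their normalizers vanish, NGTDM coarseness is capped at 10⁶. Matrix
construction uses numba kernels (GLSZM uses `scipy.ndimage.label`); the
test suite checks them against plain-Python brute-force enumeration of
pairs, runs, zones and neighborhoods.

Shape features are mesh-based: the binary VOI is lightly Gaussian
smoothed (σ = 0.6 voxel) before marching cubes, because the raw binary
staircase overestimates the surface area of smooth objects by several
percent (a digitized ball would otherwise get sphericity ≈ 0.92 instead
of ≈ 0.98); mesh volume follows from the divergence theorem, axis
lengths from 4·√eigenvalue of the physical coordinate covariance.
Shape features depend only on the VOI, so they are computed once per
VOI and reused across images of a case.

Feature columns are named `<source>_<voi>_<filter>_<family>_<feature>`.
Counting convention: 107 unfiltered + 93 LoG features per image and
VOI; the data-set combinations count both VOIs, and "advMRI" includes
the anatomical images (800 cMRI, 1600 advMRI, 2800 phyMRI columns;
combinations additive).

## Feature selection

* **ICC**: two-way random effects, absolute agreement, single rater —
  ICC(2,1) — computed in closed form from the two-way ANOVA
  decomposition and cross-checked against `pingouin` in the tests. The
  variant is configurable in principle by replacing `compute_icc`;
  ICC(2,1) is the standard choice for two-segmentation stability.
  Features with zero variance in both readings are undefined (NaN) and
  discarded. The stability threshold is 0.9 ("excellent"
  reproducibility).
* **Filters**: the information-theoretic scores (information gain, gain
  ratio, symmetrical uncertainty) operate on supervised MDL
  (Fayyad–Irani) binnings of each feature; a feature whose MDL
  criterion accepts no split scores 0. The correlation score is the
  class-prior-weighted mean |point-biserial correlation| against each
  one-vs-rest indicator; OneR is the training accuracy of the
  majority-class-per-bin rule; ReliefF uses all instances, k = 10
  nearest hits/misses, Manhattan distance on range-scaled features and
  prior-weighted miss contributions. Ties rank lexicographically, so
  rankings are deterministic.
* **Consensus**: "top ranked" is operationalized as top-50 per filter —
  the same cap as the output set; a feature qualifies with ≥ 3 of 6
  appearances, and qualifiers beyond 50 are dropped by mean rank. If
  fewer than 50 qualify, all qualifiers are returned (documented
  deviation from a hard cap).
* **SMOTE**: synthetic minority rows are convex combinations of a
  minority row and one of its k = 5 same-class nearest neighbors;
  classes smaller than k+1 reduce k with a warning. By default SMOTE is
  applied *inside each training fold* of cross-validation; balancing
  the whole table before splitting (the historical protocol) leaks
  synthetic neighbors of validation cases into training and is
  available as `smote="pre"`. The permuted-label test pins the default
  at chance level.
* **Wrapper**: best-first forward search; subsets scored by internal
  5-fold stratified CV accuracy of the actual downstream classifier;
  the search stops after 5 consecutive expansions without improving the
  best subset. With ≤ 10 candidates this provably coincides with
  exhaustive search in the tests.

## Classification protocol

Standard learners are scikit-learn models; the package's own content is
the protocol and metrics. Family settings: GaussianNB; logistic
regression (max 1000 iterations); SVC with polynomial kernel, degree 1,
C = 1, probability outputs; 3-nearest-neighbors; CART decision tree
(standing in for a pruned C4.5); MLP with one hidden layer of
(#features + #classes) neurons, 500 epochs; AdaBoost with 10
depth-3-tree rounds; random forest with 100 trees; bagging of 10
extremely-randomized trees (standing in for bagged random trees).
Scale-sensitive learners (logistic, SVM, kNN, MLP) are standardized in
a pipeline. All seeds are explicit.

Cross-validation is stratified 10-fold (shuffled, seeded), falling back
to unstratified folds with a warning when the smallest class has fewer
members than folds. Per-class one-vs-rest sensitivity, specificity,
precision, F1, binary accuracy and trapezoidal AUROC are averaged over
folds and then weighted by class support; classes absent from a
validation fold are skipped for that fold, and zero-support classes get
zero weight. Two accuracy notions are reported because they genuinely
differ: the support-weighted one-vs-rest binary accuracy (`accuracy` in
the weighted metrics) and the plain fraction correct
(`overall_accuracy`).

The grid is 9 families × 5 data-set combinations × 3 VOI choices = 135
models, keyed (family, data set, VOI), with heat-map export of any
weighted metric.

The bundled `datasets.cohort_readings` table carries published
per-patient readings of a 20-patient test cohort (histology plus three
model predictions and the consensus human reading); the error-counting
utilities recompute its misclassification totals (5, 5, 5 and 6) from
the per-patient entries as a worked example.

## Synthetic cohort

The generator emulates the acquisition protocol of a physiological-MRI
brain-tumor study: 60-dynamic GE and SE susceptibility series (TR
1.5 s, TE 30/80 ms), 8-echo GE and SE relaxometry trains, a two-point
DWI pair, anatomical CE-T1w/FLAIR, at 3 T with anisotropic 1×1×3 mm
voxels, plus tumor and edema masks (edema excludes the enhancing core).
Lesions are ellipsoids in a homogeneous background; ground-truth
physiology is drawn per entity from Gaussian profiles, smoothed for
spatial coherence and clipped to the physiological ranges.

The literature gives no quantitative per-entity physiology table, so
the per-entity means in `default_profiles` are package choices placed
inside the physiological ranges (e.g. meningioma: high CBV ≈ 18 %, low
OEF; lymphoma: low CBV ≈ 5 %, low ADC; glioblastoma: high CBV and a
90 % clockwise-loop probability reflecting arteriole-dominated
neovascularization). The `separation` knob scales every class mean
toward background physiology to make the problem harder.

Forward models are the exact inverses of the mapping stage: DSC curves
are CBF·(AIF ⊛ e^{−t/MTT}) with MTT = CBV/CBF, so integrals are
proportional to blood volume and deconvolution recovers flow; the SE
bolus is lagged by ±1 dynamic relative to GE, the lag sign (per case,
drawn from the profile's clockwise probability) setting the hysteresis
rotation; R₂* is constructed from R₂, OEF and µCBV by inverting the
qBOLD relation; noise is Rician via complex Gaussians. A second
reader's segmentation is emulated by adding a smooth random field to
the signed boundary distance and re-thresholding, with the jitter
amplitude backed off until Dice ≥ 0.80.

What passing tests on this cohort do **not** show: robustness to
realistic anatomy, partial-volume effects, motion or susceptibility
artefacts, contrast-agent leakage, scanner or protocol variation, or
overlapping class physiology. The end-to-end AUROC ≥ 0.9 result on
well-separated profiles is a correctness check of the chain, not a
clinical performance claim.

## Problem sizes and runtime choices

The full synthetic study uses the emulated cohort composition — 167
training cases (77/17/28/16/29 across GBM/AG/MNG/PCNSL/META) and 20
test cases (9/3/3/0/5; no PCNSL) — on 48×48×20 volumes, with 50
re-segmented cases for the stability filter and phyMRI features of the
tumor VOI; this keeps a full run in a few CPU-minutes. The
classifier-grid demonstration uses 30 cases (6 per class) with
consensus-selected features per table. Per-voxel perfusion and qBOLD
mapping is restricted to the dilated lesion region in cohort pipelines
(`roi` argument), since features only read the VOIs. The end-to-end
experiment omits the per-classifier wrapper stage — its cost grows
quadratically with candidate features times internal folds, and the
consensus set is what the sanity bound is about; wrapper behavior is
validated separately against exhaustive search.

## Known limitations

* Dedicated contrast-leakage, background-field and stimulated-echo
  corrections are not implemented; the gamma-variate first-pass fit is
  the only leakage control.
* AIF auto-identification is a documented heuristic
  (earliest-arrival/highest-peak candidates); synthetic cases carry the
  true AIF, so deconvolution is tested in isolation from AIF selection.
* Truncated-SVD deconvolution underestimates flow (see above); CBV,
  which drives most downstream maps, is unaffected.
* Texture definitions follow the IBSI conventions listed here;
  implementations differ in degenerate-case conventions and aggregation
  order, so third-party values may deviate on pathological inputs.
* The fraction-correct and weighted one-vs-rest accuracy differ by
  construction; consumers must pick the notion they mean.
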