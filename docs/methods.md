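# Methods

`swallowtail` implements an automated classifier for early Parkinson's
disease (PD) on neuromelanin-sensitive "setMag" MRI, fusing hand-crafted
radiomics features of the substantia nigra pars compacta (SNpc) with
deep features from a small CNN, and ships a synthetic midbrain phantom
so that the entire pipeline is testable and reproducible without
patient data.  This note records the model, its assumptions, the
defaults, and the design choices that were genuinely open.

## The synthetic phantom

Each synthetic subject is a 96 x 96 x 16 voxel volume at
0.5 x 0.5 x 1 mm, containing a bright midbrain ellipsoid on a dark
background, bilateral hyperintense SNpc crescents confined to exactly 4
contiguous axial slices (the slab a rater would delineate), and a
dorsolateral "swallow-tail" sector inside each crescent — the
nigrosome-1 analogue — rendered as an intensity uplift.  The disease
effect emulates neuromelanin loss with two knobs applied to PD cases
only:

| parameter | meaning | default |
|---|---|---|
| `swallowtail_attenuation_pd` | multiplies the tail intensity uplift | 0.5 |
| `snpc_area_shrink_pd` | scales the in-plane crescent area | 0.8 |
| `swallowtail_contrast_hc` | tail S0 uplift, intensity units | 220 |
| `noise_sigma` | Rician noise scale, intensity units | 6 |
| `echo_times` | ms, ascending | 5, 10, 15, 20, 25 |
| `jitter_amplitude` | second-rater boundary jitter, voxels | 0.6 |

Multi-echo magnitudes follow a mono-exponential T2\* decay
S(TE) = S0 · exp(−TE/T2\*) with tissue-specific T2\* (background 40 ms,
midbrain 35 ms, iron-rich SNpc 30 ms), so the three shortest-TE volumes
are the brightest — the property setMag reconstruction exploits.  Noise
is Rician (magnitude of a complex Gaussian), the standard MR magnitude
model.  Per-subject anatomical variability is limited to small integer
translations of the midbrain center and a multiplicative intensity
gain; the default attenuation/shrink values are tool knobs chosen so
that a single intensity threshold separates the classes in the
noiseless limit — they are not literature-derived effect sizes.  A
second-rater mask is produced by perturbing the per-slice signed
distance transform with a smooth Gaussian random field; at the default
amplitude the inter-rater Dice coefficient falls in roughly
[0.85, 0.98], which is what the ICC/DSC code paths need to see.

The phantom deliberately omits: realistic neuroanatomy, k-space /
susceptibility (QSM dipole-inversion) physics, motion and bias-field
artifacts, partial-volume effects, and scanner-to-scanner variation.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and recovers a planted disease effect of this simple form —
not that it would reach comparable accuracy on clinical data.

## Preprocessing

setMag is the voxelwise combination of the magnitude volumes of the
three shortest echo times.  The combination operator is the arithmetic
mean: it is permutation-invariant, linear, and preserves the intensity
scale; sum and root-sum-of-squares differ only by scale factors that
downstream normalization removes.  Volumes are resampled to
0.5 x 0.5 x 1 mm with nearest-neighbor interpolation (so masks pass
through the same path without label mixing).  Brainstem patches are
contrast-enhanced by grayscale inversion (max − pixel) followed by
global 256-level histogram equalization; global rather than adaptive
(CLAHE) equalization is the simplest reading of the procedure and keeps
the transform monotone in pixel rank.

## Brainstem localization

The published pipeline used an off-the-shelf object detector for the
brainstem crop; detection methodology is not a contribution here, so
the package uses a fully specified, desk-scale substitute with the same
contract (a 40 x 40 crop on each of 4 slices): a two-convolution
heatmap network (8 then 1 channels, valid 5 x 5 kernels) over the 2x
average-pooled, min-max-normalized slice, read out by a spatial softmax
(soft-argmax) into an expected (row, col) center and trained with
squared error against the true center.  Fifteen epochs of Adam at
lr 2e-3 reach near-zero loss on the phantom; held-out IoU against the
true 40 x 40 box is ~1.0 (the acceptance bound is 0.7).  Crops are
clamped, never zero-padded, at slice borders, so histogram equalization
never sees artificial margins.  An intensity-centroid heuristic (Otsu
foreground, upper half, intensity-weighted centroid) serves when no
trained detector is available.  At inference the 4 slices are the
mask-bearing slices when a mask exists, else the 4 central slices.

## Radiomics

Feature extraction follows the IBSI definitions with the pyradiomics
naming convention `<image>_<family>_<feature>`.  The default profile is
exactly 1781 features: 107 on the original image (18 first-order, 14 3D
shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) plus 93 (all
families except shape) on each of 18 filtered images — 8 sub-bands of a
one-level 3D stationary `coif1` wavelet transform, Laplacian-of-Gaussian
at sigma = 1..5 mm, and square / square-root / logarithm / exponential /
gradient-magnitude maps.  The LoG sigma count (5) is forced by the
decomposition 1781 = 107 + 18 x 93 given 8 wavelet sub-bands and the 5
single-output filters; the sigma values themselves are the package's
choice.  Numerical conventions:

* discretization is fixed-bin-width (default 25 intensity units),
  `level = floor((v − min)/w) + 1`;
* GLCM and GLRLM use the 13 unique 3D direction offsets at distance 1,
  symmetric GLCM, features computed per direction and averaged;
  directions with no voxel pair are skipped;
* GLSZM/GLDM/NGTDM use 26-connectivity; GLDM dependence tolerance is
  alpha = 0 and the dependence size counts the center voxel;
* degenerate ROIs return documented fallbacks, never NaN: correlation
  and MCC fall back to 1, the information measures to 0, NGTDM
  coarseness is capped at 1e6;
* shape is computed once, in 3D over the 4-slice ROI, from a
  marching-cubes mesh (volume via the divergence theorem, diameters via
  convex-hull pruned pairwise distances, axis lengths from the PCA of
  physical voxel coordinates);
* the volume is cropped to the mask bounding box plus a (10, 10, 2)
  voxel margin before filtering, which bounds the cost of the filter
  bank without changing in-mask values (the margin exceeds every filter
  support that touches the mask except the outermost tail of the
  largest LoG kernel, whose contribution is negligible at these sizes).

The final feature table is standardized per feature to zero mean / unit
variance with statistics fit on training rows only.

## Feature selection

Reproducibility filtering uses ICC(2,1) — two-way random effects,
absolute agreement, single measurement — computed from the ANOVA mean
squares on the double-delineated subset (default 30 training cases),
keeping features with ICC > 0.8.  ICC(2,1) is the standard form for
two-rater absolute-agreement reproducibility; bit-identical columns are
treated as perfectly reproducible.  Sparse selection is an L1-penalized
logistic regression with the penalty chosen by five-fold
cross-validated deviance (the `lambda.min` convention, which is the
denser choice and matches a target signature of ~10 features better
than `lambda.1se`).  Because the exact signature size on any given
cohort is an outcome, not a contract, the pipeline exposes `cap_to_k`
(default 10 in the orchestrator): surplus features are trimmed by
coefficient magnitude, shortfalls are topped up along the
regularization path.

## The CNN

The classifier is a modified LeNet on 40 x 40 patches:
conv 6@5x5 → pool → conv 16@5x5 → pool → flatten(784) → fc 200 (ReLU,
the deep-feature layer) → fc 2 → softmax; the 784→200→2 head realizes
the fixed 1 x 200 feature-layer constraint.  It is implemented directly
in numpy with hand-written backward passes (im2col convolutions), and
the gradients are verified against central finite differences in the
test suite.  Training: Adam (lr 1e-3, batch 32), up to 40 epochs with
early stopping (patience 8) on validation accuracy, five-fold
cross-validation split at case level so all four patches of a case
share a fold, and per-patch standardization.  Augmentation (each
training patch plus two copies with scale ~ U(0.95, 1.05) and rotation
~ U(−5°, +5°), bilinear, edge-extended) applies to training folds only.
The saved model is the fold checkpoint with the highest validation
accuracy.  A refit-on-everything option exists but is not the default:
without a validation signal the refit cannot be checkpointed, and at
these cohort sizes it measurably generalizes worse (0.80 vs 0.92
held-out image accuracy in a 64-training-case comparison).

Reported augmented-image counts in the source clinical study do not
equal three times its stated training-image count; the package follows
the tripling rule, which is the only self-consistent reading.

## Fusion and classifiers

Each case's 4 x 200 deep-feature block (feature-layer activations per
slice) is aggregated to one 200-vector by the per-feature mean — the
only permutation-invariant choice that keeps 200 nameable features for
ranking; ranking on the 800 slice-wise features is the alternative the
package documents but does not use.  Deep features are standardized
with training statistics, ranked by mean decrease in impurity averaged
over 100 random forests with derived seeds, and the top 20 are
concatenated with the (10) selected radiomics features into the 1 x 30
hybrid vector.  Where the source material gives both "top 10" and
"top 20" for this step, only 10 + 20 produces a 1 x 30 vector, so 20 is
the default (configurable).  Six classifiers are fitted on the fused
table: KNN (k=5), random forest (100 trees), L2 logistic regression,
RBF SVM with probability outputs, a one-hidden-layer (64) MLP, and
AdaBoost on 50 decision stumps — fixed, seeded defaults, all
configurable.

## Evaluation

Diagnosis is patient-wise: a subject is PD when at least 3 of their 4
image-level calls are PD; the patient-level probability for ROC
analysis is the mean of the 4 image probabilities (for case-level
classifiers the single case probability is used directly).  AUC uses
the rank (Mann-Whitney) formulation with tie correction; its 95% CI is
a stratified percentile bootstrap (2000 resamples).  Model improvement
uses the category-free (continuous) NRI — no risk categories are
defined for this task — with the asymptotic normal test, ties counting
as neither up nor down, and the IDI (change in discrimination slope)
with a Welch t-test on the paired differences.  Inter-rater
segmentation agreement is the Dice coefficient, defined as 1 when both
masks are empty.

## Orchestration and reproducibility

A single master seed expands into fixed per-stage seeds (simulation,
split, detector, CNN, MDI, LASSO, classifiers, bootstrap) recorded in a
run manifest together with per-stage wall time and SHA-256 checksums of
stage inputs and outputs; reruns with the same config are
bit-reproducible and the manifest shows that no fitted component
(scaler, ICC subset, LASSO, MDI ranking, detector, CNN) ever sees a
test case.  The 8:2 split takes the floor of the test share and
apportions it across classes by largest remainder, which reproduces a
111/27 split of 138 cases.  The external-validation path generates a
fresh cohort under a different seed (and, by default, 20% higher noise)
and evaluates frozen models only.

## Problem sizes

The default cohort mirrors the study conditions: 65 HC + 73 PD, split
111/27, with 30 double-delineated training cases.  The test suite's
shared end-to-end fixture uses a 64-case cohort with a shortened CNN
schedule (25 epochs), which keeps the whole suite within a few minutes
on one CPU while leaving every statistical check comfortably above its
threshold; the acceptance script runs the full 138-case configuration.

## Known limitations

* The phantom's disease effect is a two-parameter caricature; effect
  sizes are not calibrated to patient data, and headline clinical
  accuracies from any real cohort are out of reach by construction.
* The localizer is a center regressor, not a general object detector:
  it assumes one bright midbrain-like structure per slice.
* Shape features use a voxel-mesh at half-voxel level crossing;
  sub-voxel surface placement differs slightly from implementations
  that interpolate the intensity surface.
* The LASSO path comes from fold-averaged liblinear fits; path-wise
  sparsity monotonicity is checked empirically, not guaranteed by the
  solver.
* NRI/IDI variants and the AUC CI method are stated conventions
  (continuous NRI, percentile bootstrap); other conventions exist and
  give different p-values.
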