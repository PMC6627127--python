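# Methods

This package reconstructs, as a tested pipeline, an MRI-based prediction
of chemoradiotherapy outcome (local control vs. local failure) in
sinonasal squamous cell carcinoma.  Per patient it derives 27 candidate
features from four sources — clinical staging, tumor shape, T2 texture,
pCASL perfusion and multi-b-value diffusion — and classifies them with an
RBF-kernel SVM wrapped in backward sequential feature elimination under a
nested 9-fold cross-validation.  Because the underlying patient images are
not public, the package ships a synthetic cohort generator calibrated to
the published group-conditional feature statistics; every pipeline stage
is exercised end-to-end on generated data.

## Feature extraction

**Shape.** Volume is voxel count × voxel volume.  Surface area comes from
a marching-cubes triangulation of the binary mask (level 0.5, anisotropic
spacing honored) after a small Gaussian pre-smoothing (σ = 0.7 mm): the
raw staircase surface of a digitized ball overestimates area by ~9% and
would depress every sphericity by that factor.  Sphericity is
π^(1/3)·(6V)^(2/3)/A with V in mm³, A in mm²; volume is reported in mL and
area in cm².  On grids much coarser than the smoothing σ the digitization
bias remains; sphericity is then comparable within a grid, not across
grids.

**T2 intratumoral features.** Relative mean signal is the tumor ROI mean
divided by the contralateral medial-pterygoid muscle ROI mean; CV is
SD/mean within the tumor.  The four Haralick features (contrast,
correlation, energy, homogeneity) come from a gray-level co-occurrence
matrix built slice-wise with four in-plane offsets at distance 1 (0°, 45°,
90°, 135°), symmetric, min–max quantized to 64 levels within the ROI, with
only voxel pairs fully inside the (non-necrotic) ROI counted, all slices
and offsets pooled before normalization.  A ROI constant after
quantization is degenerate: contrast 0, energy 1, homogeneity 1,
correlation reported as 0 and flagged.  Quantization depth and offsets are
configurable; min–max quantization makes all four features invariant to
affine intensity rescaling.

**Perfusion.** The single-compartment pCASL model

    TBF = 6000 λ ΔM exp(PLD/T1b) / (2 η M0 T1b (1 − exp(−τ/T1b)))

with τ = 1650 ms, PLD = 1280 ms (the acquisition protocol) and consensus
constants λ = 0.9 mL/g, T1b = 1650 ms, η = 0.85 (all configurable).  The
control image stands in for M0 (no separate M0 scan in the protocol).  The
control−label subtraction is kept signed: rectifying it to a magnitude
biases the ROI mean upward wherever true perfusion signal is comparable to
the noise (notably the low-flow reference muscle), which would deflate
every relative-TBF value.  Relative TBF is tumor flow over muscle flow and
is invariant to global scanner gain.

**Diffusion.** Five models are fitted to the tumor ROI-mean signal
(ROI-mean-then-fit; the reported per-tumor parameters are single ROI
values, and ROI averaging is the noise-robust reading — voxelwise fitting
of a tri-exponential at clinical SNR is dominated by noise).  The standard
signal forms are used: mono-exponential (ADC, log-linear closed form on
the reduced schedule {0, 200, 400, 800, 1000, 2000} s/mm²), IVIM
bi-exponential (f, D*, D; all 12 b-values), tri-exponential (f1–f3, D1–D3;
all 12), stretched exponential (α, DDC; reduced) and kurtosis (K, D_k;
reduced).  The reduced schedule excludes the perfusion-sensitive low-b
range for the models that target tissue diffusion.  IVIM and
tri-exponential fits are seeded by a segmented high-b-first decomposition
and refined by bounded joint least squares with a three-start jitter
(fixed internal seed, so fits are deterministic functions of the data);
the tri-exponential fractions are parameterized on the simplex
(f1 = u1, f2 = (1−u1)u2) so they sum to one exactly, and the coefficient
bounds D1 ∈ [3, 300], D2 ∈ [0.3, 3], D3 ∈ [0.05, 1.2] (×10⁻³ mm²/s) keep
the compartments ordered.  Non-convergence returns a flagged best-so-far
result, never an exception mid-pipeline.

A conditioning caveat that matters for interpretation: at a b0-SNR of 50
with a ~500-voxel ROI, the Cramér–Rao bound for the intermediate
coefficient D2 is a ~0.9 relative SD — the (f2, D2)/(f3, D3) exchange
direction is nearly flat.  The bounded fitter measures ~26% median
relative error there (the bounds act as a weak prior); no estimator can do
fundamentally better at that noise level.  Published between-patient SDs
of D2 (~15%) are of the same order as this fit instability.

## Classification protocol

Per outer fold (32 training / 4 validation of 36):

1. z-scoring fitted on the training rows only; held-out rows reuse the
   training statistics (the original report does not state whether
   features were standardized; fold-internal standardization is the
   strict, leakage-free choice);
2. exhaustive (γ, C) grid search over γ = 2⁻²⁰…2¹⁰, C = 2⁻¹⁰…2¹⁰ (integer
   exponents), scored by inner 4-fold CV accuracy repeated 3× (the inner
   protocol is not specified by the original report; repeated inner CV
   smooths the 1/32-grained accuracy), ties broken toward smaller C then
   smaller γ;
3. backward elimination from all 27 features; each iteration drops the
   feature whose removal leaves the best inner-CV score; a size-k subset
   is scored with γ·k₀/k, keeping the kernel bandwidth matched to the
   dimension (for standardized features E‖x−x′‖² grows ∝ k, so a fixed γ
   tuned at 27 features scores small subsets with a nearly flat kernel);
4. the selected subset is the best-scoring prefix of the ranking (smallest
   on ties); (γ, C) are re-tuned on that subset and the final model refit;
   a full grid search inside every elimination step would multiply cost
   ~650-fold with no stated protocol reason;
5. sensitivity, specificity, PPV, NPV and accuracy are computed on the
   training rows (resubstitution) and the 4 held-out patients; "local
   control" is the positive class (the published fold counts only resolve
   with ~19–20 positives of 32); fold means are NaN-aware because a
   4-patient fold can lack one class when folds are unstratified (the
   default, matching the random division described).

The SVM engine is libsvm via scikit-learn; the hot loop calls the
low-level binding directly (identical predictions to the public
estimator, pinned by a test) because a nested experiment performs tens of
thousands of fits on 24–32-sample problems.

## Synthetic cohort

`sample_cohort` draws each patient's 25 continuous features from
independent group-conditional Gaussians at the published means/SDs
(a correlation-matrix hook exists, but marginals are the only published
calibration), truncated to physical ranges; the tri-exponential fraction
triple is clipped to [0.01, 0.97] and renormalized to sum 1; T/N stages
are drawn from the published contingency counts; 22 control + 14 failure
by default.  Because some published SDs are large relative to their means
(failure-group volume 34.3 ± 28.6 mL), truncation shifts expectations; the
calibration tests therefore compare sample means against the closed-form
truncated-Gaussian expectations the truncation rule induces
(`expected_truncated_means`), not the raw printed numbers.  At n = 10⁴ per
group all 27 features match those targets within 4 SE.

Rendering: the tumor mask is a ball modulated by seeded degree-2..4
spherical harmonics and stretched volume-conservingly along a random axis;
one irregularity parameter drives both, and is bisected until the
mesh-measured sphericity hits the sampled target (volume is re-calibrated
by radius bisection at every step).  The stretch is capped so the
transverse radius stays ≥ 2 in-plane voxels.  On the default acquisition
grid (3.59 × 3.59 × 5.0 mm, the printed DWI voxel size) the reachable
sphericity range is ≈ [0.47, 0.94]; sampled targets outside it are
clamped to the nearest reachable shape, while the standalone operation
raises an infeasible-shape error.  DWI is generated voxelwise from the
tri-exponential forward model — the richest of the five — so the other
four models are deliberately fitted to mis-specified data; Rician noise at
b0-SNR 50 (typical 3 T head/neck EPI) with the acquisition's per-band
signal averaging (1× for b ≤ 100, 2× for 200–800, 3× above).  ASL noise is
Gaussian on the subtraction with SD √2·(M0/SNR)/√N_pairs (control-image
SNR 100, 30 averaged control/label pairs, the scale a 5-minute pCASL scan
implies).  The T2 tumor is a spatially correlated Gaussian field affinely
rescaled so relative mean and CV are exact; its correlation length is
searched so the measured GLCM contrast matches the sampled target
(scan-then-bisect, because for very small ROIs the contrast–length curve
turns non-monotone when a heavily smoothed field approaches a ramp).

Ground truth is recorded twice: `sampled` (the Gaussian draw) and
`realized` (what noiseless extraction of the rendered images measures).
The two differ where rendering cannot carry independent information:
surface area is functionally determined by volume and sphericity; ADC,
IVIM, SEM and DKI values are whatever those models fit on the
tri-exponential signal; GLCM correlation, energy and homogeneity follow
from the single correlation length that matches contrast.  Round-trip
tests compare extraction against `realized` (every feature within 1%, 5%
for sphericity- and GLCM-dependent features, with noise off), and
additionally against `sampled` for the generating tri-exponential
parameters themselves.

What passing these tests does **not** show about real data: the generator
draws features independently (real radiomic features co-vary), renders
spatially homogeneous tumors (one diffusion/perfusion value per tumor, no
necrotic cores unless flagged explicitly), and contains no anatomy,
k-space/EPI artifacts or motion.

## Accuracy reference for the classification analogue

The published headline metrics were measured on 36 real patients whose
images are not deposited, so they cannot be targets.  Instead the
classification analogue is checked against a Monte-Carlo accuracy oracle:
an optimally tuned RBF-SVM trained on a large rendered reference cohort
(150 patients, same group ratio) and scored on held-out rendered patients
— a consistent lower bound of the Bayes accuracy of the feature
distribution the classifier actually sees.  The nested-CV mean validation
accuracy on a rendered 36-patient cohort must come within 0.10 of that
oracle, and label-permutation runs (20 seeds) must average in [0.3, 0.7].
The exact likelihood-ratio Bayes accuracy of the *sampled* parameter
distributions is higher (~0.97) precisely because rendering discards
information (see `realized` vs `sampled` above); using it as the
reference would measure the renderer, not the classifier.  For context,
the original study reports mean validation accuracy 0.92 on its real
cohort; that number is documented here, not asserted.

## Problem sizes and determinism

Default test problem sizes: calibration at 10⁴ samples per group,
elimination-ranking Monte-Carlo at n = 200 × 50 seeds, classification
analogue on one rendered 36-patient cohort with three CV partitions and a
150-patient oracle cohort.  All randomness flows from explicit integer
seeds through `numpy` generators (`SeedSequence` spawning per patient and
per fold); identical seeds give bit-identical cohorts and experiment
traces.  Optimizer tolerances: bounded trust-region least squares with
xtol = ftol = gtol = 10⁻¹⁴; ADC by closed-form log-linear regression.
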