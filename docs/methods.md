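# Methods

`libspec` implements a discrimination pipeline for laser-induced breakdown
spectroscopy (LIBS) of plant material, built around two complementary routes
for taming very wide spectra (V ≈ 22,000 channels, 229–878 nm): aggressive
variable selection feeding 1-D classifiers, and a deterministic
spectrum→matrix recombination feeding a small 2-D CNN. This note records the
model, the tunable parameters, the numerical choices, and what the synthetic
test harness does and does not establish.

## Data model and splitting

A dataset is a flat table of spectra with a shared, strictly increasing
wavelength axis and per-spectrum metadata: origin class (1–12), plant,
tablet, plant part (underground/aerial), and laser position on the tablet
(1–16). The physical sampling unit is the tablet — a pressed pellet ablated
at several positions — so splitting into calibration/validation/prediction
sets happens at tablet level to prevent position-level leakage. With a 3:1:1
ratio, the two small subsets are rounded to the nearest tablet and
calibration takes the remainder: 118 tablets give 70/24/24, i.e.
1,120/384/384 spectra at 16 positions per tablet. Underground and aerial
parts are analyzed as separate datasets.

Two additional splitters exist for small designs. A stratified tablet split
guarantees every origin at least one calibration tablet. A position-holdout
split goes further: per origin, one tablet (half the tablets, rounded up)
goes to calibration with two of its positions carved out as validation, and
the remaining tablet(s) form a tablet-level prediction holdout. The
motivation is structural: with two tablets per origin a three-way tablet
split cannot give every origin both a calibration and a validation tablet,
and a validation set covering only half the classes mis-steers threshold
based early stopping (training halts while uncovered classes are still
unlearned). Position-holdout validation shares tablets with calibration and
therefore measures within-tablet generalization only; the prediction set
remains a clean unseen-tablet holdout and is the only set quoted as
generalization performance.

## Preprocessing

Denoising is a multi-level Daubechies wavelet decomposition with soft
thresholding of detail coefficients at the universal threshold
σ·√(2·ln V), σ estimated by the median absolute deviation of the finest
detail level; boundary handling is symmetric extension. The wavelet order
and level are tuned by exhaustive grid search over [3, 10]² maximizing the
mean per-spectrum signal-to-noise ratio, with ties broken to the smaller
(order, level). The SNR definition is a design choice (the quantity is
under-specified in the field): peak signal over residual spread,
max(denoised) / SD(original − denoised); a zero residual is flagged and
treated as +∞ by the search. Parameters are tuned once per plant part.

Area normalization divides each spectrum by its total intensity,
X_i = x_i / Σ_j x_j, removing shot-to-shot laser-energy fluctuations; output
spectra sum to 1 within 1e-12, and the operation is scale-invariant and
idempotent. Processing order is denoise → normalize.

## Variable selection

**Stage 1 — SD filter.** Channels that never see an emission line carry only
near-zero readout noise and have near-zero standard deviation across
spectra. The filter keeps channels above a cutoff chosen by one of three
modes: `knee` (default; the maximum-curvature point of the ascending sorted
SD curve, found as the point of maximum perpendicular distance below the
endpoint chord), a fixed `threshold`, or `keep_top` K. The kept count is
logged because the knee is a heuristic replacement for a by-eye cutoff.

**Stage 2 — iterative RF permutation importance.** The forest is an ensemble
of CART trees (scikit-learn base learners, max_features = √p) over a
bootstrap drawn by the package, so each tree's out-of-bag (OOB) rows are
explicit. A variable's importance is the mean over trees of the increase in
that tree's OOB error after permuting the variable's values within the
tree's OOB block:

    Vim_j = Σ_t (OOBerror2_tj − OOBerror1_t) / N

Permutation is the standard realization of "perturbing" a variable: it
preserves the marginal distribution while destroying the association with
the class. Per round, the forest size is tuned over {50, 60, …, 110} trees
by forest-level OOB accuracy (majority vote over the trees for which a
sample is OOB; ties prefer fewer trees), the ⌈0.05·n⌉ lowest-Vim variables
are dropped (Vim ties drop the larger channel index), and the tuned forest
is refit on the survivors to record that round's OOB accuracy. The schedule
runs up to 60 rounds (or until one variable remains) and the retained set is
the round with the best OOB accuracy, earliest on ties — so a zero-round run
returns the input mask. The variables-remaining sequence is pure arithmetic,
n ← n − ⌈n/20⌉ (exact integer ceiling): from 2,016 retained channels it
reaches 325 after 35 rounds and 277 after 38.

## Spectral matrix

A spectrum of V variables is cut into n = ⌊V/h⌋ consecutive segments of h
variables, stacked row-major into an n×h matrix (0-based indexing); pixel
(r, c) holds variable r·h + c, making pixel↔wavelength mapping a bijection
on the retained prefix. The V − n·h trailing variables are discarded with a
warning (they may carry lines; a weighting scheme that protects them is out
of scope). Default h = 150; h ∈ {110, 150, 200} are the comparison values.
The transformation is exactly invertible on the retained prefix and
conserves totals, which the tests assert.

## Classifiers

Three CNNs, built on an in-package numpy layer stack with explicit
forward/backward passes (convolutions via im2col + BLAS; the backward passes
are verified against central finite differences in float64):

- **1D-CNN1** (AlexNet-flavoured): four conv blocks — convolution (kernel 3,
  'same' padding) → batch normalization → max-pool 2 → ReLU — with
  512/128/64/16 kernels, then dense blocks of 256/64/32 (ReLU, dropout 0.3),
  softmax output.
- **1D-CNN2** (ResNet-flavoured): a 64-kernel conv block, then residual
  blocks of (64, 2), (128, 2), (256, 2) convolutions with identity skips
  (1×1 projection only where channel counts change; each block followed by
  max-pool 2), a 128-neuron dense block, softmax output.
- **2D-CNN**: two conv blocks — 64 kernels of 7×7, then 16 of 3×3, each with
  batch norm, max pooling and ReLU — then dense blocks of 256 and 64 and a
  softmax output. The 2-D blocks pool 4×4 (shrunk per axis when an input
  dimension is smaller than 8). This pooling choice is deliberate: with 2×2
  pooling the flattened feature map at the 146×150 survey geometry would
  drive the dense layer to ~5.5M parameters, more than either 1-D network;
  4×4 pooling keeps the 2-D network the simplest of the three (~0.36M
  parameters at 146×150 versus ~0.76M for 1D-CNN1 at 2,016 inputs), matching
  its design intent.

Unstated engineering details are fixed as documented defaults: 'same'
convolution padding so only pooling shrinks extent; batch-norm momentum 0.9
with running statistics seeded from the first training batch; minibatch size
32; SGD with momentum 0.9; categorical cross-entropy on the softmax;
dropout after each dense activation; float32 parameters (float64 available
via `dtype`, used by the gradient-check tests).

**Staged training.** Training runs a sequence of (learning rate, validation
threshold) stages — the reference schedule is rates 0.1/0.05/0.01/0.005
against thresholds 0.6/0.75/0.92/0.96 — each stage ending when validation
accuracy reaches its threshold or at a 1,000-epoch cap. Rates must strictly
decrease and thresholds strictly increase; an "iteration" is one epoch over
the calibration set. Per-epoch history (stage, epoch, running calibration
accuracy, validation accuracy) and per-stage stop reasons are recorded; a
non-finite loss aborts with the stage named.

**Baselines.** LDA (least-squares ridge fallback with automatic shrinkage
when calibration variables are collinear), KNN with k ∈ 3..20 chosen on
validation accuracy (ties to the smaller k), and an RBF SVM with C and γ
grid-searched over integer powers of ten in [1e−8, 1e8] by stratified 5-fold
cross-validation on the calibration set (ties to the smaller pair). All
three wrap scikit-learn.

## Evaluation and interpretation

Accuracy is 100·correct/total, reported at two decimals with half-up
rounding. Confusion matrices count rows = true class, columns = predicted.
Saliency is the absolute gradient of the target class's pre-softmax score
with respect to each input pixel, computed in eval mode by the same backward
machinery as training; per-origin maps average the saliency of all
prediction-set spectra of that origin at their true class, and the pixel
ranking maps to wavelengths through the matrixization bijection. t-SNE
layer views embed a named layer's activations (spatial axes averaged,
channels kept as features — a collapsed-to-scalar alternative cannot feed
t-SNE), PCA-reduced to 12 dimensions, perplexity 30 (clamped below n/3 for
small inputs), PCA initialization, fixed seed.

## Synthetic data

No public LIBS survey of this design exists, so the generator emulates one:
emission lines as Gaussian peaks (σ = the line's width; Lorentzian
optional) at ~44 fixed centers including the printed Ca (612.30, 616.38,
854.29 nm) and H (656.28 nm) lines, on a uniform axis over 229–878 nm. Line
strengths factor as origin multiplier × per-plant log-normal jitter ×
part-specific factor (aerial Ca ×1.5, aerial H ×0.1, mirroring the
observation that calcium is stronger and hydrogen nearly absent in aerial
tissue). A configured fraction of channels (default 85%), those farthest
from any line in width units, are designated baseline and carry only
|N(0, 1e−4·noise_sd)| — a planted ground truth for the SD filter. Spectra
add Gaussian channel noise, clipped at zero. Seeded runs are bit-exact.

The full-survey design reproduces the counting arithmetic: 12 origins, ten
plants each except origin 2 with eight, both parts, one tablet per
plant-part, 16 positions — 236 tablets, 3,776 spectra, V = 22,015. Origin
profiles there are log-normal effects (scale 0.35) on nutrient-element
lines only; matrix-element lines (C, H, N, O, CN, C2) are common to all
origins, as every sample is the same species.

The reduced fixture used by the end-to-end tests is deliberately small and
strongly separable: V = 1,200 (an 8×150 spectral matrix at h = 150), two
plants per origin, 8 positions, noise SD 0.003, and Hadamard sign-pattern
"signature" profiles — each origin's discriminative lines scaled by
exp(±1.0) with signs from distinct Hadamard rows, so all origin pairs are
equidistant. This structure was chosen after observing that independent
log-normal profiles can leave two origins nearly collinear after area
normalization, which makes a "separable fixture" claim false by accident.
Effect sizes here are harness conditions, not estimates of real
between-origin differences: passing tests show the pipeline recovers
planted signal under favorable conditions, not that real origins are
separable at these rates. Realism gaps of the generator: uniform (not
echelle) wavelength grid, no self-absorption, Stark broadening, matrix
effects, baseline drift, or correlated noise.

## Problem sizes in the test suite

Unit tests run on toy arrays. The stochastic recovery suite uses the
reduced fixture across 20 fixed seeds: the h=150 2-D CNN trained with the
reference staged schedule (expected pass: ≥18/20 seeds at ≥90%
prediction-set accuracy, and planted wavelengths in the top 1% of the
origin-averaged saliency ranking for ≥3/4 of origins in ≥18/20 seeds), and
the RF eliminator at 10 rounds (expected: all planted channels survive to
the best-OOB round in ≥90% of replicates). The elimination-schedule
quantities (325 and 277 retained variables) are exact arithmetic and are
also what `scripts/acceptance.py` recomputes.

## Known limitations

- Validation in the few-tablet design shares tablets with calibration (see
  above); only the prediction set measures tablet-level generalization.
- The numpy CNN stack is CPU-bound and single-threaded beyond BLAS; it is
  sized for the fixture geometries, not for 146×150 matrices at thousands of
  spectra.
- `knee` SD-filtering assumes a hockey-stick SD curve; datasets without a
  silent-channel population need `threshold` or `keep_top`.
- Bit-exact rerun reproducibility holds per machine/BLAS build; across
  builds, float32 reductions may differ in the last ulp.
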