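# Methods

## Problem and model

A synthetic CT (sCT) is judged by its voxel-wise HU agreement with the
ground-truth CT it replaces. `sctqa` predicts, from the sCT alone, the
per-axial-slice mean absolute error

MAE(slice i) = (1/n) Σⱼ |GTⱼ − sCTⱼ|,

where j runs over the n pixels of the slice. The predictor is a cascade:
a 4-class MAE-interval classifier followed by four interval-specific
regressors. The intervals are the quartiles of the training-label
distribution (balanced classes by construction); the regression training
ranges are the classification bins relaxed by ±5 HU and clamped to
[0, saturation], so a slice misclassified into a neighboring bin still
lands in a regressor whose training range contains its true MAE. The
high bin is closed by saturating all labels (and, at evaluation time,
all predictions) at an upper bound; by default the maximum observed
label rounded up to the nearest 10 HU, or set explicitly in config.

Conventions chosen where the arithmetic needed pinning down:

- Quantiles use linear interpolation between order statistics, rounded
  to the nearest integer HU for classification boundaries.
- Classification bins are half-open [bₖ, bₖ₊₁); the boundary value
  belongs to the upper bin; the last bin is closed at saturation.
- Regression ranges are closed intervals; membership at an endpoint
  counts.
- Classifier argmax ties go to the lowest class index.
- Cascade output is clipped to [0, saturation].

## Estimators and training

Estimators are convolutional networks running on a compact numpy engine
written for this package (im2col convolution, 2×2 pooling, dense layers,
softmax cross-entropy / MSE, Adam with separate L1 and L2 penalties on
weights — biases excluded). Two backbones ship:

- `tiny`: three conv blocks (8/16/32 channels, 3×3 kernels, average
  pooling) and a 64-unit dense head on 32×32 inputs. Average pooling is
  used deliberately: estimating an error *amplitude* is an averaging
  problem, and mean-preserving downsampling carries that signal to the
  head far better than max pooling.
- `vgg16`: the classic 13-conv + 3-dense topology with a width
  multiplier, for full-scale images; constructible and tested
  structurally, not trained at desk scale.

Inputs are resampled to the backbone size, windowed to [−1000, 2000] HU
(air through dental metal) and mapped to [0, 1]. Regression targets are
affinely mapped from the bin's relaxed range to [0, 1] and inverted at
inference; this keeps all regressors on the same loss scale.
Augmentation is horizontal mirroring plus random translations with air
padding, applied to the input only (the scalar label is kept; slices
are surrounded by air and shifts are small). The default translation
limit is ±8 px; desk-scale 32×32 runs use ±2 px, the same fraction of
the field of view.

The classifier's checkpoint is the epoch maximizing the validation
*distance-weighted accuracy* 1 − Σ|ĉ−c|/(N·(K−1)), not the minimal
cross-entropy: a 1-class error is recoverable by the relaxed regression
ranges, a 3-class error is not, and epoch selection should reflect
that. Regressor checkpoints minimize validation MSE. Splits
(75/10/15) and the optional k-fold (default k = 5) are at patient
level; slice-level splits would leak near-duplicate adjacent slices
between partitions.

Default hyperparameters follow the reference recipe: learning rate
5·10⁻⁵, L1 = L2 = 4·10⁻⁴, batch 32, 100 epochs. For the desk-scale
tiny backbone the tests and examples use their own recipe — learning
rate 3·10⁻³, no weight penalties, batch 16 — because a three-block net
with a few hundred training slices sits in a very different
optimization regime than a full VGG-16 on clinical cohorts: at 5·10⁻⁵
it does not converge within a reasonable epoch budget, and penalties of
4·10⁻⁴ overwhelm the small MSE gradients and collapse the output to
the label mean. The defaults remain the full-scale values; the desk
recipe is a config choice, not a code path.

## Phantoms

The phantom module generates head-like axial anatomy: an elliptical
soft-tissue body (40 HU) with a skull rim and a jittered interior bone
blob (700 HU) on an air background (−1000 HU), with randomized air
cavities that are more frequent near the cranial/caudal ends — the
analogue of nasal cavities, where real sCTs err most. The pseudo-sCT
adds a zero-centered error texture supported on body pixels
(GT > −500 HU), normalized to mean(|field|) = 1 over the slice and
multiplied by the requested per-slice MAE, so the achieved slice MAE
equals the request to floating-point precision. Peak field magnitude
is capped at 8× the slice mean, which keeps corrupted volumes inside
the valid CT range [−1024, 3071] HU for targets up to ~130 HU.

Two corruption styles support the modality experiments in miniature:
`CBCT` (short-range Gaussian-correlated noise plus a directional
sinusoidal streak component) and `MR` (a long-range smooth bias field);
they differ clearly in spatial autocorrelation. The level sampler used
for separability experiments deals its levels in balanced proportions
with a small jitter, so quartile binning on such a corpus places
boundaries between the levels.

What the phantom does *not* emulate: real scatter/beam-hardening
physics, anatomy-correlated conversion failures, registration residuals,
or any dependence of error texture on local anatomy. Passing phantom
tests therefore demonstrates that the pipeline's machinery —
labeling, binning, routing, training, evaluation — is correct and that
the estimators can recover a visible amplitude signal; it does not
certify accuracy on clinical sCTs.

## Evaluation

Per slice, PD = MAE_GT − MAE_pred and APD = |PD|, both after saturating
the two MAE values at the scheme bound. Summaries report the median and
the 5th/25th/75th/95th percentiles (linear-interpolation quantiles).
The experiment matrix runs exactly four experiments — CBCT→sCT_CBCT,
MR→sCT_MR, MIXED→sCT_CBCT, MIXED→sCT_MR — and two comparisons
(each single-modality pipeline vs MIXED on the matching test set),
using the two-sided Wilcoxon rank-sum test on per-slice APD: exact
enumeration for tie-free samples of ≤25 per group, otherwise the
normal approximation with tie correction. The rank-sum form is used as
named even though the compared predictions are paired per slice; no
multiple-testing correction is applied to the two p-values. Slices
whose GT body fraction (pixels > −500 HU) is below 2% are excluded from
corpora by default: all-air slices carry near-zero MAE and no anatomy.

## Problem sizes and determinism

Desk-scale runs use 32×32×(12–20) phantoms, 6–20 patients and 25–150
epochs; the end-to-end recovery experiment trains on 8 patients of
32×32×20 with labels spanning [0, 100] HU and evaluates on a held-out
cohort, reaching median APD below 10 HU with |median PD| within 5 HU.
Every stochastic stage (phantom anatomy, corruption, splits, shuffling,
augmentation, initialization) is driven by explicit seeds; inference is
deterministic. Training is seeded-stochastic: a fixed seed reproduces
the training log bit-for-bit on the same platform.

## Known limitations

- The HU-validity clamp in labeling ([−1024, 3071]) means volumes with
  sentinel values outside that range are silently repaired (with a
  warning); phantom volumes are constructed to stay inside it.
- Saturation is applied before binning; if a deployment saturates after
  binning, boundaries near the cap can differ by a rounding step.
- The numpy engine is single-threaded per operation and intended for
  desk-scale training; full-resolution VGG-16 training requires a GPU
  framework implementation of the same contracts.
- Voxel-level error maps are out of scope: the method predicts one
  scalar per axial slice.
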