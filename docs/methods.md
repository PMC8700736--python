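# Methods

## Model and assumptions

`octfuse` is a feature-engineering classifier for grayscale images, built
around three ideas: (i) a single pooled statistic loses information (the
"routing problem"), so three block statistics — max, max of column means,
max of column minima — are propagated in parallel; (ii) frozen pre-trained
networks are cheap, diverse feature generators whose usefulness for a new
task can be *measured* (by cross-validated classifier loss) rather than
assumed; (iii) instance-based feature weighting (ReliefF) plus an explicit
subset-length sweep (iterative ReliefF) picks a compact final feature set
for a quadratic-kernel SVM.

The pipeline assumes images are 2-D intensity matrices (color inputs are
collapsed by channel averaging), at least 12×12 so the third-level carrier
still admits one 3×3 block, with finite intensities. Labels are categorical
with every class represented at least `folds` times wherever stratified CV
is used.

## Pooling decomposition

Blocks are k×k and non-overlapping; when a side is not divisible by k the
partial edge blocks are **discarded** (floor semantics: output shape
⌊H/k⌋×⌊W/k⌋). This is the simplest deterministic convention consistent with
non-overlapping tiling, and it makes the shape law exact for property
testing. Within-level pooling uses k = 3; carrier downsampling between
levels uses plain max pooling with k = 2, applied recursively to the
current carrier (not to the original image). Intensities are treated as
reals throughout — no integer re-quantization between levels.

Max-mean and max-min pooling are defined as the maximum over the block's
*per-column* statistics. An alternative narrative reading — route the
column containing the global maximum, then take its mean/min — agrees on
blocks where the globally-maximal column also has the maximal column
statistic (e.g. the worked block with middle column 8, 9, 25 → 14 and 8)
but disagrees elsewhere; the per-column-statistic definition is normative
here, and a dedicated test pins the distinguishing input (columns
(30,0,0), (12,12,12), (0,0,0) → 12, not 10).

## Feature extraction

A `FeatureExtractor` is a named deterministic map image → ℝ^D. The 18
classical ImageNet CNN slots (ResNet18 … VGG19) are registered by name and
resolve only when an optional torch/torchvision backend is importable;
otherwise they raise an explicit "unavailable" error. Images reaching a
CNN are resized to its native input by bilinear interpolation and
grayscale is replicated to three channels; D defaults to 1000 (the final
fully-connected layer). The library's own tests and examples use mock
extractors exclusively, so no weights are ever downloaded.

The fused vector per image is the concatenation of the extractor applied
to the original image (segment 0) and to c1…c9 (segments 1–9): length
10·D. Column provenance (extractor, segment, within-segment index) is
recorded on every matrix and carried through selection and fusion, so any
surviving feature can be traced to its source image scale.

## ReliefF and IRF

Hyperparameters the original formulation leaves open are fixed as the
conventional defaults: k = 10 nearest neighbours (exposed as a parameter,
smaller in desk-scale tests), all n instances sampled (m = n), Manhattan
distance on range-normalized features, miss contributions weighted by
P(C)/(1 − P(class(instance))). Constant features have zero range; their
diff is defined as 0, so their weight is exactly 0. Weights therefore lie
in [−1, 1]. Ties — equal distances during neighbour search, equal weights
during ranking, equal losses during the IRF sweep — always break toward
the smaller index/length, making every stage reproducible.

IRF ranks **once** on the input matrix and then scores every prefix length
in `[range_lo, range_hi]` with unit step (so a [100, 1000] sweep evaluates
exactly 901 candidates) using the supplied loss function, by default the
stratified 10-fold CV misclassification rate of the quadratic SVM.
Re-ranking per candidate would change nothing for prefix subsets and would
multiply cost by the range width.

## Classifier and metrics

The SVM is scikit-learn's `SVC` with a degree-2 polynomial kernel,
`C = 1`, `coef0 = 1`, one-vs-one multiclass, preceded by training-set
standardization. "Auto" kernel scale is implemented as
γ = 1/(p·Var(X_train)) (scikit-learn's `gamma="scale"`), i.e. the kernel
(γ·x·z + 1)²; after standardization the mean feature variance is ≈ 1, so
γ ≈ 1/p. Zero-variance features are left centered (not rescaled) and
logged. Fold assignment is stratified with an explicit seed; the fold
count is configurable (10 by default, with a hold-out split as the
alternative final-evaluation scheme — both produce reports with identical
schema).

Accuracy, macro-averaged precision/recall/F1 (macro chosen because the
reference results are consistent with equal class weighting under balanced
classes), Cohen's κ and the multiclass Matthews correlation coefficient
are reported ×100 on a single scale. Predicted labels outside the truth
universe are an error, not an extra confusion column. The feature t-tests
use Welch's unequal-variance form (a deliberate choice where only
"Student's t-test" is specified); features degenerate in both groups of a
pair report p = 1.

## Synthetic data and what it shows

The generator emulates the one property of retinal OCT that the
decomposition exploits — bright quasi-horizontal layers — as per-class
vertical sinusoids (class-specific frequency 3/6/10/15 cycles and phase)
under multiplicative Gaussian speckle, min-max rescaled to [0, 1].
Rescaling rather than clipping keeps intensities continuous; saturation
would make pooled blocks bit-identical across images of a class and leak
label information to *any* deterministic extractor, including the noise
mock. It does not model real speckle statistics, lesions, or acquisition
artifacts, so passing tests demonstrate the pipeline's selection and
fusion machinery, not clinical performance.

Mock extractors: the *informative* kind summarizes a 32×32 bilinear
resize by 8 row-band, 8 column-band and 8 vertical-gradient-band energies,
a 16-bin histogram and 4 global moments, projected to D dimensions by a
fixed seeded Gaussian matrix; the *noise* kind emits a pseudo-random
D-vector seeded by a BLAKE2 digest of the image content — deterministic
per image, independent across images, hence chance-level CV loss.

## Desk-scale study conditions

The recovery experiment uses 90 images (3 classes × 30, σ = 0.15, seed 1),
six mock extractors (three informative, three noise, D = 16), n_keep = 40,
IRF range [10, 60], ReliefF k = 5, 10-fold CV. These sizes keep the full
suite under a minute of pipeline time while leaving every stage
non-trivial (160 → 40 → 200 → best-length columns). Under these conditions
the pipeline recovers the informative extractor subset exactly and
classifies at 100% CV accuracy.

## Known limitations

- ReliefF is O(n²·p); fine for desk-scale n, slow for n in the tens of
  thousands without subsampling (the `m = n` choice is then the knob).
- Per-extractor ReliefF selection and the IRF sweep are computed on the
  full matrix before cross-validation, mirroring the reference protocol;
  this risks selection bias under CV. `PipelineConfig(fold_safe=True)`
  removes the final stage's leakage by re-ranking the fused features
  inside each training split (keeping the IRF-chosen subset length); the
  earlier per-extractor selection and the length choice itself remain
  full-matrix, so the flag bounds, not eliminates, the optimism.
- The Bayesian SVM hyperparameter search of the original design is
  replaced by its fixed selected hyperparameters (quadratic kernel, C = 1,
  standardize, auto scale).
- CNN backends are unexercised by the test suite; their preprocessing
  (resize + channel replication + [0,1] scaling) is deliberately minimal.
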