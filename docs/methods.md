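# Methods

`adstage` implements a four-phase analysis of 2D brain slices for
Alzheimer's staging — whole-brain segmentation, gray-matter (GM)
segmentation, hybrid stage classification, and saliency-based explanation —
and validates every phase on synthetic phantoms with exact ground truth.
This note records the models, the parameters that matter, the numerical
choices, and what the phantom experiments do and do not demonstrate.

## Phantom model

A phantom emulates an axial T1-like slice as five concentric elliptical
regions: background (intensity 0), skull rim (0.90), CSF (0.15), a
gray-matter ribbon (class-dependent intensity), and a white-matter core
(0.80), plus a central CSF-filled elliptical ventricle (aspect ratio 0.6).
Ring radii are fractions of the image side (skull outer 0.46, skull
thickness 0.04, CSF thickness 0.03), so geometry scales with resolution;
`ring_radii` exposes the resolved values.

The two classic structural biomarkers of the disease are built in as class
effects. At the 224 px reference resolution:

| class | GM thickness (px) | GM intensity | ventricle radius (px) |
|-------|------------------|--------------|----------------------|
| CN    | 9                | 0.55         | 6                    |
| MCI   | 7                | 0.50         | 8                    |
| AD    | 5                | 0.45         | 11                   |

so the cortical ribbon thins and dims while the ventricle enlarges from
cognitively normal to Alzheimer's. Other resolutions scale these linearly
(with small floors so structures stay resolvable at 64 px, the size used by
the scaled-down experiments). Per-sample variation is a uniform ±3% jitter
of the x/y ellipse axes plus a small center offset; noise is additive
Gaussian with sigma 0.02 clipped to [0, 1]. These effect sizes are design
choices, not estimates from clinical data: they are deliberately strong so
that CPU-scale training converges, and no quantitative claim about real
MRI follows from recovering them. Per-sample seeds are
`global_seed + record_index`, giving order-independent reproducibility.

What the phantoms deliberately lack: 3D anatomy, cortical folding, partial
volume effects, bias fields, Rician noise, and inter-subject anatomical
variability. Passing the recovery tests therefore shows the implementation
is correct and the pipeline wiring is sound — not that the architecture
would reach any particular accuracy on clinical data.

## Preprocessing

- **Middle-slice selection**: keep the middle fraction (default 40%) of a
  volume's axial slices; the count is round-half-up of `fraction * n` (at
  least 1) and the window is floor-centered. The fraction is the stated
  recipe; the rounding and centering rules are our own convention.
- **Normalization**: bilinear resize to a square (default 224), then
  per-slice min-max scaling to [0, 1]. A constant slice maps to zeros
  (divide-by-zero guard).
- **Augmentation**: expansion of a class to an exact target count by a
  rotation drawn from U(−7°, +7°) composed with a zoom from U(0.9, 1.1),
  bilinear interpolation, zero fill; source images are cycled in order so
  the expansion is balanced, and the originals are always kept. Augmenting
  is applied to the *training split only*: expanding before the split would
  place near-copies of a training slice in the test set and inflate
  accuracy. (This ordering is the defensible one even where descriptions of
  such recipes leave it ambiguous.)
- **Split**: stratified 60/20/20; per class the validation and test counts
  are round-half-up of their ratios and the remainder goes to training.

## Segmentation

Both segmenters come from one encoder–decoder builder. Encoder level *i*
applies two same-padded 3×3 convolutions with ReLU and a 2×2 max-pool; the
bottleneck is another double convolution; decoder level *i* upsamples with
a 2×2-stride-2 transposed convolution, concatenates the mirror encoder
feature (upsampled tensor first), and applies a double convolution; a
final 1×1 convolution with a sigmoid produces the foreground probability.
The *vanilla* variant (depth 4, filters doubling from a base of 32 at full
scale) segments the whole brain; the *multi-layer* variant (depth 3, skip
connection at every level) segments the gray-matter ribbon. Filter counts
beyond "three encoder/decoder layers" are our choice (base 32, doubling).

**Balanced cross-entropy.** Background dominates a slice, so the loss
weights the foreground term by β and the background term by 1−β:

    L = mean over pixels of [ −β·y·log(p) − (1−β)·(1−y)·log(1−p) ]

With `beta="auto"` (default), β is the background-pixel fraction of the
training masks (clipped to [0.01, 0.99]): the rarer the tissue, the larger
its weight. Predictions are clipped to [1e-7, 1−1e-7] before the logs. A
Dice loss `1 − (2Σpy + 1)/(Σp + Σy + 1)` is available as the alternative
objective (smoothing constant 1).

**Training.** Adam, batch size 8; the reference recipe is 100 epochs at
learning rate 1e-4. The scaled-down phantom experiments (150 training
slices at 64 px, 15 epochs) use learning rate 1e-3 — the same optimizer
budget argument in reverse: a tenth of the epochs warrants roughly ten
times the step size, and phantoms are far easier than clinical data. The
checkpoint kept is the epoch with the best validation Dice. Prediction
thresholds probabilities at 0.5.

**Metrics.** Dice, IoU, accuracy, precision, recall, F1 from the
foreground confusion counts. Dice and F1 are the same number
(2TP/(2TP+FP+FN)) and Dice = 2·IoU/(1+IoU); both identities are tested.
Ratios with empty denominators are 1 when prediction and truth agree
exactly and 0 otherwise.

**Neural-network core.** No deep-learning framework is used: layers are
NumPy float32 in NHWC layout with hand-written backward passes, verified
against finite differences. Convolutions are evaluated as a
shift-and-accumulate sum of k² channel-mixing matmuls, which on CPU avoids
materializing an im2col patch matrix. Max-pool ties resolve to the first
element in row-major order. Input gradients are first-class (saliency
needs them).

## Classification

The backbone is pluggable behind a three-attribute protocol (`input_size`,
`in_channels`, `out_channels` + `forward`/`backward`). The reference
backbone in this family of pipelines is a pretrained EfficientNet-B0 final
convolutional stage (1280 channels, stride 32); the package's concrete
default is `SmallCNNBackbone`, a compact random-initialized CNN with the
same contract, which keeps the package self-contained. On phantoms its
random convolutional features are already highly discriminative, so frozen
random features are sufficient for the recovery experiments.

The multi-scale head runs three parallel branches over the shared feature
map — same-padded convolutions with 3×3, 5×5 and 7×7 kernels (128 branch
channels at full scale, 64 in the scaled-down experiments), LeakyReLU
(slope 0.01), 2×2 max-pool, adaptive average-pool to 1×1, dropout 0.3
(training only) — and concatenates them into a feature vector of length
3 × branch_channels. A linear softmax layer on this vector trains the head
by categorical cross-entropy (Adam, lr 1e-4 reference / 1e-3 scaled-down,
batch 32). The single-scale ablation variant is the same class with one
3×3 branch.

**SVM.** Feature vectors are standardized (scaler fitted on training data
only; constant dimensions keep scale 1). The binary decision rule is the
RBF kernel sum `f(x) = sign(Σ_i α_i y_i exp(−γ‖x_i − x‖²) + b)`; the
multi-class extension is one-vs-rest with argmax over per-class decision
values, chosen because it also exposes exactly the per-class continuous
scores the one-vs-rest ROC analysis needs. γ tokens follow the standard
convention: "scale" = 1/(d·var(X)), "auto" = 1/d. Grid search evaluates
every cell of kernels {rbf, linear} × C {0.1, 1, 10} × gamma
{scale, auto} by stratified 5-fold cross-validated accuracy; the table is
sorted descending with ties broken by the documented grid order (rbf
before linear, larger C first, scale before auto), making the winner
deterministic. The best cell is refitted on all training data. Support
vectors, dual coefficients, bias and γ are exposed per class so the
decision values can be reproduced from stored parameters alone (and are,
in the tests).

**Evaluation battery.** Accuracy, one-vs-rest per-class
precision/recall/F1, 3×3 confusion matrix (true classes as rows); ROC per
class over all score thresholds with trapezoidal AUC and the optimal
operating threshold as argmax(TPR − FPR), taking the smallest qualifying
threshold on ties; McNemar's test on paired predictions,
statistic (b−c)²/(b+c) without continuity correction (the corrected
variant is available behind a flag), referred to chi-square with 1 df,
degenerating to (0, p=1) when b+c=0. An undefined per-class AUC (class
absent) is reported as missing, never as 0.

## Saliency

Saliency is |∂(class score)/∂pixel|, maximum over input channels,
normalized per map by its own maximum (a zero map stays zero; per-map
rather than per-batch normalization because brightness statements are
per-image). Gradients flow through the differentiable path — backbone,
multi-scale head, softmax layer — never through the SVM, whose sign
decision has zero gradient almost everywhere; passing an SVM raises an
error that points to the head-based path.

Overlays Gaussian-blur the map (sigma 2 px default), optionally add a
Sobel edge map of the slice, and tint the predicted class's color channel
(AD red, MCI blue, CN green) over the grayscale slice. Quantification
divides each map into four equal quadrants, numbered row-major from the
top-left, and averages per class; for even image sides the unweighted mean
of the four region means equals the global mean exactly.

## Pipeline and reproducibility

`run_pipeline` executes the stages generate → preprocess → train-seg →
train-clf → evaluate → explain for each seed in the configured list
(default 42–46, 5 repeats), under a run directory holding the config
snapshot, a log, per-seed artifacts, and a `summary.csv` of per-metric
mean ± sample standard deviation. The summary content is a pure function
of config and seeds; two identical runs produce byte-identical summaries,
and this is tested. All randomness flows from explicit seeds through NumPy
generators.

## Problem sizes of the bundled experiments

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so the whole battery completes in minutes on one CPU while leaving
comfortable margins on the recovery properties: segmentation uses 180
phantoms at 64 px (150 train / 30 val, 15 epochs multi-layer, 6 epochs
vanilla); classification uses 300 phantoms per class (60/20/20 split, 5
head epochs) for the accuracy check and 60 per class across 5 seeds for
the multi-scale-vs-single-scale direction; saliency checks 5 seeds at 40
per class; the determinism check runs the full pipeline twice at 15 per
class, 32 px. Typical results at these scales: gray-matter validation
Dice ≈ 0.97, whole-brain Dice ≈ 0.99, test accuracy 1.0 (the phantom
classes are strongly separated by construction), GM-to-background saliency
ratio ≈ 6.

## Known limitations

- Phantom geometry is radially symmetric; quadrant saliency tables are
  therefore nearly uniform within a class, unlike real cortical anatomy.
- The default backbone is random-initialized; transfer-learned features
  would be needed for any claim about real MRI.
- The pure-NumPy networks are single-threaded CPU code; they are sized for
  64–224 px 2D slices, not volumes.
- `balanced_cross_entropy` requires β strictly inside (0, 1); the limiting
  behavior at β=1 (background term vanishes) is approached continuously
  but the endpoint itself is rejected as a parameter error.
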