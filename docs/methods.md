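# Methods

## The model

`noseleaf` implements a fine-grained image classifier for seven horseshoe-bat
(*Rhinolophus*) taxa whose discriminative evidence is a small facial key
region (the noseleaf). The network is a VGG16 backbone with batch
normalization after every convolution, modified in three ways:

1. **Residual attention blocks.** After the third and fourth max-pooling
   stages a block computes `ReLU(x + CBAM(Conv7x7(x)))`, at 256 and 512
   channels respectively. The convolutional block attention module (CBAM)
   applies channel attention — global max- and average-pooled descriptors
   through one shared bottleneck perceptron `C -> C/r -> C` (ReLU inside, no
   biases), summed, sigmoid — and then spatial attention — per-pixel channel
   max and mean, concatenated, convolved 7x7 to one channel, sigmoid. All
   attention weights are strictly in (0, 1) and multiply the feature map
   elementwise. The identity skip keeps a direct gradient path around the
   attention arm.
2. **Convolutional head.** VGG's three fully connected layers are replaced
   by a 1x1 convolution (512 -> 1024), ReLU, global average pooling, and a
   single affine map to the class scores, with softmax at inference. This is
   what shrinks the network to 31,353,869 trainable parameters, 22.7% of the
   1000-class reference VGG16-BN (138,365,992).
3. **Full convolutionality.** Up to global average pooling the network has
   no fixed spatial size; any input of at least 32x32 (so five halvings
   leave >= 1 pixel) yields the same number of class scores.

Conventions that pin the parameter count to the published "31.35 M":
attention perceptrons carry no bias terms, the spatial-attention convolution
does, the residual-block convolutions carry biases, and neither the blocks
nor the head contain normalization layers. The bottleneck ratio `r`
defaults to 16; the residual-block kernel is 7x7 (a 3x3 reading would give
~18.3 M parameters, inconsistent with the published size).

### Compute accounting

`count_macs`/`layer_budget` count one multiply–accumulate per kernel element
per output element of every convolution and affine layer; pooling,
normalization and activations are excluded. The default model at 224x224
costs 20,407,767,848 MACs (2.041e10). Published "FLOPs" figures mix 1x and
2x MAC conventions between rows, so the package standardizes on MACs and
reports the convention explicitly.

## The numerical engine

The layers run on a small reverse-mode automatic-differentiation engine
(`noseleaf.nn`) over NumPy float32 arrays. Convolution is im2col plus one
BLAS matmul; the column matrix is recomputed in the backward pass rather
than stored, halving peak memory. Max pooling uses non-overlapping windows
with floor semantics; gradient at ties is split equally. Batch
normalization uses batch statistics in training mode (running buffers
updated with momentum 0.1, unbiased variance) and the running buffers in
eval mode. The cross-entropy used in training is computed from
log-softmax — mathematically identical to `-sum(y_k log f_k)` on the
softmax probabilities but stable for saturated scores. Float64 inputs are
propagated in double precision end to end, which is how the test suite runs
cancellation-free central-difference gradient checks against every
primitive.

Weight initialization is He-uniform for convolutions and affine maps, zeros
for biases, ones/zeros for batch-norm scale/shift, drawn from a generator
seeded per model build. With fixed seeds and a single BLAS thread, training
is bit-reproducible.

## Training

Plain SGD, `theta <- theta - lr * grad`, optional momentum (default 0).
The learning rate starts at 0.01 and is multiplied by 0.75 every 20 epochs
(`lr0 * 0.75^floor(epoch/20)`); "every 20 epochs the rate becomes 0.75 of
its value" is the interpretation adopted for the reported schedule, rather
than a one-time reset to 0.0075. Batch size (32), epoch budget (100) and
momentum (0) are package defaults where no values were reported. Per-epoch
records (lr, training loss, training accuracy, optional held-out accuracy)
form the loss/accuracy curves; the best-scoring weights are retained. When
no validation split exists the test split may be used for per-epoch
monitoring, with a leakage warning in the log.

K-fold cross-validation splits a manifest stratified by class: folds are
pairwise disjoint, cover every record, and per-class fold sizes differ by
at most one.

## Dataset bookkeeping and augmentation

A `DatasetManifest` (pandas-backed CSV: `path,label,split,provenance,
source_path`) is the single source of truth for accounting. The published
study's numbers are reproduced as plain manifest arithmetic: 879 originals
with per-class counts 89/176/91/127/56/190/150, an explicit per-class test
map (30/59/30/42/20/62/50, totalling 293; the printed counts follow no
single rounding rule, so exact reproduction requires the explicit map),
and per-class augmented-copy counts that grow the training split from 586
to 1280.

Augmentation operators (all deterministic per seed, all on 8-bit RGB):

- **GridMask** — unit size `d` drawn from a configured range, grid phase
  uniform in `[0, d)`; within each unit only a `ceil(k*d)`-sided square
  survives, so the masked fraction approaches `1 - k^2` (64% masked at the
  default k = 0.6).
- **Row blackout** — rows at 0-based indices `period-1 (mod period)` set to
  black (the 4th, 8th, ... rows for the default period 4).
- **Gaussian noise** — i.i.d. per channel, std `sigma * 255` (default
  sigma 0.05), clipped and requantized.
- **Red-channel rotation** — only the red plane rotates about the center
  (default 45 deg, counterclockwise, bilinear, zero fill); right angles are
  exact index permutations.
- **Gaussian blur** — per-channel, reflective borders, default sigma 1.
- **Resize/standardize** — bilinear to 224x224, scaled to [0,1], channel
  standardization. The configurable mean/std default to the ImageNet
  statistics; `dataset_statistics` computes a dataset's own statistics,
  which is the appropriate choice when training from random initialization
  (it also keeps a dark background at ~0, the value convolutional zero
  padding uses, avoiding border saliency artifacts).

Each augmented copy applies a seeded random subset of the operator stack
(at least one operator); the chain is recorded in the output filename and
the source image in `source_path`. Test images are never read or extended,
so the augmented-source set is disjoint from the test split by
construction.

## Synthetic data

The generator emulates the structural properties of the study's
photographs that the toolkit needs to be testable without downloads: a
dark noisy background (mean 20, sigma 8 of 255 — the black-background
photography protocol), one bright procedural glyph per image
(ellipse/triangle/crescent/cross/ring/bars/diamond families, one family
per class, intensity 160–235) whose half-open bounding box is recorded,
position jitter of 12% of the image side, glyph sizes of 30–48% of the
image side, and the published class-imbalanced counts by default.
`inter_class_similarity` interpolates every class's glyph geometry toward
a common prototype (0 = maximally distinct). Generation is
bit-deterministic per seed.

What the generator does *not* emulate: photographic texture, pose and
viewpoint variation, within-class morphological variation, illumination
changes, or any actual bat anatomy. Passing tests therefore demonstrate
that the pipeline (architecture, optimization, metrics, saliency) is
correct and that the model can discover and localize a planted
discriminative signal — not that it reaches any particular accuracy on
real photographs.

## Evaluation

Confusion matrix (rows true, columns predicted; argmax ties break to the
lowest index), accuracy = trace/total, one-vs-rest precision/recall/F1 per
class, macro-F1 as their unweighted mean. Degenerate 0/0 ratios are
reported as 0 with a flag rather than raised. Percentages destined for
tables round half-up to two decimals. ROC curves and AUC (trapezoidal) use
scikit-learn one-vs-rest; the multiclass aggregation default is
micro-average, with per-class and macro modes available. AUC is verified
in the tests against brute-force Mann–Whitney pair counting.

## Grad-CAM

Saliency for class `c` at a chosen convolutional layer: channel weights
are the spatial means of `d(score_c)/d(activation)` taken at the
pre-softmax score; the map is `ReLU(sum_k w_k A_k)`, min–max normalized
over the single image, bilinearly upsampled to input resolution. The
softmax probability of the explained class is recorded from the same
forward pass. A raw map that is nowhere positive yields a flagged all-zero
heatmap. Normalization makes the map invariant to positive rescaling of
the class score (verified against a closed-form oracle on a linear-head
toy model).

The localization score reports the fraction of heatmap mass inside a
ground-truth box and whether the argmax pixel falls inside.

## Problem sizes used by the test suite

The NumPy engine on one CPU core sustains roughly 40–90 GFLOP/s through
the conv layers, so the self-contained training checks run at reduced
resolution, chosen once:

- **Overfit smoke check:** the full VGG16-CBAM trains on 70 synthetic
  images (7 classes x 10) at 80x80 — the smallest size at which the
  deepest feature map before pool 5 is still 5x5 — batch 8, seeded,
  stopping once training accuracy reaches 99.5%. It reaches 100% within
  ~5 of the allowed 30 epochs, in a few minutes.
- **Saliency localization:** on 50 freshly generated held-out images, the
  argmax of the Grad-CAM heatmap is scored against the planted glyph box
  at the *full-resolution* layer (`stage1.conv2`). Deeper maps cannot
  support point-localization against a tight mask-derived box at this
  scale: after five-fold pooling a cell spans 16 px while box sides are
  ~15–40 px, and the peak cell's center regularly sits just outside the
  box even when the mass is concentrated on the glyph. The deep default
  layer (`stage5.conv3`) is therefore scored by mass enrichment instead —
  heatmap mass inside the box relative to the box's share of image area —
  which the acceptance check requires to exceed the uniform-heatmap null
  of 1 on average (measured ~1.6x on the smoke fixture).

## Known limitations

- Single-threaded CPU training only; no GPU, no mixed precision, no
  optimizer beyond SGD(+momentum). Wall-clock cost limits practical use to
  small images or small datasets.
- The reference VGG16-BN exists for parameter/MAC accounting and sanity
  forwards; it omits dropout (parameter-free) and is not intended for
  training.
- Pretrained backbone weights are not bundled; training starts from random
  initialization unless a checkpoint is supplied.
- ROC aggregation on heavily imbalanced test sets: micro-averaging weights
  samples, not classes; use the macro mode when class balance matters.
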