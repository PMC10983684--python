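# noseleaf

Fine-grained image classification of horseshoe bats (*Rhinolophus*) with an
attention-augmented VGG16, plus everything around it: dataset manifests and
augmentation, SGD training, multiclass evaluation, and Grad-CAM saliency
maps that show *where* the classifier looks. The package is aimed at
researchers who photograph morphologically similar taxa against a
controlled background and want a CPU-runnable, fully reproducible reference
pipeline — and at anyone who wants an exactly-accounted implementation of
the VGG16-CBAM architecture.

Horseshoe bats are a hard fine-grained problem: species differ by subtle
facial structures (the noseleaf — horseshoe, sella, lancet) rather than
by global appearance. The model addresses this with attention.

## The model

VGG16 with batch normalization, modified three ways:

- **Residual CBAM blocks** after max-pools 3 and 4 (256 and 512 channels):

      out = ReLU( x + CBAM( Conv_{7×7}(x) ) )

  CBAM refines a feature map `F` sequentially: channel attention
  `M_c = σ( MLP(avgpool F) + MLP(maxpool F) )` with a shared bottleneck
  perceptron `C → C/r → C` (r = 16), then spatial attention
  `M_s = σ( Conv_{7×7}([maxpool_ch F'; avgpool_ch F']) )`, each multiplying
  the map elementwise. The identity skip preserves a direct gradient path.
- **Convolutional head**: the fully connected stack is replaced by a 1×1
  convolution to 1024 channels, global average pooling, and one affine map
  to the K = 7 class scores (softmax at inference).
- Training: cross-entropy `L = −Σ_k y_k log f_k(x)` minimized by SGD
  `θ ← θ − α ∇L`, with α starting at 0.01 and decaying ×0.75 every 20
  epochs.

The size reduction is exact and testable: 31,353,869 trainable parameters
versus 138,365,992 for the reference VGG16-BN with its original classifier
— 22.7%. The network core runs on a small NumPy reverse-mode autodiff
engine included in the package (`noseleaf.nn`), so nothing beyond the
scientific Python stack is required.

## Worked example

Everything below runs CPU-only in a few minutes; no data downloads — the
synthetic generator plants a class-discriminative glyph on a dark
background (emulating the black-background photography protocol) and
records its bounding box, so saliency can be scored against ground truth.

```python
import numpy as np
from noseleaf.architecture import (ModelConfig, build_vgg16_cbam,
                                   count_macs, count_parameters)
from noseleaf.augmentation import dataset_statistics, resize_normalize
from noseleaf.evaluation import evaluate
from noseleaf.interpret import gradcam, localization_score
from noseleaf.synthetic import SPECIES, SyntheticSpec, generate_arrays
from noseleaf.training import TrainConfig, train

model = build_vgg16_cbam(ModelConfig(input_size=(64, 64)), init_seed=0)
print(f"parameters: {count_parameters(model):,}")
print(f"MACs at 224x224: {count_macs(model, (224, 224)):,}")

spec = SyntheticSpec(per_class_counts={c: 9 for c in SPECIES},
                     image_size=64, seed=0)
images, labels, boxes = generate_arrays(spec)
mean, std = dataset_statistics(images)
x = np.stack([resize_normalize(im, (64, 64), mean=mean, std=std)
              for im in images])
train_idx = np.flatnonzero(np.arange(len(x)) % 3 != 0)   # 42 train / 21 test
test_idx = np.flatnonzero(np.arange(len(x)) % 3 == 0)

result = train(model, (x[train_idx], labels[train_idx]),
               TrainConfig(epochs=25, batch_size=8, seed=0,
                           stop_at_train_accuracy=1.0))
print(result.log[["epoch", "lr", "train_loss", "train_accuracy"]]
      .tail(3).to_string(index=False))

report = evaluate(model, x[test_idx], labels[test_idx], class_names=SPECIES)
print(f"test accuracy {report.accuracy:.3f}  macro-F1 {report.macro_f1:.3f}  "
      f"micro AUC {report.roc['micro'].auc:.3f}")

i = test_idx[0]
row = boxes.iloc[i]
box = (row.x_min, row.y_min, row.x_max, row.y_max)
fine = gradcam(model, x[i], int(labels[i]), target_layer="stage1.conv2")
deep = gradcam(model, x[i], int(labels[i]))        # stage5.conv3
print(f"Grad-CAM P={deep.softmax_score:.2f}; peak inside glyph box: "
      f"{localization_score(fine, box).argmax_inside}; deep-layer mass in "
      f"box {localization_score(deep, box).mass_fraction:.0%}")
```

Output:

```
parameters: 31,353,869
MACs at 224x224: 20,407,767,848
 epoch   lr  train_loss  train_accuracy
     7 0.01    0.678962        0.738095
     8 0.01    0.238503        0.928571
     9 0.01    0.091473        1.000000
test accuracy 0.714  macro-F1 0.729  micro AUC 0.964
Grad-CAM P=0.37; peak inside glyph box: True; deep-layer mass in box 9%
```

Reading it: the constructed network has exactly the published parameter
budget ("31.35 M") and 2.04×10¹⁰ multiply–accumulates per 224×224 forward
pass. Ten epochs of seeded SGD memorize the 42 training images; on the 21
held-out images the model reaches 71% accuracy (chance is 14%) with a
micro-averaged one-vs-rest AUC of 0.96 — a tiny dataset, so the point is
the pipeline, not the score. The Grad-CAM peak falls inside the planted
glyph's bounding box, and the deep layer concentrates 9% of its saliency
mass in a box occupying 6% of the image: the classifier's evidence sits on
the discriminative region, which is the property the real study verifies
on noseleaf photographs.

The same pipeline is scriptable from the shell:

```sh
noseleaf synth    --out data/ --seed 3
noseleaf augment  --in data/ --out aug/ --seed 3
noseleaf train    --config cfg.yaml --data aug/ --out run/ --seed 3
noseleaf evaluate --checkpoint run/checkpoint.npz --data aug/ --out report/
noseleaf explain  --checkpoint run/checkpoint.npz --image img.png \
                  --class-name R_affinis --out explained/
noseleaf inspect  --arch vgg16_cbam        # per-layer params/MACs table
```

## Dataset accounting

`DatasetManifest` reproduces the study's bookkeeping as plain arithmetic:
879 original images across 7 species (56–190 per class), a stratified
split into 586 training and 293 test images via an explicit per-class test
map, and per-class augmentation (GridMask, row blackout, Gaussian noise,
red-channel rotation, Gaussian blur) growing the training split to 1280.
All of it round-trips through a five-column CSV.

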