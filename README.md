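# sonosex

Sex determination in red abalone (*Haliotis rufescens*) normally requires
physically everting the animal's gonad — stressful for broodstock and
impractical at hatchery scale. Ultrasound makes the gonad/digestive-gland
complex visible non-invasively: a thin, echogenic gonad band envelops the
cone-shaped digestive gland, and subtle differences in that band's geometry
and echotexture carry the sex signal. `sonosex` is a tested, reusable
implementation of the image-analysis side of that idea, written for
aquaculture and conservation groups who want to train and audit their own
classifiers on such images.

Because multi-frame ultrasound of individually identified animals is rarely
public, the package includes a first-class **synthetic phantom generator**
that emulates the statistical structure of such a dataset — per-individual
latent anatomy, multiplicative gamma speckle, sex-linked band differences
with a configurable effect size, acquisition defects, and burned-in device
overlays — so the entire pipeline is testable without any download.

The pipeline stages:

* **preprocess** — overlay stripping; specimen ROI by thresholding at
  intensity 5, taking the largest enclosed-area contour, and cropping to its
  bounding box; zero-padding; metadata parsed from
  `<ID>_<location>_<sex>_<size>_<YYYYMMDD>_<frame>.png` filenames; automated
  stand-ins for three visual quality-exclusion criteria (echo ghosts,
  missing anatomy, incomplete capture).
* **partition** — splits drawn over *individuals*, never frames, stratified
  by sex, plus a leakage auditor; training-split balancing by offline
  augmentation.
* **baseline** — 64×64 flatten → standardize (train-only) → PCA → logistic
  regression, grid-searched over C × penalty × solver × components and
  selected by validation **balanced accuracy** (mean of per-class recalls).
* **cnn** — the custom families: *forward* (64→128→256→512) and *reverse*
  "double compression" (512→256→128→64, per-block max pooling, one dropout
  stage immediately before flattening, single sigmoid output, binary
  cross-entropy), implemented directly on numpy with explicit backprop,
  seeded training, checkpoint gating and early stopping.
* **evaluate** — confusion matrices and per-class precision/recall/F1, plus
  a leakage-inflation harness that quantifies how much frame-level random
  splitting inflates apparent accuracy.
* **interpret** — activation-map overlays, K-means with elbow + silhouette
  selection of K, t-SNE embeddings, silhouette scoring.

## Worked example

Train the desk-scale reverse-family CNN on the strong-geometry benchmark
(females' gonad band several times thicker than males', no compensating
brightness difference) and evaluate on individuals never seen in training:

```python
import numpy as np
from PIL import Image
from sonosex import (assign_splits, build_cnn, check_leakage, desk_scale_train_config,
                     evaluate_predictions, generate_frames, predict, train_model, CNNConfig)
from sonosex.benchmarks import strong_geometry_config, N_VAL_PER_SEX, N_TEST_PER_SEX

frames, manifest = generate_frames(strong_geometry_config(), seed=21)
print(f"{len(frames)} frames from {manifest['individual_id'].nunique()} individuals")

assignment = assign_splits(manifest, N_VAL_PER_SEX, N_TEST_PER_SEX, seed=5)
print(f"leaked individuals: {check_leakage(assignment, manifest).n_leaked}")

X = np.stack([np.asarray(Image.fromarray(f).resize((48, 48), Image.BILINEAR)) for f in frames])
y = manifest["sex"].to_numpy()
split = assignment.frame_split(manifest).to_numpy()
tr, va, te = split == "train", split == "val", split == "test"

model = build_cnn(CNNConfig(family="reverse", schedule=(16, 8), input_size=48,
                            dense_head=(32,), dropout_rate=0.2), seed=0)
history, _ = train_model(model, X[tr], y[tr], X[va], y[va],
                         desk_scale_train_config(max_epochs=60, learning_rate=1e-3,
                                                 seed=0, patience=1000))
labels, _ = predict(model, X[te])
report = evaluate_predictions(y[te], labels, split="test")
print(f"test confusion {report.matrix.as_array().tolist()}")
print(f"test accuracy {report.accuracy:.3f} on unseen individuals")
```

Output:

```
140 frames from 28 individuals
leaked individuals: 0
test confusion [[16, 4], [0, 20]]
test accuracy 0.900 on unseen individuals
```

The confusion matrix rows are truth (F, M), columns predicted: all 20 male
frames and 16 of 20 female frames of the eight held-out animals are
classified correctly. Rerunning with `effect_size=0`
(`benchmarks.zero_effect_config()`) drops unseen-individual accuracy to
chance — while a frame-level random split of the same data still scores well
above chance, which is exactly the leakage the individual-level protocol
exists to prevent (see `leakage_inflation_experiment`).

A full experiment — simulate → preprocess → split → balance → baseline →
CNN → evaluate → interpret, with stage caching and provenance — runs from
one config:

```bash
sonosex run-all --out runs/demo --seed 1
```

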