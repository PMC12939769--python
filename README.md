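# blastoseg

Lightweight multimodal semantic segmentation of human blastocyst
micrographs into five components: background (BG), zona pellucida (ZP),
trophectoderm (TE), blastocoel (BC/BL) and inner cell mass (ICM).

Morphological assessment of day-5 embryos drives transfer decisions in
IVF, and pixel-level component maps give embryologists areas, positions
and ratios instead of subjective visual grading.  Blastocyst images are
hard for intensity-only segmenters: contrast between compartments is
low, ZP and TE differ mostly in micro-texture, shapes vary with
expansion stage, and BC+BG pixels dominate the class balance.
`blastoseg` addresses this with:

* a **multimodal input stem** that decomposes each grayscale frame into
  fixed intensity, local-binary-pattern texture, and 0°/90° Gabor
  orientation channels;
* a **dual-path grouped encoder–decoder** under a strict budget of
  0.65 M trainable parameters (the default configuration uses 528,533):
  four stride-2 encoder stages (400 → 200 → 100 → 50 → 25 px), a compact
  bottleneck, and a refinement decoder with two semantic skip pathways,
  ending in a five-channel softmax pixel classifier;
* **generalized Dice training** (Adam, lr 0.001, squared-gradient decay
  0.95, L2 0.0005) with class weights `w_c = 1/(Σ_i g_ci)²` against the
  class imbalance;
* evaluation by per-class and mean **Jaccard** `JC = tp/(tp+fp+fn)` and
  **Dice** `DSC = 2tp/(2tp+fp+fn)`, a softmax-margin confidence score
  with a 5th-percentile review flag, a 16× paired augmentation scheme,
  an ablation harness over the three architectural modules, and a
  noise/blur robustness sweep;
* a **synthetic blastocyst phantom generator** with pixel-perfect masks,
  so the whole system is testable although the real annotated dataset is
  access-restricted.

Everything runs on numpy — the package carries its own small
reverse-mode autodiff engine (`blastoseg.nn`) with grouped/strided/
transposed convolutions, batch norm and Adam, each gradient verified
against finite differences in the test suite.

## Worked example

Generate phantoms, train briefly at reduced resolution, and score:

```bash
blastoseg phantom --n 8 --size 128 --seed 1 --out work/phantoms
blastoseg ablate --n 32 --size 64 --epochs 10 --seed 0 --out work/ablation.tsv
```

Library use:

```python
import numpy as np
from blastoseg import build_network, NetworkConfig, generate_dataset
from blastoseg.training import TrainConfig, train
from blastoseg.evaluation import evaluate_model

train_set = generate_dataset(64, size=128, seed=11)
test_set = generate_dataset(16, size=128, seed=2024)
net = build_network(NetworkConfig(input_size=128, seed=0))
net, history = train(net, train_set, TrainConfig(epochs=20, seed=0))
report = evaluate_model(net, test_set)
print(round(history.train_loss[0], 3), "->", round(history.train_loss[-1], 3))
print("mean JC", round(report.mean_jc, 3), np.round(report.per_class_jc, 3))
```

prints (seeds as shown, single-threaded)

```
0.856 -> 0.084
mean JC 0.906 [0.989 0.898 0.843 0.965 0.837]
```

i.e. the generalized Dice loss falls by an order of magnitude over 20
epochs and the held-out phantoms are segmented at mean Jaccard 0.91 —
background easiest (0.99), the thin trophectoderm ring and the small
low-contrast ICM hardest, matching the difficulty ordering seen on real
blastocysts.

The five-class masks use labels {0: BG, 1: ZP, 2: TE, 3: BC, 4: ICM};
overlays color correct pixels by class (TE red, ICM blue, ZP green, BC
yellow, BG gray) and errors black (spurious foreground on background)
or pink (missed foreground).

See `docs/methods.md` for the model, the phantom's construction, all
defaults, and the study sizes used by the scaled-down checks.

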