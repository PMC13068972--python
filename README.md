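# histomag

Magnification-aware breast-histopathology classification toolkit:

- **`histomag.fixtures`** — synthetic BreakHis-style H&E image generator with
  exactly known stain ground truth (Beer–Lambert two-stain formation,
  per-image illumination gains, contrast jitter, class-dependent nuclear
  density/size, magnification-dependent object scale).
- **`histomag.stain`** — four-stage normalization pipeline: CLAHE on the LAB
  luminance channel, per-channel CDF histogram matching, Shades-of-Gray
  color constancy (Minkowski p-norm, p=6), and Macenko optical-density stain
  normalization (SVD basis estimation with raw-SVD and
  angle-percentile modes; self-normalizing (literal) and reference-coupled
  reconstruction).
- **`histomag.balance`** — BreakHis-style tree scanning, per-magnification
  class counting, balancing plans, seeded augmentation (flips, rot90,
  shift-scale-rotate, brightness/contrast, HSV, Gaussian blur) and
  stratified 70/15/15 splitting.
- **`histomag.nn`** — a compact, fully configurable Vision Transformer
  implemented in NumPy on a small reverse-mode autodiff engine (patch
  projection, learnable positional embeddings, pre-norm MHSA/GELU-MLP
  encoder blocks, GAP or class-token aggregation, MLP head) with an AdamW
  training loop, early stopping, LR-on-plateau and best-weight
  checkpointing.
- **`histomag.gwo`** — Grey Wolf Optimizer over the 5-D hyperparameter space
  (learning rate on a log scale, projection dim, heads, depth, dropout) with
  leader-guided encircling, bound clipping, config decoding and fitness
  caching.
- **`histomag.metrics`** — confusion matrices, per-class precision/recall/F1,
  ROC/AUC, stratified 5-fold cross-validation reports and the paired t-test.

## CLI

```bash
histomag fixtures generate --out data/ --per-class 20 --mags 40,100,200,400 --seed 0
histomag stain preprocess --in data/ --out clean/ --mode literal
histomag data scan --root clean/ --out manifest.csv
histomag data balance --manifest manifest.csv --out balanced/ --seed 0
histomag data split --manifest balanced/manifest_balanced.csv --seed 42
histomag vit train --data balanced/ --mag 40 --epochs 10 --lr 1e-3 --seed 42
histomag gwo optimize --data balanced/ --mag 40 --pop 10 --iters 25 --proxy-epochs 2
histomag eval cv --data balanced/ --mag 40 --k 5 --seed 42
histomag eval ttest --a a.csv --b b.csv
```

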