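# x2p — prompt-guided biplanar 2D/3D vertebra localization

`x2p` localizes vertebral body centers in 3D (mm, world frame) from a pair of
calibrated radiographs (LAT + AP views), guided by one user-placed point
prompt per view marking the top-most vertebral body. It implements:

- a **U-Net + spatial-pyramid-pooling** feature extractor shared across views
  (`x2p.backbone`),
- **prompt-guided feature enhancement**: a binary prompt mask and feature
  crop feed a cross-attention stack that amplifies repetitive vertebral
  features; a unidirectional squared-distance mask injects vertical position
  (`x2p.prompting`, `x2p.backbone.FeatureEnhancer`),
- a **dual-attention context extractor** over learnable per-vertebra
  embeddings: coarse attention on max-pooled features selects the top-k
  foreground cells, fine attention runs only on the corresponding
  high-resolution features; linear heads emit per-slot 16x16 heatmaps
  (`x2p.brickformer`),
- **multi-view 3D fusion**: per-view features + rescaled heatmaps are
  unprojected into a pseudo-3D voxel volume along calibrated rays, fused by
  elementwise mean, refined by a 3-block 3D conv head, and turned into
  coordinates by per-slot softmax + soft-argmax; slots are validated by the
  max-probability rule (`x2p.fusion3d`, `x2p.geometry`),
- **losses** (heatmap MSE + Dice + 3D MSE) and **metrics** (PCL@tau, MPE,
  AUC of the PCL curve, per-level reports) (`x2p.objectives`, `x2p.metrics`),
- a **synthetic phantom generator**: procedural vertebra-chain attenuation
  volumes, perspective line-integral (DRR-style) biplanar rendering, random
  rigid pose perturbation, and exactly projected landmark/prompt annotations
  (`x2p.phantoms`), so the entire pipeline trains and evaluates without any
  external data.

Everything runs on a small NumPy reverse-mode autodiff engine (`x2p.nn`) —
no deep-learning framework is required. Training the bundled desk-scale
profile (128x128 images, 64^3 volume) takes minutes on one CPU.

## Quick start

```bash
# 1. generate a synthetic biplanar dataset (writes PNGs + JSON/CSV + manifest)
x2p generate --n 60 --seed 7 --out data/phantoms --image-size 128

# 2. train the desk profile end-to-end
x2p train --dataset data/phantoms --out runs/desk --epochs 15 --seed 1

# 3. localize vertebrae on one calibrated pair
x2p infer --checkpoint runs/desk/checkpoint.npz \
    --image-lat data/phantoms/sample_0000/lat.png \
    --image-ap  data/phantoms/sample_0000/ap.png \
    --cameras   data/phantoms/sample_0000/cameras.json \
    --prompt-lat 64,20 --prompt-ap 64,20 --out pred.json

# 4. evaluate on the held-out split (PCL@{10,20}, MPE, AUC + per-level CSV)
x2p evaluate --checkpoint runs/desk/checkpoint.npz \
    --dataset data/phantoms --split test --out report.csv

# 5. prompt-displacement robustness sweep
x2p sweep-prompt --checkpoint runs/desk/checkpoint.npz \
    --dataset data/phantoms --axis x --offsets -20,-10,0,10,20 --out sweep.csv

# 6. attention complexity accounting (dual-attention vs vanilla)
x2p flops --width 512 --height 512 --d 64 --n-slots 10 --alpha 32 --topk 8
```

Configuration is YAML (`x2p train --config run.yaml`); named presets
`desk`, `longfilm` (512x512, d=64, N=10, alpha=32, k=8) and `carm`
(N=5, alpha=8, k=4) are built in — see `x2p.config`.

Tall inputs (height > the configured window) are processed by sliding
windows top-to-bottom; the bottom-most valid vertebra of each window becomes
the prompt of the next, and per-window results are merged.

## Conventions

- World frame: right-handed, millimetres, +z superior.
- Pixels: 0-based `(x=column, y=row)`, centers at integers; row index grows
  downward (superior anatomy at small y).
- Cameras: 3x4 projection matrices mapping homogeneous world mm to pixels,
  serialized as JSON `{"view": "lat|ap", "P": [[...]]}`.

## Tests

```bash
python -m pytest -q tests/
```

Unit and property tests per module plus `tests/test_acceptance.py`, which
implements the acceptance criteria (equation-exactness oracles, dual-attention
equivalence, complexity accounting, geometry round trip, phantom consistency,
a scaled-down end-to-end training run, and a prompt-robustness sweep). The
training-based criteria dominate the runtime — the full suite takes about
20 minutes on one CPU; everything except the training criteria finishes in
about two minutes.

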