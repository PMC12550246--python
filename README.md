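# leaffusion

Multi-level fusion of handcrafted image descriptors for classifying
visually similar plant species from leaf photographs.

Four descriptors are computed per image and concatenated into one fused
feature vector with a recorded segment map:

| Segment | Descriptor | Default size |
|---|---|---|
| C1 | joint 3-D RGB color histogram (8×8×8 bins, normalized) | 512 |
| C2 | rotation-invariant uniform LBP histogram (P=24, R=3) | 26 |
| C3 | Gabor filter-bank statistics (4 orientations × 3 sigmas, mean+std) | 24 |
| C4 | HOG (8×8 cells, 2×2 blocks, 9 bins, L2-Hys) | 8100 |

Downstream: SMOTE oversampling of minority classes in feature space,
per-column standardization, a cross-validated suite of eight classic
classifiers plus a soft-voting ensemble, an inter-class cosine
similarity matrix over class mean vectors, and a stress-testing harness
(Gaussian noise, rescaling, lossless 90°/180°/270° rotation, rectangle
occlusion) applied to evaluation images only.

A deterministic synthetic leaf generator ships with the package so the
entire pipeline is exercisable without any external dataset: classes
differ controllably in base color, vein texture (frequency/orientation)
and contour shape, which lets tests dial in both easy color-separable
regimes and "look-alike" regimes where classes share color and differ
only in texture.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(descriptor oracle equivalence against brute-force reference
implementations, normalization and rotation invariants, SMOTE and
metric contracts, end-to-end recovery on synthetic data, stress-harness
sanity). The full suite takes a couple of minutes on one CPU.

## CLI

```sh
# render a synthetic fixture dataset from a YAML/JSON spec
leaffusion generate-fixtures --config spec.yaml --out images/

# extract fused features (CSV + sidecar segment map)
leaffusion extract --root images/ --out features.csv --resize 128 128

# SMOTE-balance a feature CSV
leaffusion balance --features features.csv --out balanced.csv

# cross-validated evaluation (guarded SMOTE inside each fold)
leaffusion evaluate --features features.csv --classifiers svm,rf,gb,vote \
    --folds 5 --seed 42 --out report/

# inter-class similarity matrix + heatmap
leaffusion similarity --features features.csv --out sim.csv --heatmap sim.png

# full pipeline from one config (see tests for the schema)
leaffusion run --config pipeline.json

# pipeline plus a stress-condition sweep
leaffusion stress --config pipeline.json --conditions noise:10,noise:20,scale:64,rot:180,occ:0.2
```

Dataset layout is one folder per class under a root directory
(`root/<class>/<image>.png|jpg`), with labels encoded 0..k−1 in
lexicographic class-name order.

Notable configuration switches:

- `--resize H W` — working resolution (default 128×128).
- `--color-mode marginal` — per-channel histograms (3·b values) instead
  of the joint 3-D cube.
- `--gabor-sigmas 1` — single-scale 8-value Gabor variant.
- `--hog-norm l2` / `--hog-vote hard` — alternative HOG dialects.
- `--paper-order` — apply SMOTE and normalization *before* splitting
  (the leakage-prone ordering, kept for comparison; default is fitting
  both on training folds only).

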