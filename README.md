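# grainct

Grain morphometrics from 3D X-ray microCT scans of cereal spikes.

X-ray microcomputed tomography makes it possible to measure the full 3D
shape of every grain in an intact wheat or barley spike — including **grain
depth**, the dimension that flat-bed scanners and photography cannot see and
that turns out to carry most of the signal distinguishing domesticated
cereals from their wild progenitors.  `grainct` implements the complete
desk pipeline for this kind of study:

- **`simgrain`** — synthetic spike phantoms (rotated ellipsoidal grains with
  lower-density hull shells on a rachis, imaging blur and noise) with exact
  ground truth, and synthetic two-population trait tables with realistic
  wild/domesticated structure;
- **`volio`** — TIFF-stack + JSON-sidecar volume I/O and CSV trait tables,
  with explicit `(z, y, x)` indexing and μm units throughout;
- **`graincut`** — segmentation of individual grains: intensity
  thresholding (which drops the low-density hull), speckle/cavity cleanup,
  watershed splitting of touching grains on the Euclidean distance
  transform, and removal of non-grain material (rachis, debris) by size,
  shape and intensity criteria;
- **`morpho`** — the five trait operators per grain — length (major-axis
  extent), width and depth (major/minor extents of the midpoint
  cross-section), volume (voxel count) and surface area (exposed-face
  count) — plus SA/V and a 0.025/0.975-percentile outlier filter;
- **`traitstats`** — Welch tests, Shapiro–Wilk normality checks, a robust
  Bayesian two-group difference model (BEST: t-likelihood, group means and
  SDs, shared normality parameter, fitted by MCMC with split-R̂
  diagnostics), and PCA with deterministic loadings;
- **`domclass`** — the domestication classifier: standardized OLS
  regression of 0/1 status on (length, width, depth) with a stratified
  20/80 train/test split, R² = 1 − SSE/SST scoring on the held-out data,
  0.5-threshold classification, and feature-subset ablation.

## The core model

For grains with status y ∈ {0 = wild, 1 = domesticated} and z-scored
dimensions, the classifier is the ordinary-least-squares fit of

    y = β₀ + β₁·length + β₂·width + β₃·depth + ε

trained on a random 20% of grains (stratified by status) and scored on the
remaining 80% by R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)².  The ablation experiment
refits on every feature subset over the same split; on populations in which
depth dominates the group separation, removing depth collapses R² from
≥ 0.9 to ≈ 0.4 — the three-dimensional measurement is what makes the
classification work.

## Worked example

```python
from grainct import simgrain, graincut, morpho, domclass

# a 8-grain spike phantom at 137.6 um voxels, 10% noise, touching grains
spec = simgrain.spike_phantom(8, voxel_size=137.6, noise_sd=20.0,
                              blur_sigma=1.0, touching_fraction=0.25, seed=3)
volume, truth = simgrain.generate_spike_volume(spec)

params = graincut.SegmentationParams(threshold_mode=150.0, min_grain_voxels=100)
labels = graincut.segment_volume(volume, params)
table = morpho.extract_traits(labels)
print(table[["grain_id", "length_um", "width_um", "depth_um"]].round(0))
```

prints eight grains around 5.2–6.2 mm long, 2.7–3.2 mm wide and
2.3–2.7 mm deep (e.g. grain 1: 5238, 2869, 2262 μm) — each within a few
percent of its phantom's true axes.  Fitting the classifier on a synthetic
two-population table:

```python
table = simgrain.generate_trait_table(simgrain.PopulationSpec(seed=1))
train, test = domclass.split_train_test(table, 0.2, seed=1)
ev = domclass.evaluate(domclass.fit(train), test)
rep = domclass.ablation(table, seed=1)
print(ev.r_squared)                                        # 0.931
print(rep.r_squared[("length_um", "width_um")])            # 0.438
```

Held-out R² is 0.931 with all three dimensions and drops to 0.438 when
depth is excluded: depth carries the domestication signal.

The same stages are available from the shell:

```sh
grainct simulate --config spike.yaml --out sim/ --seed 3
grainct segment  --in sim/volume --params seg.yaml --out labels/
grainct measure  --labels labels/ --out traits.csv
grainct stats    --traits traits.csv --out stats/
grainct classify --traits traits.csv --seed 1 --ablate --out model/
```

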