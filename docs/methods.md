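# Methods

This note documents the models, conventions and numerical choices behind
`grainct`, in the order the pipeline runs.

## Conventions

All volumes are indexed `(z, y, x)`, 0-based, with voxel centres at integer
voxel coordinates; z is the spike axis.  Physical quantities are
micrometres (μm, μm², μm³) everywhere inside the package; unit conversion
happens only at table-writing boundaries.  The default voxel size is
68.8 μm/voxel at 512 × 512 slice resolution, matching the cabinet
μCT geometry the pipeline targets.  The proprietary scanner format (Scanco
ISQ) is deliberately unsupported; TIFF stacks with a JSON sidecar are the
interchange format.

## Spike phantom (`simgrain`)

Grains are rotated tri-axial ellipsoids.  This shape is chosen because all
five trait operators have closed forms on it (2a, 2b, 2c, (4/3)πabc, and
the Knud Thomsen area approximation), so every downstream measurement can
be validated against an analytic oracle.  Each grain consists of an
endosperm core (default intensity 200) optionally wrapped in a hull shell
of thickness 150 μm and lower intensity (default 100), mimicking the
lemma/palea chaff that real segmentations must exclude; a rachis cylinder
(radius 400 μm, intensity 90) runs along z.  The imaging chain is modelled
as a Gaussian blur (σ in voxels) followed by additive Gaussian noise.
Default phantom grains are ~6 × 2.8 × 2.3 mm — small-grain cereal scale.

`spike_phantom` arranges grains in four rows 90° apart around the rachis
with conservative spacing computed from the worst-case jittered size and
tilt, so non-pair grains are guaranteed not to touch.  "Touching" pairs
are placed side by side with endosperm surfaces about one voxel apart;
their hull shells interpenetrate (allowed and intended), while endosperm
cores may never overlap, so the ground-truth labelling stays unambiguous.
Every generator is a pure function of its spec: identical seeds give
bit-identical volumes.

What the phantom does **not** model: X-ray physics (beam hardening, ring
artefacts, partial-volume effects beyond blur), awns, pedicels, grain
creases, or non-ellipsoidal grain shapes.  Passing the recovery tests
therefore shows the geometry/algorithm chain is correct, not that the
segmentation would be artefact-robust on real scanner data.

## Two-population trait model

Synthetic trait tables draw (length, width, depth) from a correlated
log-normal model per group.  Defaults: wild grains 6.2 × 2.6 × 2.0 mm
(geometric means), within-group CVs 6/5/5%, between-trait correlations
0.3–0.4; the domesticated group shifts depth by +0.35 log units (~42%),
width by +0.08 (~8%) and length by +0.005 (~0.5%).  These values are
simulation conventions, not estimates from any dataset: they encode the
qualitative domestication signal (depth ≫ width ≫ length ≈ 0) with depth
separating the groups by ~7 within-group SDs — nearly disjoint
populations, which is what a held-out 0/1-target OLS R² above 0.9
mathematically requires (R² ≈ d²/(d²+4) at separation d).  Volume and
surface area are derived from L/W/D via the ellipsoid formulas
(V = πLWD/6; Knud Thomsen with p = 1.6075) and flagged as derived.

## Segmentation (`graincut`)

1. **binarize** — Otsu (between-class variance over a 256-bin histogram)
   or a fixed threshold.  Hull exclusion is implemented by intensity
   class: a fixed threshold placed between the hull and endosperm
   intensities selects endosperm only, which is how "the hull is removed
   by segmentation, not measured".
2. **clean** — components smaller than `min_grain_voxels` are removed at
   the configured connectivity (default 26 for foreground; surface
   reasoning uses 6 — the conventional dual pairing); cavities are filled
   in 3D and slice-wise.  Idempotent.
3. **split_touching** — exact Euclidean distance transform; seeds are
   h-maxima at merging depth `h_maxima_depth` (default 2 voxels).  The
   seeds are taken as the regional maxima of the grey-reconstruction of
   (d − h) under d, *not* of the raw h-maxima mask: the raw mask marks
   only voxels within float resolution of each peak, so two equal-height
   plateaus of one merged maximum would come out as two seeds and
   over-segment a single grain.  Watershed floods the negated distance map
   within the foreground; computation runs per connected-component
   bounding box since most of a spike volume is background.  Labels are
   compacted to {1..K} ordered by centroid z, making output deterministic.
4. **remove_non_grain** — components failing the voxel-count window, the
   per-trait plausibility bounds ("expected grain limits", defaults
   length 1–15 mm, width/depth 0.5–6 mm, configurable, never hard-coded
   into the algorithms), or the endosperm mean-intensity test are dropped
   with logged reasons.  Idempotent.

## Trait operators (`morpho`)

- **Axes and extents.** Principal axes are eigenvectors of the
  voxel-coordinate covariance.  Extents are peak-to-peak projections of
  voxel centres **plus one voxel**: voxels are treated as unit cubes, so a
  single voxel has length one voxel size.  This convention puts digital
  ellipsoid extents at 2⌊c⌋+1 voxels — the smallest axis of a
  (40, 20, 10) test ellipsoid lands exactly on a 5% relative deviation,
  which the tests treat as the boundary of acceptable.
- **Width/depth.** The midpoint cross-section is a voxel *slab*: voxels
  whose major-axis projection lies within half a voxel of the midpoint of
  the length extent.  2D principal axes within the slab give width (larger
  extent) and depth (smaller); circular sections assign both to the common
  value.
- **Volume** is the voxel count times voxel_size³ — exact by definition.
- **Surface area** counts exposed 6-neighbour voxel faces.  This
  "Manhattan" estimate over-counts smooth surfaces (→ 1.5× for a sphere in
  the fine-resolution limit: 6πr² instead of 4πr²) but is exactly
  reproducible and monotone; do not compare against marching-cubes areas.
  SA/V inherits the same bias.
- **Outlier filter.** Per-trait 0.025/0.975 quantiles (linear
  interpolation of order statistics, type 7 — stated because the tail
  counts depend on it), union-removal across the five traits, then the
  grain-limit bounds.  Constant traits are exempt (a degenerate
  distribution has no tails).  Per-trait union filtering is the minimal
  reading of a percentile rule "on the data"; joint (Mahalanobis)
  filtering is intentionally not implemented.  The filter runs in a single
  pass — it is not re-applied after the limit constraints.

Measured recovery on 50 random rotated digital ellipsoids (major axis
≥ 40 voxels): mean absolute relative error ≈ 1.1% (length), 1.5% (width),
2.6% (depth), 0.1% (volume) — the acceptance script recomputes these.

## Statistics (`traitstats`)

Welch's t (unequal variances, Welch–Satterthwaite df) and Shapiro–Wilk
(3 ≤ n ≤ 5000) wrap SciPy.  PCA eigendecomposes the correlation matrix by
default (traits have incommensurate units); covariance is available.  Sign
convention: each loading column's largest-magnitude entry is positive —
without a fixed convention loading signs are not reproducible.

The Bayesian two-group model is Kruschke's BEST with its reference priors:
t-likelihood with group means μ₁, μ₂ ~ N(pooled mean, 1000·pooled SD),
group SDs σ₁, σ₂ ~ U(pooled SD/1000, pooled SD·1000), shared ν with
ν − 1 ~ Exp(mean 29).  The posterior is sampled with emcee's
affine-invariant ensemble (32 walkers, 2000 warm-up + 3000 retained steps,
differential-evolution moves, which mix far better than the stretch move
on this correlated 5-parameter posterior).  Walker trajectories are
treated as chains for split-R̂; any parameter above 1.05 raises an error
rather than returning unreliable draws.  From the Δ = μ₁ − μ₂ posterior we
report P(Δ > 0) and the symmetric overlap measure 2·min(P(Δ>0), P(Δ<0)) —
≈ 1 for indistinguishable means, ≈ 0 for clear separation.  Both are
exposed because "probability of overlapping averages" admits more than one
convention (e.g. ROPE-based definitions).

## Classifier (`domclass`)

Status is encoded wild = 0, domesticated = 1.  The split is seeded,
uniform and stratified by status (default 20% train).  Features are
z-scored with training-set statistics only — leakage-free standardization.
OLS is fitted via statsmodels; constant or collinear features raise with
the offending name.  R² on the held-out set uses the 0/1 labels directly
as the regression target; classification thresholds predictions at 0.5,
and misclassified grains are reported with their distance from the
boundary (they concentrate near it).  The report includes both R² and
accuracy so either summary can be used.  Ablation reuses one split across
all seven feature subsets so the R² values are directly comparable.  The
model is per-taxon by design; no cross-taxon transfer is attempted.

## Problem sizes

Tests and the acceptance script run phantoms at 137.6 μm voxels (a 2×
coarser binning of the default scanner geometry) with 6–30 grains, 10–20
seeds per property, 2000 Welch null replicates, and n = 100–500 per group
for the MCMC checks.  These sizes were chosen so the full battery runs in
a few minutes on one CPU while keeping every oracle comparison meaningful.

## Known limitations

- Surface area (and SA/V) is connectivity-defined, not geometric.
- The watershed assumes roughly convex grains; deeply creased or bent
  grains could be split at the crease.
- The hull/endosperm separation relies on an intensity gap; scans where
  hull and endosperm densities overlap would need the Otsu path plus
  morphological hull stripping, which is not implemented.
- The classifier is linear OLS on three dimensions by construction; it is
  a reimplementation target, not the best possible classifier (logistic
  regression or regularization are out of scope).
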