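# Methods

This note documents the statistical models, the synthetic study design,
and the numerical choices behind `wntomics`, in the spirit of the methods
documentation of packages like statsmodels or scanpy: what is computed,
under which assumptions, which knobs matter, and what the tests do and do
not establish.

## Differential screening

Per-feature statistics compare CTNNB1-mutated (MUT) against wild-type
(WT) samples on log₂-scale abundances. The effect size is the difference
of group means (log₂ fold change, MUT − WT); inference uses the **Welch**
unequal-variance *t*-test with Welch–Satterthwaite degrees of freedom. A
pooled-variance test is deliberately not the default: with unbalanced
groups (12 vs 6 in the discovery design) the pooled test is anticonservative
when the smaller group has the larger variance. Features with any missing
value in either group are dropped (count logged), never imputed. Constant
features (zero variance in both groups, equal means) are degenerate and
report t = 0, p = 1 with a flag.

**Storey q-values.** π₀ (the true-null fraction) is estimated as
π̂₀(λ) = #{p > λ}/(n(1−λ)) on λ = 0.05, …, 0.95, smoothed with a cubic
smoothing spline (`scipy.interpolate.UnivariateSpline`, k = 3, default
smoothing), evaluated at λ = 0.95 and clamped to (0, 1]. q-values are the
right-to-left running minimum of π̂₀·n·p₍ⱼ₎/j on the sorted p-values, so
they are monotone in p and reduce exactly to Benjamini–Hochberg when
π₀ = 1. Fewer than 10 p-values fall back to π₀ = 1 (the spline is
meaningless there).

**Concordance cascade.** Four stages, each auditable per feature:
discovery q < `q_max` (default 0.1); presence in the validation cohort;
identical nonzero fold-change sign; within-side rank percentile ≤ `decile`
(default 0.10) in both cohorts. "Within-side" means upregulated features
are ranked among upregulated ones (descending log₂FC) and downregulated
among downregulated (ascending); a feature with log₂FC = 0 belongs to
neither side. This reading of "top 10% up- or downregulated" is the
default because the phrase is naturally per-direction; a global-decile
variant (rank by |log₂FC| over all features) is available via
`ScreenConfig(per_side=False)`. Ranking uses |log₂FC| by default
(`rank_by="t"` switches to the t statistic); ties break lexicographically
by feature id so results are deterministic.

## Preranked GSEA and the consistency filter

Features are ranked by descending log₂ fold change (each dataset by its
own MUT-vs-WT contrast; the ranking metric is configurable but log₂FC is
the default since the effect estimate, not its significance, is what the
three datasets share). The enrichment score is the weighted
Kolmogorov–Smirnov running sum: walking down the list, a set member adds
|m|ᵖ/Σ_hits|m|ᵖ (default p = 1), a non-member subtracts 1/(N − n_hits);
ES is the signed extreme of the running sum. If all hit weights are zero
the hit increments fall back to 1/n_hits (the classic unweighted form,
which p = 0 also yields).

Significance and normalization use **gene-label permutations**: the hit
positions are redrawn uniformly without replacement `n_perm` times
(default 1,000). NES divides the observed ES by the mean magnitude of
same-sign permutation scores; p = (1 + #{same-sign |ES*| ≥ |ES|}) /
(1 + #same-sign). Same-sign normalization (rather than all-permutation)
follows the GSEA convention so that positive and negative scores are
normalized against their own null tail. A set with no same-sign
permutation score gets NES = NaN and a flag rather than a fabricated
value. Permutation streams are seeded per set name, so collection order
does not affect results. Inside the permutation loop the ES is computed
from the sorted hit positions alone in O(k): the running sum attains its
positive extremes immediately after a hit and its negative extremes
immediately before one; the property suite checks this shortcut against
the full O(N) running sum.

The **consistency filter** keeps a pathway when its NES has the same sign
in all three datasets and lies in the top `pct` (positive) or bottom
`pct` (negative) of each dataset's NES distribution (default 0.15). The
tail test is boundary-inclusive: a pathway is in the tail when the
fraction of pathways strictly more extreme is below `pct`, so ties at the
cutoff are kept and a degenerate single-pathway table passes trivially.
The sign test is applied before the percentile test; percentiles are
computed over all scored pathways of the dataset.

## Synthetic study conditions

The generator's defaults are the study conditions every recovery test and
the acceptance script run under; they are fixed, not tuned per test.

* **Cohorts**: 12 WT + 6 MUT discovery samples with 1,600 proteins;
  37 WT + 23 MUT validation samples with 9,000 features (proteome and
  transcriptome), 95% of discovery features included by id. 10% of
  discovery proteins carry a planted shift of ±1.5 log₂ units on the MUT
  group mean, identically in all three matrices (the consistency logic
  assumes concordance; a `discordance_frac` knob breaks it for negative
  tests, and `dropout_frac` adds MCAR missingness). Residual noise is
  Gaussian with sd 0.5 — effects strong but not trivial at n = 18.
  Abundances are simulated directly on the log₂ scale; the validation
  transcriptome is emitted on the same scale by assumption (its
  normalization is otherwise unspecified in this design).
* **Gene sets**: 100 sets, sizes uniform on [10, 60]; 10% are enriched,
  seeded with ≥ 60% planted features of one direction (the set shrinks if
  the pool cannot sustain 60%); null sets sample uniformly from the full
  universe so they overlap planted features only by chance — which is
  what lets the "contains ≥ 1 protein of interest" pathway filter retain
  a realistic background of null pathways.
* **Cell tables**: each image is a 1.2 mm TMA-core disc (area ≈ 1.131 mm²),
  coordinates in µm with origin at the core's bounding-box corner, areas
  reported in mm². Phenotype counts are Poisson draws from planted
  densities: tumor 700, macrophage 150, Treg 70, other 400 cells/mm²,
  and CD8 450 (WT images) vs 280 (MUT images) — the contrast scale
  reported for CD8 TILs in this tumor type. Marker intensity is modeled
  per cell as a latent mean (3.0 if the cell's phenotype marker, 0.5
  otherwise, cell-to-cell sd 0.3) with 40 lognormal pixel samples
  (σ = 0.25) around it, so the 97.5% pixel quantile strictly exceeds the
  pixel mean and quantile summarization is exercised nontrivially.
  Per-image batch shifts are additive Normal(0, 0.5) per marker on the
  pixel scale. `default_thresholds()` returns the midpoint of the two
  latent levels propagated through the quantile, which is what "gating at
  planted midpoints" means in the tests.
* **Interaction regimes**: four placement modes — `weak` (homogeneous
  Poisson in the disc), `tumor_immune` (tumor cells in Gaussian clusters,
  immune cells placed 25 µm around random tumor cells), `immune_immune`
  (CD8/macrophage/Treg share tight aggregates), and `tumor_clustered`
  (tumor aggregated, immune uniform). Four regimes exist so that k = 4
  clustering has four well-separated ground-truth patterns to recover.
  Regime assignment is per image: a fixed regime, a deterministic
  `cycle`, or `genotype_linked` (MUT cores 90% weak, WT cores spread
  across all four), which plants the genotype-by-interaction-pattern
  association probed by the Fisher test.

What the generator does **not** emulate: mass spectra or TMT reporter
ions, read counts, image rasters or segmentation errors, spatial
heterogeneity of marker intensity within a phenotype, missing-not-at-
random dropout, or inter-patient correlation between cores. Passing
recovery tests therefore demonstrates the correctness of the statistical
machinery under the planted model, not robustness to those real-data
pathologies.

## mIF phenotyping

Cell intensity is the q = 0.975 quantile of that cell's pixel samples
(linear interpolation between order statistics, numpy/R type-7 — stated
because quantile conventions differ). The quantile is computed over
pixels per cell, not as an image-level cap.

**ComBat.** The parametric empirical-Bayes location/scale model with
batch (image) as the only covariate: per marker, standardize against the
batch-size-weighted grand mean and pooled residual variance; estimate
per-batch location γ̂ and scale δ̂²; shrink toward across-marker
moment-matched priors (normal for γ, inverse-gamma for δ²) by the
standard fixed-point iteration; adjust and restore scale. Only the
parametric prior is implemented (the tooling default in this domain).
Degenerate cases: one batch returns the input unchanged; a batch with
fewer than 3 cells is an error (named); zero within-batch variance is
guarded with small clamps so that noiseless batch shifts are removed
exactly. With only 4 markers the hyperpriors are moment-matched across 4
points — crude but exactly what the reference implementation does; the
test suite pins the output to `sva::ComBat` within 1e-5.

**Gating** is a first-match decision tree in a fixed priority order
(CK → CD8 → CD68 → FOXP3), so every cell receives exactly one phenotype;
threshold selection is a config input (in the emulated workflow it is a
manual step).

**Tumor masks.** DBSCAN (Euclidean, eps = 30 µm, min_pts = 5) on tumor
cells discards spatially isolated tumor cells as noise; eps ≈ 2–3 cell
diameters and a handful of neighbors is the rationale, and both knobs are
exposed. Each cluster contributes a concave hull via
`shapely.concave_hull` with ratio = concavity/(concavity + 1) (default
concavity 2.0 → ratio 2/3; `convex=True` switches to convex hulls and is
recorded in the mask metadata since it changes areas). Degenerate
clusters (collinear) fall back to the convex hull or contribute nothing.
Point-in-mask tests are boundary-inclusive (`covers`). Total tissue area
is the concave hull over all cells of the image at the same concavity;
the tumor area is the mask clipped to the tissue hull (which enforces
mask ⊆ tissue); stromal area is the difference, floored at 0 with a log
line. Images with fewer than 3 cells have no defined area and are
skipped.

## Spatial interaction

The neighborhood graph is the Delaunay triangulation of the cell
centroids (no edge-length cutoff by default, since boundary edges are
part of the stated construction; `max_edge_um` removes long rim edges
when set). Duplicate coordinates are jittered by 1e-6 µm with a warning.
The interaction score of an ordered pair (A, B) is the mean number of
type-B Delaunay neighbors per type-A cell — the classic convention of
multiplexed-imaging toolkits for "edges divided by nodes"; homotypic
edges count once per endpoint. Pairs with no A cell are missing, not
zero. The per-image feature vector is the 16 ordered-pair scores over
{tumor, CD8 T, macrophage, Treg}; missing scores are imputed as 0 (with a
logged count) and features are z-scored across images before k-means
(k = 4, 10 restarts, seeded). Clusters are renumbered by ascending mean
total raw interaction, so label 0 is always the "weak interaction"
pattern and labels are stable across runs. For the genotype test, the
cluster grouping is a config input; the default (`"auto"`) designates the
two clusters with the strongest mean immune–immune centroid scores as
the immune-enriched group, mirroring how those patterns are recognized,
and records the choice in the run report.

## Exact statistics

**Fisher.** Both margins are conditioned on; the two-sided p-value sums
hypergeometric probabilities ≤ P(observed)·(1 + 1e-7) — the probability-
mass rule of the R statistical environment, with the tolerance guarding
floating-point ties. Tables with an empty row or column return p = 1.

**ΔΔCt.** Replicate Cts are averaged per sample and gene; ΔCt subtracts
the arithmetic mean of the reference-gene Cts (equivalent to a geometric
mean of linear quantities — stated because multi-reference conventions
differ); ΔΔCt subtracts the calibrator-group mean; fold change is
2^(−ΔΔCt). Group summaries are geometric-mean fold changes, so the
calibrator group's summary is exactly 1; the group comparison is a Welch
t-test on per-sample ΔCt. Samples missing the target or any reference
are dropped with a logged count.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or load external inputs) → screen →
GSEA on three datasets → consistency filter → mIF summarization /
ComBat / gating / masks / densities → Delaunay profiles / clustering /
genotype enrichment. One global seed fans out to per-stage seeds by fixed
offsets, so each stage is independently reproducible; identical config +
seed gives bit-identical artifacts and reports. The JSON report carries
per-stage counts, the package version, the seed, and a hash of the
scientific configuration (the output directory is excluded from the
hash); it is validated against the schema shipped in the package by a
minimal built-in structural check (required keys and types).

### Problem sizes

Test and acceptance runs use the default study conditions wherever a
recovery claim refers to them (cohort sizes 12 + 6 / 37 + 23, 1,600 /
9,000 features, 40 images, 1,000 permutations). Auxiliary module tests
use smaller instances — a few hundred features, 8–10 images with
density scaled to roughly half — chosen as the smallest sizes at which
the tested property is not dominated by sampling noise.

## Known limitations

* The Storey spline smoothing uses scipy's default smoothing parameter,
  not the df = 3 generalized cross-validation of the R implementation;
  π̂₀ estimates agree in the interior but are not digit-identical.
* fgsea's multilevel Monte-Carlo p-value refinement and leading-edge
  reporting are out of scope; permutation p-values are floored at
  1/(1 + n_perm).
* The concave hull underestimates tissue area when cells are sparse near
  the core rim; density estimates are correspondingly biased upward by a
  few percent at default densities.
* k-means cluster semantics ("weak" = lowest total interaction) are a
  heuristic; with strongly unbalanced regime mixes a small outlier
  cluster can rank below the homogeneous one, which is why the immune
  grouping for the Fisher test is selected by centroid content, not by
  rank.
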