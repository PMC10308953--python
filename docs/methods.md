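# Methods

This note documents the statistical procedures, the synthetic-data model,
the default parameters and the numerical choices made where the design
was genuinely open.

## Study design and data model

The package models serial-propagation experiments: communities from
`n_origins` distinct origins are grown in replicate microcosms
(generation G0), and each G0 replicate inoculates two G1 microcosms,
after which propagation is one-to-one, for `n_generations` 28-day
generations. With the default 10 origins × 2 G0 replicates × 4 lineages ×
5 generations this gives 180 samples (20 at G0, 40 at each of G1–G4) and
160 parent→child transitions. Each sample carries an origin, generation,
lineage and parent link, plus three functional readouts: DOC (mg C g⁻¹
litter), total CO₂ accumulation (mg g⁻¹ litter) and total N (mg g⁻¹
litter). Metadata validation enforces that every non-G0 sample's parent
exists and sits exactly one generation earlier, which makes the lineage
graph a forest.

## Table preparation

- **Rarefaction** subsamples each sample's counts *without replacement*
  (a multivariate hypergeometric draw per column), so retained columns
  sum exactly to the requested depth; samples below depth are dropped
  with a logged warning rather than an error, since partial designs are
  common in practice. A bacterial depth of 5,457 and fungal depth of
  6,670 reads (the emulated study's minimum sample sizes) are the
  reference depths; the pipeline defaults to each table's own minimum.
- **Rank aggregation** sums counts over a chosen rank (bacterial
  co-abundance analysis uses families). Taxa without a label at that rank
  are kept as `Unclassified_<deepest assigned label>` groups by default —
  discarding them would silently change column sums — with a flag to drop
  them.
- **Prevalence filtering** is strict (>) by default: "present in more
  than 80 % of samples" excludes a taxon observed in exactly 80 %.

## Diversity and PERMANOVA

Shannon diversity uses the natural logarithm (no base is standard in this
literature); Pielou evenness H/ln S is defined as 1 for single-taxon
samples (the limit of a maximally even community). Bray–Curtis is
computed on rarefied counts.

Beta-dispersion embeds the dissimilarity matrix by principal coordinates.
Negative eigenvalues (non-Euclidean dissimilarities) are kept as
imaginary axes; a sample's distance to its group centroid is
√max(d²_real − d²_imag, 0), the standard correction.

PERMANOVA partitions the Gower-centered inner-product matrix
G = −½ J D² J by *sequential* (order-of-entry) sums of squares:
SS(term) = tr((H_k − H_{k−1}) G) with H_k the projector onto the
cumulative design-matrix column space. The factor order defaults to
origin, generation, origin×generation, the order in which such results
are conventionally reported. Pseudo-F uses the full-model residual mean
square; p-values come from free permutation of sample labels with the +1
correction, p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so p is never
zero. Restricted permutation schemes are not implemented. With Euclidean
distances and one factor the decomposition reproduces the classical
one-way ANOVA partition (tested to 1e-8), and the implementation is
cross-checked against an independent one-way PERMANOVA implementation.

## Stability statistics

Functional stability of a child sample is ΔDOC = |DOC(Gn) − DOC(Gn−1)|
along its lineage; compositional change is Bray–Curtis between the same
two samples. Per-generation variability is the coefficient of variation
(SD with n−1 denominator over mean). Stratification pools ΔDOC across
all child generations (G1–G4), takes the 25th and 75th percentiles with
linear interpolation between order statistics (the convention of the
common analysis environments, recorded in the output), and labels
samples ≤ q25 *most stable* and ≥ q75 *least stable*; boundary values
fall in the tail groups because the stability intervals are closed. A
degenerate distribution (q25 = q75) yields all-intermediate labels and a
warning rather than arbitrary tie-breaking. Stratification is
scale-equivariant by construction.

## Association analyses

All-pairs Pearson correlations drop incomplete observations pairwise;
zero-variance features are reported as NA and excluded from the
multiple-testing family. The false discovery rate is controlled by
Benjamini–Hochberg at 0.1, while figures/outputs flag significance at
p_adj < 0.05; both thresholds are arguments. BH families are: one family
per trait-correlation analysis, and one family per stability group for
the taxa ~ function screens (the family structure is recorded in the
outputs).

Function dissimilarity between two samples is |xᵢ − xⱼ| for one variable.
The combined DOC/CO₂ dissimilarity is the Euclidean distance over
z-scored (DOC, CO₂) pairs; a product form |DOCᵢ·CO2ᵢ − DOCⱼ·CO2ⱼ| is
available behind a flag since the combined quantity admits both readings.
Constant variables z-score to zero and contribute nothing.

Mantel tests correlate lower triangles and permute rows and columns of
the second matrix jointly; the default alternative is one-sided positive
(the convention of the common implementations), with a two-sided option.
For n ≤ 8 an exact mode enumerates all n! relabelings. Permutation
p-values carry the +1 correction.

## Co-abundance networks

Basis correlations follow the SparCC estimator: per inner iteration,
fractions are resampled from Dirichlet(counts + 1); the variation matrix
T_ij = Var log(x_i/x_j) is formed from the log-fraction covariance; basis
variances ω solve t = [(D−2)I + J] ω; and ρ_ij = (ω_i + ω_j − T_ij) /
(2√(ω_i ω_j)), clamped to [−1, 1]. The most strongly correlated pair with
|ρ| above the exclusion threshold (0.1) is iteratively removed from the
linear system (up to 10 rounds), with per-taxon exclusion caps so the
system stays solvable; non-positive ω are floored at 1e-4. The reported ρ
is the component-wise median over 20 inner iterations. Default counts
(20 iterations, 10 exclusion rounds, threshold 0.1, +1 pseudocount)
follow the estimator's standard workflow and are all configurable.

Edge calling uses two devices computed from shuffled tables (each taxon's
counts permuted independently across samples, i.e. without replacement):
per-pair two-sided pseudo-P values, (1 + #{|ρ_null| ≥ |ρ_obs|}) /
(1 + n_tables), and a per-network magnitude threshold equal to a high
quantile (default 0.99) of the pooled null |ρ|, so that thresholds
represent equal levels of confidence across networks with different
abundance distributions. An edge is retained iff pseudo-P < 0.01 *and*
|ρ| ≥ threshold. The reference bootstrap count is 10,000; tests and the
reproduction script use a few hundred shuffled tables, which fully
resolves the 0.01 cutoff (minimum attainable pseudo-P is
1/(n_tables+1)) at a fraction of the cost. Null-table inference uses
fewer inner iterations (default 5) since the null is an ensemble.
Network metrics (degree histograms including isolated nodes, connected
components, mean degree, largest-component fraction) are computed on the
undirected edge set.

Known bias: with realistic count noise the planted-pair estimate of a
true basis correlation of 0.8 centres near 0.76 — the Dirichlet prior and
multinomial sampling attenuate strong correlations slightly. This is a
property of the estimator, not of the implementation, and is well within
the recovery tolerance used in validation.

## Synthetic generator

Latent dynamics per domain: a base log-abundance vector (standard
normal), origin profiles = base + N(0, legacy_sd²) per taxon, and per
generation

log p_child ∝ log p_parent + A·p_parent + N(0, drift_sd²),

where A is a sparse signed interaction matrix (connectance ×
strength_sd), followed by a multinomial transfer bottleneck of
`transfer_depth` cells (extinct taxa stay extinct; `None` means
exhaustive transfer) and multinomial sequencing at `seq_depth` (columns
sum exactly to depth). A single linearised update per generation is
deliberate: it produces tunable, connectance-dependent instability and is
analytically checkable at zero noise, without integrating continuous
dynamics. Bacteria and fungi are generated independently and share
metadata; cross-domain coupling is out of scope of this version.

DOC is a linear readout of the *bacterial* latent composition (the
emulated system's composition–function links are strongest for bacteria):
DOC = baseline + scale · Σ wᵢ pᵢ + N(0, noise²), clipped at 0, with
weights wᵢ ~ N(0,1) on a configurable fraction of taxa (options force
positive weights or place them on the most abundant taxa, for recovery
experiments that plant known DOC producers). CO₂ = intercept +
tradeoff·DOC + noise with a negative default tradeoff, mirroring the
DOC–respiration trade-off expected of stable communities; TN is drawn
independently.

Defaults emulate the study conditions: 10 origins, 2 G0 replicates, 4
lineages/origin, 5 generations; sequencing depths equal the study's
rarefaction depths (5,457 / 6,670); legacy_sd 1.0 and drift_sd 0.3 give
origin-dominated composition (PERMANOVA origin R² ≫ generation R²);
doc_baseline 3, doc_effect_scale 20 and doc_noise_sd 0.3 put DOC near
2–4 mg g⁻¹ with per-generation CVs around 0.2–0.45 and pooled ΔDOC
quartiles of roughly 0.2 / 0.6–0.8 mg g⁻¹, the scale of the emulated
measurements. What the generator does *not* emulate: litter chemistry,
intra-generation time courses, cross-domain interactions, and
compositionally structured measurement error — so passing recovery tests
demonstrate correctness of the statistical machinery under the stated
model, not performance on real sequencing data.

## Validation experiment designs

The `validation` module fixes the following designs (sizes chosen so each
experiment runs in seconds to minutes on one CPU):

- **Calibration**: Mantel and PERMANOVA type-I error over 200 null
  simulations (n = 15/20 samples, 199/99 permutations); network false
  edges on fully shuffled 20 × 50 tables with 199 null tables, averaged
  over 5 runs.
- **Drift recovery**: paired cohorts of 100 lineages (25 origins × 4)
  over three generations share a seed — identical communities and DOC
  mapping — and differ only in drift_sd (0.05 vs 0.5). Nuisance noise is
  held low (exhaustive transfer, no interactions, dense effect weights,
  assay noise 0.05, legacy_sd 0.3, baseline 10 so DOC never clips at 0):
  a recovery experiment varies the parameter of interest and quiets
  everything else. Because ΔDOC is half-normal within a cohort, a small
  fraction of high-drift transitions always lands near zero; the
  low-drift share of the most-stable quartile concentrates around
  0.85–0.95.
- **SparCC recovery**: 20 runs, 30 taxa × 100 samples, one planted basis
  correlation of 0.8; median estimate and edge-detection rate with 199
  shuffled tables.
- **DOC-taxon recovery**: 50 runs planting a single positive effect on
  the most abundant bacterial taxon (assay noise 0.1); the taxa ~ DOC
  screen must flag it positively at p_adj < 0.05.
- **Coupling mechanism**: 50 runs each of 20 first-generation microcosms
  where DOC is either a noiseless dense function of composition or
  dominated by assay noise (scale 1, noise 4); the composition ~ DOC
  Mantel test should be significant in the former and not in the latter.

## Limitations

- PERMANOVA supports only free permutation; nested/restricted designs
  (e.g. permuting within origins) are not available.
- The SparCC null uses whole-table shuffling for both pseudo-P and the
  magnitude threshold; per-pair bootstrap resampling variants are not
  implemented.
- BIOM input is not supported; tables are tab-separated text.
- The generator's interaction term is phenomenological; it creates
  connectance-dependent instability but is not a mechanistic
  consumer-resource model.
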