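# Methods

## Residue quantification

Amino-sugar masses are computed by internal-standard GC quantification:
`m_x = m_i · (A_x / A_i) · Rf_x`, where `m_i` is the added myo-inositol
mass, `A_i`/`A_x` the inositol and analyte peak areas, and `Rf_x` a
detector response factor relative to inositol. The printed form of this
equation is ambiguous about where `Rf` sits; we place it as a multiplier
calibrated from pure standards (`Rf = (m_std/m_i_std)·(A_i_std/A_std)`)
with default 1, which reduces to plain area-ratio quantification under a
uniform detector response. Masses are scaled by the analysed dry soil mass
to g kg⁻¹. N-methylglucamine, added before derivatization, provides an
optional recovery fraction.

Residue pools follow the standard biomarker conversions: `BRC = MurN × 45`,
`BRN = MurN × 6.67`; fungal glucosamine removes the bacterial share
assuming 2 mol GlcN per mol MurN,
`fungal GlcN = (GlcN/179.17 − 2·MurN/251.23) × 179.17`, then
`FRC = fungal GlcN × 9` and `FRN = fungal GlcN × 1.4`. A negative fungal
GlcN — legitimate in bacteria-dominated samples with measurement noise —
is clamped to zero and flagged rather than raised. These definitions give
two exact identities used as invariants: FRC:FRN = 45:7, BRC:BRN =
45:6.67, and degree-1 homogeneity. Galactosamine is quantified but enters
no conversion. Contribution ratios (BRC/SOC etc.) are stored at full
precision; one-decimal rounding happens only when rendering, because
published replicate-averaged ratio columns are not exactly reproducible
from rounded means (observed discrepancies up to 1.5 percentage points).

Group comparison uses one-way ANOVA followed by Fisher's LSD with the
pooled within-group mean square (df = N − k). The compact-letter display
assigns letters to maximal cliques of the non-significance graph, so two
groups share a letter exactly when they are not significantly different.

## Distance statistics

All distance machinery is built on the Gower-centered matrix
`G = −½·J D² J` (J the centering projector), whose trace is the total sum
of squared distances `Σ_{i<j} d²_ij / N`.

* **Rarefaction** subsamples each sample without replacement (multivariate
  hypergeometric) to exactly the target depth; shallower samples are
  dropped with a warning. The subsampling method is a package choice.
* **PCoA** eigendecomposes `G`; coordinates are eigenvector·√eigenvalue
  for positive eigenvalues; negative eigenvalues are reported, not
  corrected; axis signs are fixed by making the dominant coordinate
  positive so downstream axis scores are reproducible.
* **PERMANOVA** partitions tr(G) sequentially (Type-I) over the hat
  matrices of the cumulatively dummy-coded design; pseudo-F uses the full
  model's residual mean square; p-values permute raw sample labels with no
  strata, `p = (#{F* ≥ F} + 1)/(n_perm + 1)`, defaulting to 9,999
  permutations. An exhaustive mode enumerates all N! label orders (N ≤ 8)
  for exact small-sample inference. Pairwise tests on factor levels use
  two-group PERMANOVA with Benjamini–Hochberg adjustment and
  clique-derived letters.
* **Dispersion homogeneity** embeds samples by PCoA keeping imaginary
  axes, measures each sample's distance to its group centroid as
  `sqrt(max(0, d²_real − d²_imag))`, and tests the one-way ANOVA F on
  those distances by permuting group labels and recomputing centroids.
* **Variance partitioning** computes the Ezekiel-adjusted R²
  (`1 − (1−R²)(n−1)/(n−1−m)`, m the design rank) of db-RDA for every
  subset of 2–4 explanatory groups. Unique fractions are
  `adjR²(all) − adjR²(all∖g)`; the shared fraction is pooled
  (`adjR²(all) − Σ uniques`) rather than decomposed into all Venn cells,
  so fractions plus the residual sum to one by construction; per-subset
  adjusted R² values are retained for finer decompositions.
* **Single-variable db-RDA** projects `G` on one centered regressor:
  `R² = xᵀGx/(xᵀx·trG)`, `F = R²/((1−R²)/(N−2))`, permutation p. When the
  regressor is a PCoA axis, R² equals that axis's proportion explained —
  a property used as a numerical cross-check.

## Association networks and keystones

Networks are built over the k most abundant OTUs after rarefaction
(default 500; ties broken lexicographically) plus soil-variable nodes
(SOC, TN, BRC, BRN, FRC, FRN). Every pair is tested by Pearson correlation
with a two-sided t test (N − 2 df); edges require `p < 0.05` **and**
`|ρ| > 0.5`, with no multiple-testing correction by default (an optional
BH mode exists). Abundances enter untransformed (a log option exists).
Centralities are degree, degree/(n−1), Wasserman–Faust closeness
(component-scaled, since thresholded networks are routinely disconnected)
and normalized betweenness. The keystone is the OTU node simultaneously
maximal in closeness, betweenness and degree centrality; when the three
maxima disagree, a logged fallback takes the best mean min–max-normalized
score. Variable nodes anchor the network but are never keystone
candidates.

## PLS path modeling

Reflective (Mode A) estimation with the path inner-weighting scheme:
latent scores are unit-variance weighted sums of standardized indicators;
inner proxies regress each latent on its predecessors and correlate it
with its successors; outer weights update as indicator–proxy correlations
until the summed squared change of |weights| falls below 1e-7 (max 300
iterations). Orientation is fixed per block by making the dominant
loading positive. Path coefficients are OLS of each endogenous latent on
its predecessors; GoF = √(mean block communality × mean endogenous R²),
with GoF > 0.7 conventionally acceptable. Effects decompose by the matrix
power series of the (acyclic) coefficient matrix: total = direct +
indirect. Significance comes from a nonparametric bootstrap (default 500
resamples) with per-block sign alignment to the full-sample fit,
percentile intervals, and a sign-based two-sided p floored at
2/(n_boot + 1) — so 500 replicates can resolve `**` but `***` requires
n_boot ≥ 2000. Single-indicator models reduce exactly to standardized OLS
path analysis, which the tests exploit as an oracle.

The default inner structure mirrors the field design: binary
inorganic/organic/season/depth blocks → bacterial and fungal community
blocks (PCoA axes 1–2 as indicators) → residue blocks (C and N pools) →
SOC and TN. How season and depth are signed is a package convention (the
second level codes 1).

## The synthetic experiment generator

The generator emulates a 39-year rice–wheat fertilization trial:
4 regimes (NoF, NPK, M, NPKM) × 2 seasons × 2 depths × 3 replicates = 48
samples, and serves as the ground-truth acceptance surface for every
downstream stage.

**Latent system.** A linear SEM over standardized latents: design factors
(standardized binaries) → community axes → residue pools → SOC/TN.
Each endogenous latent's structural residual is drawn orthogonal to its
parents and scaled so the latent has exactly unit sample variance; the
configured coefficients are therefore the *true standardized
coefficients*, which the path-model recovery tests target. Defaults put
the stronger residue→soil paths on the fungal side (0.60/0.55 vs
0.25/0.30), reflecting the larger fungal contribution to soil C and N.

**Communities.** OTU log abundances combine a static base (sd 1.2), direct
additive shifts from each design factor for 10% of OTUs (coefficient
sd 0.4), a loading on the marker's community latent for 25% of OTUs
(magnitudes 0.33–0.37), idiosyncratic replicate noise (sd 0.6 — soil
replicates vary substantially), and multinomial read sampling at
Poisson(40,000) depths, leaving rarefaction at 30,000/25,000 real work.
Loading magnitudes are drawn from narrow bands rather than a normal
distribution: heavy-tailed loadings create single dominant hub taxa that
are not part of the intended ground truth.

**Keystone and guild.** One fungal OTU is planted with log abundance
`2.5 + 0.5·k`, where `k` has *exact* in-sample correlation
`keystone_effect` with the fungal-residue latent (Gram–Schmidt
construction; correlation is scale-invariant, so mean and sd are free and
chosen to keep the keystone abundant and its series regular). A residue
guild — 30% of fungal OTUs, loading magnitudes ≈ 0.57–0.63 — tracks the
keystone's abundance itself: a keystone taxon structures the taxa around
it, and guild members co-vary with the residue latent through it. This
geometry (keystone–member correlation `a`, member–member `a²`) makes the
planted keystone the network's natural triple-maximal node: recovery under
the default network rule was 600/600 across two disjoint 100- and 500-seed
validation ranges, with the strict rule firing in ~99% of datasets.

**Chemistry.** True amino-sugar masses are log-linear in the residue
latents with biological noise sd 1.0 on the log scale — residue pools
integrate years of turnover, so plot-to-plot variability around the latent
is substantial. GC peak areas are back-computed by inverting the
quantification equation exactly (the round-trip is machine-precision), and
SOC/TN are linear in their latents with small observation noise
(`noise_sd`, default 0.3).

**Determinism.** One root seed spawns named sub-streams per table, so a
config edit in one component does not shift the draws of another.

**What the generator does not emulate.** Real amplicon data have
compositional zero-inflation beyond the multinomial (a `zero_inflation`
flag exists, default off), taxon-specific sequencing biases, phylogenetic
correlation among OTUs, and chromatogram-level artefacts; the published
statistics of the real trial (pseudo-F values, path coefficients) depend
on the real OTU tables and are not reproduction targets. Passing tests
demonstrate correctness of the statistical machinery and recoverability of
planted structure, not the field result itself.

## Problem sizes

Defaults were chosen so a full pipeline run (48 samples, 400 + 200 OTUs,
9,999 PERMANOVA permutations, 500 bootstrap replicates) completes in well
under a minute, and the validation suite — including 500 null PERMANOVA
simulations, 100 keystone-recovery datasets and 50 path-recovery fits —
in about one minute on one CPU.

## Known limitations

* Raw-scale Pearson correlation over lognormal abundances is
  leverage-sensitive at n = 48: single co-spiking samples can create
  spurious edges. The network module reproduces the published edge rule
  faithfully; compositionality-aware alternatives are out of scope.
* The pooled shared fraction in variance partitioning does not separate
  two-way from higher-order overlaps.
* PERMANOVA permutes labels freely; blocked/restricted permutation is not
  implemented.
* Bootstrap confidence intervals are percentile-based; no BCa correction.
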