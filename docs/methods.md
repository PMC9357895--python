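# Methods

This note documents the statistical procedures implemented in `stemtrace`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Data model and preprocessing

An `AbundanceMatrix` holds non-negative LFQ intensities (proteins ×
samples), a boolean missingness mask and per-protein unique-peptide counts.
Missing entries are treated as left-censored low-abundance observations:
they are replaced by zero, and the mask is preserved so downstream stages
can distinguish structural zeros from measured zeros.

The preprocessing chain runs in the order **filter → replace → normalize**:

1. *Master-protein filter*: keep proteins supported by more than two unique
   (and razor) peptides, i.e. `unique_peptides ≥ 3`.  The cutoff is
   configurable (`min_unique_peptides`); 0 disables the filter.
2. *Zero replacement* as above.
3. *Median normalization*: each sample is divided by the median of its
   **nonzero** observed entries.  Zeros are excluded because after
   replacement a raw median would depend on each sample's censoring depth
   rather than its scale; with the nonzero convention every sample's
   nonzero median equals 1 afterwards and the operation is idempotent.
   Normalizing each sample to its own median (target 1) rather than to a
   grand median only differs by a global constant, which no downstream
   statistic depends on.

Accepted missing-value tokens on read are the empty cell, `NA` and `NaN`.
When a matrix is written after zero replacement, the zeros serialize as
numbers; only still-unreplaced (NaN) entries serialize as empty cells, so
the structural-zero mask survives a round trip only for raw matrices.

## Day-specificity statistic

For protein *j* and day *d*,

    Z_jd = (<p>_jd − <p>_all) / σ_j

with `<p>_jd` the mean normalized abundance over the samples of day *d*,
`<p>_all` the mean over **all** samples of that protein, and `σ_j` the
sample standard deviation (n−1 denominator) over all samples of that
protein.  The mean and σ are per protein, not pooled across proteins: a
cross-protein pool would be dominated by between-protein abundance scale
and could not produce per-day specificity with a single cutoff.  The
statistic is computed on the normalized raw scale by default (a log2(x+1)
option exists); it is invariant to any global rescaling of the matrix.
Conventions: σ = 0 (constant protein) gives Z = 0 on every day, and the
specificity rule is the strict inequality `Z_jd > threshold` (default 1.5).
For every protein the sample-size-weighted z-scores sum to zero across
days, which the tests exploit as an exact invariant.

*Threshold scan.*  A protein's multiplicity is the number of days it is
specific to.  Lower thresholds call more proteins but blur day exclusivity
(multiplicity > 1); higher thresholds call fewer, strictly day-exclusive
proteins.  The scan computes, over a grid (default 0.5–3.0, step 0.1), the
number of proteins specific to ≥ 1 day and the mean multiplicity among
them, then selects the smallest threshold whose mean multiplicity is
≤ 1 + tol (tol = 0.05) — the balance point that keeps the most proteins
while day calls remain essentially exclusive.  The ≤ 1 + tol rule is this
package's formalization of that balance; if no grid value attains it the
largest grid value is returned with a warning.

*Over-representation.*  Day-specific sets are tested against user-supplied
annotation collections (GMT format) with the one-sided hypergeometric
upper-tail probability of the observed overlap, terms intersected with the
caller-supplied background, terms below `min_term_size` skipped, and
Benjamini–Hochberg adjustment across tested terms.  No ontology database is
bundled or queried.

## Trajectory clustering

Each (protein, replicate) pair contributes one profile row: the protein's
per-day abundance in that replicate (day-cell means when several samples
exist), normalized to unit sum so clustering sees trajectory *shape* only.
Unit-max normalization is available as an option.  All-zero rows are
dropped and counted.  Clustering is Euclidean k-means with k-means++
seeding, best of 10 restarts by inertia, 300-iteration cap, deterministic
under a fixed seed; k defaults to 20 and is fully configurable.  Since the
replicates are pooled, per-cluster replicate composition (fraction of
member rows per replicate) acts as a concordance diagnostic: exchangeable
replicates should contribute ≈ 1/R to every cluster.  Each cluster's peak
day is the argmax of its centroid, ties broken toward the earliest day.
"Top shared proteins" of a cluster are those whose rows land in that
cluster for every replicate present, ranked by mean abundance across all
samples; their per-day expression is reported normalized by each protein's
maximum day value.

## Moderated differential abundance

Adjacent-day (and endpoint) contrasts are two-group comparisons on
log2(x + pseudocount) abundances, pseudocount 1 on the normalized scale
(needed because structural zeros remain after replacement).  The
per-protein residual variance `s²_g` with `d_g = n1 + n2 − 2` degrees of
freedom is shrunk toward a prior variance:

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)
    t_g   = logFC_g / (s̃_g · √(1/n1 + 1/n2)),   logFC = group2 − group1

with two-sided p-values from the t distribution on `d0 + d_g` degrees of
freedom.  The prior `(d0, s0²)` is estimated by moment matching on the log
variances: under the hierarchical model `s²_g ~ s0²·F(d_g, d0)`, the mean
and variance of `log s²_g` have closed forms in digamma/trigamma functions;
the trigamma equation is inverted by Newton iteration.  If the empirical
spread of `log s²` does not exceed what `d_g` alone implies, the prior is
degenerate (`d0 = ∞`) and every protein is tested against the common
variance `s0²` with a normal reference.  At `d0 = 0` the statistic is
exactly the ordinary pooled-variance two-sample t.  This moderated test is
a deliberate, documented stand-in for a precision-weighted count pipeline:
the data are intensities, not counts, so no mean–variance precision
weights are estimated, and results are expected to differ in detail from
count-based tools while sharing the shrinkage behaviour.

Benjamini–Hochberg step-up adjustment is applied across proteins.  A
protein is flagged significant under strict inequalities
`p_adj < p_cutoff` (default 0.05) **and** `|logFC| > lfc_cutoff` (default
1).  The volcano table reports `(logFC, −log10 p_adj)` and a class in
{`significant`, `p_only`, `lfc_only`, `ns`}; the display cutoff used for
volcano colouring is configurable independently of the significance cutoff
(e.g. 1e-4 versus 0.05).

## Reference comparison and influence analysis

For each (condition, timepoint) pair, the derived dataset's per-protein
mean abundance vector is correlated (Pearson) with the reference dataset's
mean vector for the same condition, over the intersection of proteins with
nonzero mean in both datasets (zeros are structural missingness, so a
protein undetected in either dataset is excluded).  Correlations use the
normalized raw scale by default, matching mean-abundance semantics; a log2
option exists.  Leave-one-out influence removes each shared protein in
turn, recomputes r by the same code path (so "matches direct recomputation
exactly" is a meaningful test), and reports Δr per protein.  The top
influencer is the protein with the largest |Δr| (lexicographic
tie-break); the report presents r with and without it, mirroring the
with/without-vimentin presentation style.  An explicit exclusion list is
also accepted, so a named a-priori exclusion is expressible.  A protein
whose removal leaves a zero-variance vector gets undefined (NaN) influence
and is excluded from the argmax.

## Synthetic-data generator

`simulate_timecourse` emulates a differentiation time course: per-protein
baseline log2 intensities ~ Normal(20, 2) (log-normal intensities, wide
dynamic range, consistent with the median-normalization premise);
day-specific marker proteins planted as a +2.0 log2 mean shift on their
day (50 per day by default), which simultaneously defines the five
"peak-day" profile archetypes, remaining proteins flat; within-protein
replicate noise sd 0.35 log2 units (≈ 25% CV, typical of cell-culture LFQ
biological replicates, and calibrated so the planted markers are
recoverable by the 1.5-z rule — the package's stated recovery targets are
properties of these defaults); per-sample multiplicative scale distortions
`2^Normal(0, 0.25)`; left-censored missingness with logistic probability in
true log2 intensity (rate 0.05 at the global median, steepness 1 per log2
unit — overall ≈ 13% missing, concentrated in low-abundance proteins);
unique-peptide counts 1 + Poisson(4) so a realistic fraction (~9%) falls
below the master-protein filter.  The truth object records marker days,
archetypes, sample scales and the pre-censoring log2 matrix so every
planted effect can be recomputed independently.

`simulate_reference_pair` draws two vectors from a bivariate normal with a
chosen population correlation (location 10, scale 1, so values stay
positive) and adds a discordant +shift to chosen outlier entries of the
second vector only — the "vimentin analog".  `simulate_condition_pair`
extends this to matched NM/OM endpoint matrices: one latent reference
proteome per condition, derived timepoint vectors correlated with it at the
target r, three replicate samples scattered around each vector (sd 0.2),
and the same outlier proteins reused across pairs.

*What the generator does not emulate*: peptide-level data and rollup,
retention-time alignment, batch effects, correlated protein modules,
intensity-dependent variance beyond censoring, or real biological pathway
structure.  Passing tests therefore demonstrate that the statistics recover
the structure they target under idealized noise — not that they would
reproduce any particular real dataset's protein lists.

## Pipeline orchestration

`run_pipeline` executes simulate → preprocess → dayspec → cluster → diff →
compare from one `RunConfig` (YAML-loadable).  A single integer seed is
fanned out deterministically to per-stage substreams (affine map modulo
2³¹−1), so the whole run is reproducible byte for byte; the manifest
records config, package version, stage status and sha256 checksums of all
outputs.  Stage toggles control whether a stage's outputs are written; the
in-memory chain always preprocesses the simulated raw matrix, so disabling
the preprocess stage never feeds raw censored data to later stages.  All
products are TSV tables (z-scores, per-day protein lists, scan table,
cluster assignments/centroids/composition/peak days/top-shared lists,
per-contrast differential tables with volcano classes, comparison reports
and influence tables); no figures are produced.

## Numerical choices and degenerate inputs

- Median of an even-length vector is the midpoint convention (numpy);
  post-normalization medians equal 1 to ≤ 1e-12.
- σ = 0 proteins: Z ≡ 0; identical groups in the moderated test: logFC = 0,
  p = 1; zero moderated variance with nonzero logFC (only possible at
  d0 = 0): t = ±∞, p = 0.
- Trigamma inversion: Newton from `x = 0.5 + 1/y`, asymptotic branches for
  extreme arguments, 50-iteration cap at 1e-10 relative tolerance.
- BH adjustment: mergesort (stable) ordering; exact step-up arithmetic.
- k-means ties and initialization are delegated to scikit-learn with a
  fixed `random_state`; restarts keep the best inertia.
- Empty clusters yield zero composition rows and a logged warning rather
  than an error.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the default design (2000
proteins × 15 samples) for normalization, day-specificity (10 seeds) and
the threshold scan; 250 proteins × 3 replicates for archetype recovery
(k = 5); 200 null replications of 2000 proteins for type-I calibration;
5000 proteins for prior recovery; and 100 simulations of 5000-protein
vector pairs for the influence analysis.  These sizes give tight Monte
Carlo error on every reported rate while keeping a full run to a few
minutes on one CPU.

## Known limitations

- The moderated test is not a reimplementation of any specific external
  tool; exact numerical agreement with count-based precision-weighted
  pipelines is out of scope.
- Only two-group, no-covariate contrasts are supported.
- Zero replacement is the only missing-value treatment; no imputation or
  batch correction.
- Enrichment requires caller-supplied annotation sets; no ontology
  database access.
- The generator's independence assumptions (no protein–protein
  correlation) make clustering recovery easier than on real proteomes;
  ARI numbers should be read as implementation checks, not benchmarks.
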