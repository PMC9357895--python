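# stemtrace

Time-course label-free proteomics (LFQ) analysis for stem-cell
differentiation studies — in particular, proteome characterization of an
iPSC → smooth-muscle-cell differentiation over days 0, 3, 5, 7 and 10, and
comparison of the derived cells against a primary-cell reference under
normal (NM) and osteogenic (OM) culture conditions.

The package implements, as a tested and reusable pipeline:

- **Preprocessing** — master-protein filtering (more than 2 unique
  peptides), replacement of missing (left-censored) values with zero, and
  per-sample median normalization over nonzero intensities.
- **Day-specificity** — the per-protein z-score statistic

  `Z_jd = (<p>_jd − <p>_all) / σ_j`

  where `<p>_jd` is protein *j*'s mean abundance on day *d*, `<p>_all` its
  mean over all samples and `σ_j` its standard deviation over all samples.
  A protein is specific to day *d* when `Z_jd > 1.5`; a threshold scan
  selects the smallest cutoff at which the mean *multiplicity* (days per
  specific protein) drops to ≈ 1.  Over-representation of the resulting
  sets in user-supplied GMT annotation collections uses the one-sided
  hypergeometric test with Benjamini–Hochberg correction.
- **Trajectory clustering** — k-means (default k = 20) on unit-sum temporal
  profiles of combined replicates, with replicate-composition diagnostics,
  peak-day cluster identification and top shared proteins per time point.
- **Differential abundance** — empirical-Bayes moderated t-tests between
  adjacent days on log2 abundances: `s̃²_g = (d0·s0² + d_g·s²_g)/(d0+d_g)`,
  `t = logFC / (s̃_g·√(1/n1+1/n2))` with d0 + d_g degrees of freedom, BH-FDR
  across proteins, and volcano-ready significance classes.
- **Reference comparison** — Pearson correlation of mean-abundance vectors
  with leave-one-protein-out influence analysis, flagging the single
  protein whose removal changes r the most (e.g. a persistently
  overexpressed cytoskeletal protein such as vimentin).
- **Synthetic data** — an LFQ-like generator with planted day-specific
  markers, profile archetypes, left-censored missingness, sample-scale
  distortions and discordant reference outliers, so every stage is
  verifiable against known ground truth without any deposited dataset.

## Worked example

```python
import stemtrace as st

cfg = st.SimConfig(n_proteins=500, markers_per_day=25, seed=42)
matrix, meta, truth = st.simulate_timecourse(cfg)
processed, factors = st.preprocess(matrix)

res = st.day_specific_sets(st.zscore_abundance(processed, meta), threshold=1.5)
scan = st.scan_threshold(res)

profiles = st.build_profiles(processed, meta)
model = st.kmeans_profiles(profiles, k=5, seed=0)

logm = st.log_transform(processed)
diff = st.moderated_t_test(logm, meta, 0, 3)

a, b, truth2 = st.simulate_reference_pair(2000, target_r=0.6, n_outliers=1,
                                          outlier_shift=8.0, seed=7)
report = st.influence_leave_one_out(a, b.to_numpy(), ids=list(a.index))
```

prints (via the obvious `print` statements):

```
proteins kept after master-protein filter: 455 / 500
day-specific proteins: {0: 17, 3: 20, 5: 23, 7: 20, 10: 23}
threshold scan selected: 0.7
cluster peak days: {0: [0], 3: [1], 5: [2], 7: [4], 10: [3]}
day 0 vs day 3: 29 significant proteins (prior d0=2.74)
r = 0.587; top influencer P0791 (planted: ['P0791']); r without it = 0.599
```

Reading the output: the master-protein filter removes proteins supported by
fewer than three unique peptides; each day's specific set contains the
proteins whose day mean exceeds their overall mean by more than 1.5 overall
standard deviations (the 25 planted markers per day dominate these sets);
the five clusters peak on the five distinct days, recovering the planted
archetypes; the moderated t-test finds the day-0/day-3 abundance changes;
and the leave-one-out influence analysis singles out exactly the planted
discordant protein, whose removal raises the correlation toward its target
value of 0.6.

The same stages are available from a shell:

```sh
stemtrace simulate --n-proteins 500 --markers-per-day 25 --seed 42 --out-dir run/
stemtrace preprocess run/matrix.tsv run/samples.tsv --out run/normalized.tsv
stemtrace dayspec run/normalized.tsv run/samples.tsv --scan --out-dir run/dayspec/
stemtrace cluster run/normalized.tsv run/samples.tsv --k 5 --out-dir run/cluster/
stemtrace run --seed 0 --out-dir run/full/      # all stages + manifest
```

All tabular outputs are TSV; `stemtrace run` writes a `manifest.json`
recording the config, seed, package version and a sha256 checksum of every
output, and re-running the same config reproduces the outputs byte for
byte.

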