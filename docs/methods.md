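# Methods

This note documents the statistical models, defaults and design choices
behind `revscreen`, and what the synthetic benchmarks do and do not show.

## Differential expression

**Transcripts.** Counts are normalized with median-of-ratios size factors
(per-gene geometric-mean reference over genes positive in every sample;
per-sample median of count/reference). Each gene is tested with a Wald
statistic on the log2 ratio of normalized group means, with a delta-method
standard error under a negative-binomial variance `mu + alpha*mu^2`. The
overdispersion `alpha` is a gene-wise pooled within-group method-of-moments
estimate `(var - mean)/mean^2`, floored at 1e-8. P-values are BH-adjusted.
This is intentionally a simplified count-DE workflow: no dispersion
shrinkage, no empirical Bayes, no covariates. The pipeline accepts
precomputed DE tables (`transcript_de_table` / `protein_de_table` in the
run config) precisely so that results from full-featured DE packages can
be consumed where their refinements matter. Genes with a zero group mean
or an undefined statistic get p = 1 and status `ns`.

**Proteins.** Zeros in intensity matrices are treated as "not detected"
(absent). Proteins with ≥2 observations per group get a Welch t-test on
log2 intensities; the reported fold change is computed on the *raw* scale,
`log2(mean case / mean control)`, which is the convention the published
worked values follow (group means of raw intensities). The alternative —
difference of log2 means — is deliberately not used; with only pooled
triplicates per group the raw-mean ratio is the more reproducible summary
of the printed tables. Adjustment is Bonferroni over tested proteins.

**One-group proteins.** A protein observed only in one group has an
undefined ratio but is often the strongest biology in the experiment
(on/off switching). Such proteins get a fixed |LFC| equal to the maximum
finite |LFC| in the experiment (`fixed_value="auto"`, overridable), signed
by the detected group. Their significance is a one-sample t-test of the
observed group's log2 intensities against the dataset's minimum observed
log2 intensity — a detection-floor argument: the missing group is at or
below the least intense observation anywhere in the matrix. This choice is
a documented assumption (the convention behind published adjusted p-values
for such proteins is not stated anywhere we could follow); the records are
flagged `lfc_imputed` and the p-value model is isolated in
`impute_one_group_lfc` so it can be swapped.

**DE calls.** `up` iff padj < alpha and lfc > lfc_min; `down` iff
padj < alpha and lfc < −lfc_min; defaults alpha = 0.05, lfc_min = 1
(i.e. a two-fold change).

**PCA outlier screen.** Samples are projected onto the first
`n_components` (default 2) principal components of log2(count+1) (or log2
intensity) data; a sample is flagged when its distance from its group
centroid exceeds `k_sd` (default 3) times the group's RMS distance. The
RMS-distance criterion is our own concrete rule for the usual "PCA
outliers were excluded" step; it is robust to the outlier inflating the
spread only when groups are not tiny, which is the regime where outlier
removal is defensible anyway. A zero-variance matrix yields no outliers
and a warning.

## Disease profile

The profile is the intersection of the two omics' DE gene sets (status
`up`/`down` in both), keyed by uppercase gene symbol, carrying the
transcript LFC and ordered by descending LFC. Direction agreement between
omics is *not* required: cross-omics discordance is biologically real
(translational regulation) and the published intersection does not impose
a sign constraint; discordant genes are flagged in the provenance sidecar
so users can drop them. An empty intersection is a warning, not an error —
the pipeline stops cleanly after writing the (empty) profile.

## Concordance screen

Concordance is the Pearson correlation between profile and signature LFCs
over shared genes, computed locally from signature tables; at least
`min_overlap` (default 10) shared genes are required, otherwise the
signature is skipped (not scored). Retention uses a strict inequality
(`concordance < cutoff`): default cutoff −0.2, with a per-library override
table defaulting to −0.6 for the "LINCS chemical perturbagen" library,
whose exports overlap disease profiles sparsely and therefore produce
noisy correlations. That rationale is generalized into a runtime warning
whenever a library's median overlap is below 20% of the profile size.
Approved-drug filtering matches names after lowercasing, trimming and
whitespace collapsing; no synonym resolution is attempted.

## Clustering

The clustered matrix has profile genes as rows and retained signatures as
columns, with the disease profile appended as a reference column by
default (`k` defaults to 8, so that with the reference appended a cut
reproduces the familiar seven-signature-clusters-plus-reference layout of
reversal heatmaps). Distances are Minkowski (default p = 2, configurable)
over mutually observed genes, rescaled by `(n_genes/n_observed)^(1/p)` so
that sparsely overlapping columns are not spuriously close. Linkage is
Ward in the squared-update (Ward.D2) convention; a column with fewer than
3 mutually observed genes against every other column is excluded, and any
remaining fully unobserved pair gets the maximum finite distance (logged).
The implementation delegates the agglomeration to SciPy; the test suite
holds it equal to an independent brute-force Lance–Williams agglomerator
on all small complete-data instances.

## Scoring and ranking

Per drug, retained signatures are collapsed to a per-gene **median** LFC
(all retained signatures of the drug, not only those in reversal
clusters — the simpler rule, configurable upstream by filtering the
signature list). The Regulation Score weights each reversed gene's
`|LFC_drug − LFC_disease|` by the gene's share of the profile's total
|LFC|; the weight denominator always runs over the full profile, so
missing genes dilute RS rather than being ignored. A sign product of
exactly zero contributes nothing (the piecewise definition covers only
strictly negative and strictly positive products; zero is "no reversal
evidence"). Overall Coverage counts strictly sign-opposite genes only —
"reversed" means moved in the opposite direction, not merely touched.
Ranking is by descending RS, ties broken by descending OC then name;
optional filters keep drugs with `prior_trials == 0` and/or blood–brain-
barrier probability ≥ a threshold (0.9 by convention for brain targets).

## Synthetic data

The generators emulate the study designs this pipeline targets:

- **Cohort counts**: NB with a single dispersion shared across genes
  (default 0.1, a typical bulk RNA-seq value; the planted-recall tests use
  0.05), per-gene baselines log-normal around 2^6.5 ≈ 90 counts spanning a
  few orders of magnitude. Planted genes (default 10%) scale the case mean
  by 2^lfc with |lfc| drawn from 1.5–4 — effect sizes clearing the
  |LFC| > 1 call threshold. Default cohort sizes in tests (20 vs 20 null;
  6 vs 6 power) bracket realistic bulk designs.
- **Proteome intensities**: log-normal with noise_sd 0.4 log2 units;
  "one-group" proteins have the *entire* depleted group absent —
  structural missingness matching on/off proteins; random per-value
  dropout is deliberately not modeled.
- **Signatures**: `−rho·profile + Normal(0, noise_sd)` with independent
  per-gene dropout. `rho` may be negative, producing disease mimics so the
  clustering tests have genuinely separable structure.

What passing these benchmarks does *not* show: robustness to batch
effects, library-specific probe sets, dispersion trends across expression
levels, correlated genes, or drug-name synonymy — none of which the
generators model. The benchmarks establish correctness of the statistics
and recoverability of planted signal, not field performance on messy
public data.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs. Benchmark problem sizes (2000-gene null
simulations, 20-drug/3-signature libraries, ≤6-column clustering oracle
sweeps) were chosen as the smallest instances at which the tested
statistics stabilize.

## Numerical details

- Dispersion floor 1e-8 keeps the Wald SE finite for underdispersed genes.
- Pearson correlation is undefined for constant vectors; such signatures
  are skipped with a log message rather than scored 0.
- Median aggregation uses the exact middle (interpolated for even counts).
- Profile ordering ties break lexicographically on gene symbol, making
  every output deterministic.
- `rank_candidates` assigns ranks after filtering, so rank 1 is always the
  best *eligible* candidate.

## Known limitations

- The transcript DE caller is anti-conservative in principle for very
  small groups (Wald, no shrinkage); with <4 samples per group prefer a
  precomputed DE table from a shrinkage-based tool.
- Signature screening recomputes concordance from the supplied LFC table;
  server-side scores from signature databases may differ when they use a
  landmark gene subset rather than all shared genes.
- Combination-therapy scoring, enrichment analysis, and live database
  retrieval (signatures, trials, BBB predictions) are out of scope;
  annotations enter only as user-supplied tables.
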