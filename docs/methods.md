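# Methods

`tmedissect` re-implements, as a tested pipeline, a strategy for splitting
bulk tumor cohorts into inflamed ("hot") and noninflamed ("cold") immune
microenvironments using immune-cell signatures derived from annotated
single-cell RNA-seq, and for characterizing the two phenotypes across
mRNA/miRNA/lncRNA expression, promoter methylation, drug connectivity, and
survival.  Every stage is validated against a synthetic cohort with planted,
recoverable structure; this note records the models, the defaults, and the
design choices that were genuinely open.

## 1. Marker derivation from single-cell data

Cells whose detected-feature count lies outside [1000, 10000] are removed,
then genes detected in fewer than 3 remaining cells (standard single-cell QC
ranges for full-length protocols).  For each immune cell type a one-vs-rest
comparison is run on log1p counts-per-10k: the test is the two-sided
Wilcoxon rank-sum (the conventional default for this task; for groups of
eight or fewer cells the exact null is used so tiny fixtures are exactly
reproducible), the log2 fold change is computed on group means of CP10k with
a pseudocount of 1, and p-values are Benjamini–Hochberg adjusted across
genes.  Genes with positive log fold change and adjusted p < 0.05 are
ranked by |PCT_target − PCT_malignant| (PCT = fraction of cells of a type
with nonzero count), ties broken by |PCT_target − PCT_rest| and then gene
id, and the top `ceil(0.01 × n_passing)` form the signature.  The ceiling
guarantees a non-empty signature whenever anything passes.  BH (not
Bonferroni) is used throughout for consistency across the package.

## 2. Single-sample enrichment and classification

The scorer is a single-sample weighted Kolmogorov–Smirnov running-sum
statistic: within one sample, genes are ranked by expression (average ranks
for ties), the genes are walked from highest to lowest rank, signature genes
add `rank^tau / Σ_set rank^tau` (tau = 1 by default) and non-signature genes
subtract `1/(N − m)`; the score is the running-sum value of maximum absolute
magnitude, signed.  It is bounded in [−1, 1], depends only on within-sample
ranks (hence is invariant to any strictly monotone transform of a sample's
expression, so counts, CPM, or log-CPM give identical scores), and is exact
against a brute-force loop to 1e−12.  Kernel-smoothed expression-level
scorers used for the same purpose share its inferential role (relative
per-sample set enrichment) but are not oracle-testable from a short
specification; the rank statistic is.

Samples are classified within each tumor type: score columns are z-scored
and winsorized at ±2.5 (without this, a single extreme sample can claim its
own k-means cluster and collapse the three-group structure), k-means with
k = 3 and 50 restarts (fixed seed) is run, clusters are ordered
by the mean over their samples of the row-mean z-score, and the top/middle/
bottom clusters become inflamed/median/noninflamed.  The cluster→label map
is determined solely by this ordering, so label swapping cannot occur.  The
three-group structure is imposed by design (k is fixed, not selected); the
median group is excluded from all downstream contrasts as a buffer against
mixtures.  Clustering is per tumor type because immune scores are not
comparable across tissues.

## 3. Differential multi-omics

Counts are normalized by trimmed-mean-of-M-values (TMM) factors: reference =
sample whose upper-quartile count fraction is closest to the cohort mean;
per sample, M and A values on doubly-nonzero genes; two-sided trimming of
30% of M and 5% of A (rank-based, both tails); factor = 2^(inverse-variance-
weighted mean of the surviving M values), with the delta-method variance
`(N−y)/(Ny)` summed over the pair; factors are rescaled to geometric mean 1.
The implementation agrees with edgeR's `calcNormFactors(method="TMM")` to
1e−6 on random fixtures (cross-checked via Rscript in the test suite).

Differential expression between inflamed and noninflamed samples is a Welch
t-test on log2(CPM + 0.5), with log2FC = log2((mean CPM_noninflamed + 0.5) /
(mean CPM_inflamed + 0.5)).  Positive log2FC therefore means "up in
noninflamed".  An NB-GLM with empirical-Bayes dispersion shrinkage would be
the heavyweight alternative; at the simulated group sizes (≥ 20) the Welch
test on log-CPM is well calibrated (verified by null simulation) and the
bespoke downstream step — pan-cancer aggregation — is preserved exactly:
a molecule enters the pan-cancer signature iff |log2FC| > 1.5 and BH-FDR <
0.05 in at least 4 tumor types, direction recorded per type.  BH families
are per molecule class × tumor type.

Promoter differential methylation tests M-values (logit2 of beta, beta
clipped to [1e−3, 1−1e−3] for variance stabilization) with a Welch t,
restricted to probes annotated TSS1500/TSS200/5'UTR/1stExon; the effect is
reported as delta-beta (noninflamed − inflamed) on the beta scale, and a
probe is significant iff adjusted p < 0.05 and |delta-beta| > 0.1.

Over-representation is a one-sided hypergeometric tail with fold enrichment
`(overlap/|query|)/(|set|/|universe|)`, BH across annotation sets; real
pathway databases are supplied by the user as GMT files.

## 4. Noncoding regulation

Spearman correlations (average ranks, two-sided t-approximation p, BH within
each noncoding-RNA × tumor-type family, minimum 10 paired samples) link
noncoding RNAs to mRNAs.  lncRNA partners: mRNAs significant (FDR < 0.05)
in ≥ 1 tumor type, ranked by mean |rho| over the tumor types where the pair
was measured (missing values excluded, never zero-filled); the top
`ceil(0.01 × n_kept)` are reported with the edge sign of the mean rho.
miRNA targets additionally require membership in a user-supplied (or
simulated) interaction database and rho < 0.  Constant expression vectors
yield missing correlations, never zero.

## 5. Drug connectivity

The classic tag-list KS statistic: with V(j) the sorted rank of the j-th of
t tags in a profile of N genes, `a = max_j(j/t − V(j)/N)`, `b = max_j(V(j)/N
− (j−1)/t)`, ks = a if a > b else −b.  Per drug, ks_up is computed from the
inflamed-up tags and ks_down from the noninflamed-up tags; the raw score is
ks_up − ks_down when the signs differ and 0 otherwise; positive scores are
divided by the maximum positive raw score and negative by the magnitude of
the most negative, so the extremes are ±1.  Positive normalized connectivity
= the drug drives the inflamed program, i.e. a candidate cold→hot converter.
Tag lists longer than 500 genes are truncated to the largest |log2FC|.
One profile per drug; multi-cell-line instance aggregation and permutation
p-values are out of scope.

## 6. Survival

Kaplan–Meier curves, the (g−1)-df log-rank test, and Cox proportional-hazards
fits are delegated to lifelines (Efron tie handling, its default); the
package adds the 95% CI convention exp(beta ± 1.96·se), an explicit
non-convergence flag for monotone likelihoods (perfect separation raises a
warning, never silent), and the two bespoke operations:

* **Maximally selected cutpoint.**  Candidates are midpoints of consecutive
  sorted unique marker values leaving ≥ minprop (default 0.1) of samples on
  each side.  Each candidate is scored by the standardized linear rank
  statistic of the log-rank (Savage) scores `a_i = δ_i − Λ̂(t_i)` (Nelson–
  Aalen cumulative hazard): `z = |S − E(S)|/sqrt(V(S))` with S the score sum
  of the low group and E, V its permutation moments.  This is the
  maximally-selected-rank-statistics construction; note that repeatedly
  computing two-sample log-rank chi-squares is *not* equivalent and can
  prefer extreme splits even for perfectly separating markers, which is why
  the linear-rank form is used.  Ties prefer the smallest cutoff.
* **Pooling.**  Fixed-effect inverse-variance pooling of per-tumor-type log
  hazard ratios; studies with non-finite SE are dropped.  Random-effects
  pooling is out of scope (and not identifiable from 3–4 strata anyway).

## 7. The synthetic world

The generators plant every quantity the pipeline is supposed to recover.
All randomness flows from one integer seed; identical configs give
byte-identical outputs.

**Single cell.**  5 cell types (one malignant) × 200 cells, 3000 genes.
Counts are gamma-Poisson (negative binomial) with gene-level lognormal
dispersion (median 0.2), lognormal library sizes (σ = 0.35), lognormal
baseline abundances.  Each cell type carries a broad lognormal background
program (σ = 0.7 per gene × type): real cell types differ in thousands of
genes, and without this background the one-vs-rest passing set would
collapse onto the planted markers and a "top 1%" selection would be
meaningless (capacity 1 gene).  Planted markers (5 per type) sit at a fixed
low baseline (0.12 expected counts) and are multiplied by `marker_fold`
(25) in their home type only, giving them the extreme PCT contrast that the
selection rule keys on.  The fully exchangeable null used by calibration
tests is `marker_fold = 1` **and** `type_program_sigma = 0`.

**Bulk cohort.**  3 tumor types × 100 samples (4 types in the end-to-end
script so the ≥ 4-types rule binds).  Infiltration f is a three-mode Beta
mixture (modes 0.05/0.20/0.45, concentration 150, equal weights — the
proportions are a free choice; equal thirds keeps every stratum testable).
Expected expression is the linear mixture `(1−f)·malignant + f·immune`
on the count scale: immune markers scale as `(1−f) + f·marker_fold`,
malignant markers as `(1−f)·marker_fold + f`, and marker baselines are
pinned to the cohort median abundance so that the rank-based score retains
dynamic range (a lognormal baseline draw can park a marker at the top of
every sample's ranking and saturate the score).  40 planted DE genes carry
an extra fold of 4 between the hot and cold strata (half up in each; the
median stratum gets the geometric midpoint).  Half of the unplanted genes
are weakly coupled to f (|log-slope| uniform in [0.8, 1.8], sign random):
this emulates the broad covariation of real tumors with immune content,
keeps those genes below the |log2FC| > 1.5 calling threshold (max true
log2FC ≈ 1.04), and gives the lncRNA "top 1% of significant correlates"
rule a realistic denominator.  Signal lncRNAs follow a latent `f + ε`
(ε ~ N(0, 0.07)) with log-slope 4, and their 5 planted partner genes share
that latent, so the partners out-correlate everything merely f-coupled.
Signal miRNAs combine a stratum fold with their own lognormal noise and
suppress their 5 planted targets log-linearly (slope −0.6 per SD); the
simulated interaction database contains the true targets plus 3 uncoupled
decoys per miRNA.  Methylation betas are Beta-distributed (precision 50)
with 40 planted promoter probes shifted by delta-beta = 0.3 between strata
(baselines chosen so no clipping occurs; the planted difference is exact in
expectation).  Survival is exponential with log hazard `−hazard_coeff·f`
(hazard_coeff = 1, so the hot-vs-cold hazard ratio is ≈ exp(−0.40) ≈ 0.67,
inside the range reported for immune-favorable markers in this literature)
with uniform administrative censoring on [0, 4800] days (≈ 30% censored).

**Drug database.**  100 drugs as uniform random rank permutations of the
gene universe, except one converter whose profile places the hot-specific
planted genes uniformly in the top 5% of ranks and the cold-specific genes
in the bottom 5%.

**What the generator does not emulate** — and hence what a green test does
not establish: scRNA dropout/ambient contamination beyond NB sampling,
doublets, many-to-many probe↔gene mappings, batch effects, correlated gene–
gene noise beyond the planted couplings, non-proportional hazards, and
cell-type composition variation within the immune compartment.  Recovery
rates measured here are upper bounds on real-data performance.

## 8. Numerical conventions and degenerate inputs

* Average ranks everywhere ties occur; stable sorts with documented
  tie-breaks (gene id last).
* BH adjustment via statsmodels `fdr_bh`; families as stated per stage.
* Constant genes: p = 1 and logFC = 0 in marker stats; missing (never 0) in
  correlations.
* Empty QC results, empty tag lists, all-zero connectivity, groups with no
  subjects, markers with < 2 distinct values, and all-infinite pooling SEs
  raise explicit errors or warnings rather than returning silent defaults.
* The tag-list KS statistic attains −1 exactly when a single tag occupies
  the last rank; otherwise it is strictly inside (−1, 1).
* Known limitation of the classifier: k-means minimizes within-cluster
  variance, so when the noninflamed cloud is much wider in score space than
  the other two (low infiltration ⇒ signature genes near the rank-noise
  floor), it can occasionally be split in two while hot and median merge,
  inflating the inflamed group of that tumor type.  Winsorization does not
  prevent this mode; per-tumor-type replicates in the tests average over it.
* Seeds: every generator consumes `numpy.random.default_rng([seed, stream])`
  with fixed per-generator stream ids, so the three generators are mutually
  consistent (the drug converter's tag genes are the cohort's planted DE
  genes) yet independent in their noise.

## 9. Test scaling

Monte-Carlo calibration tests use 50–100 replicates at reduced matrix sizes
(documented per test); the two full-pipeline stochastic checks are scaled to
a desktop budget: pooled-HR direction is verified over 20 end-to-end
replicates (≥ 19 must be protective) and classification/marker/DE recovery
over 2–5 replicates of the default world, with thresholds applied to the
replicate mean.  The drug-connectivity recovery runs the full 100 replicates
(it is cheap).
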