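# Methods

This note documents the models, algorithms and numerical choices behind
`fermtx`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates and gap extraction

All intervals are 0-based half-open internally; GFF3 (1-based inclusive)
converts at the I/O boundary and BED6 output is native 0-based.  Gap
extraction is stranded: for each contig and strand separately, every
annotated feature — all biotypes, including UTRs and whole transcripts —
marks its bases occupied, overlapping features are merged, and the
maximal complementary runs are the gaps.  Antisense annotations therefore
do not block a gap on the opposite strand.  Only gaps strictly longer
than `min_gap_length` (default 100 bp, so length ≥ 101) are kept; the
strict inequality is a deliberate reading of the "> 100 bp" rule and is
recorded in the configuration.  Whether reference features should be
merged across biotypes before gap calling was an open choice; merging is
assumed, since any annotated base is annotated regardless of how many
features cover it.

## NPTR calling

A gap's expression statistic is the mean over all samples of its
size-factor-normalized count scaled to fold coverage:
`(k_gj / s_j) · L_read / L_g`, with `L_read = 50` bp.  The call is
inclusive (≥ 4.0) and the whole gap is the unit — no narrowing to covered
sub-intervals, which fragments calls.  A `max`-over-samples statistic is
available behind a keyword but is not the default.  Size factors are the
median-of-ratios estimator with a strictly positive geometric-mean
reference; if no feature is positive in every sample the function raises
rather than silently switching to a pseudo-reference, because the two
estimators are not interchangeable.

## Negative-binomial time-course model

Each feature is modelled as `k_ij ~ NB(mu_ij, alpha_i)` with
`log mu_ij = x_jᵀ beta_i + log s_j` and variance `mu + alpha·mu²`.  The
full design holds an intercept, 11 condition dummies (12 strain ×
timepoint levels, first level as reference) and additive batch dummies;
the static (reduced) design holds intercept + batch only, so the
screening test asks whether expression moves with condition at all while
batch effects are absorbed in both models.

Coefficients are fitted by IRLS (working weights `mu/(1 + alpha·mu)`),
tolerance 1e-8 on the step and the relative log-likelihood change,
maximum 100 iterations; non-converged features are flagged and excluded
from testing.  Features with all-zero counts are dropped up front.

**Dispersion.** `alpha_i` is estimated per feature by maximizing the
Cox–Reid adjusted profile likelihood — the NB log-likelihood at the
IRLS-profiled `beta(alpha)` minus `½ log det(XᵀWX)` — on the log-alpha
scale within [1e-8, 10], initialized by method of moments.  The
adjustment matters: the unadjusted profile MLE is biased low on a
36-sample/14-parameter design (we measured a median of 0.027 at a true
alpha of 0.05), which makes every downstream test anticonservative.  No
empirical-Bayes shrinkage across features is applied; this keeps features
independent at the cost of noisier per-feature dispersions, which the
test references below absorb.

**Test references.** The screening statistic `2(ll_full − ll_reduced)`
(same alpha in both fits, clipped at 0) is referred to `F(11, n − p)`
via `stat/11`, and Wald contrast statistics to `t(n − p)`, where
`n − p = 22` residual degrees of freedom for the standard design.  These
quasi-likelihood-style small-sample references account for the estimated
dispersion; with the asymptotic χ²/normal references the null screening
p-values are visibly non-uniform (≈ 4.5% below 0.01), while under the
F/t references they pass a Kolmogorov–Smirnov uniformity check.  Wald
log-fold-changes are reported in log₂; the between-strain sign convention
is (+prsA − control), and within-strain changes are (later − earlier).

**Contrast covariance.** Standard errors come from the inverse expected
Fisher information `(XᵀWX)⁻¹` at the MLE; a singular information matrix
yields NA estimates with a flag.

## Independent filtering and stage-wise testing

Candidate filter thresholds are the 0th–95th percentiles (step 1) of the
mean normalized count.  For each, screening p-values of passing features
are BH-adjusted at the target level and rejections counted; the smallest
threshold achieving the maximum count is chosen and features below it
are marked not expressed.

Stage I applies BH across the `m` expressed features' screening p-values
at `alpha = 0.01`, giving the screened set S.  Stage II adjusts each
screened feature's 16 contrast p-values by Holm within the feature, then
multiplies by `m/|S|` (capped at 1); features outside S get NA.  This is
the confirmation-stage default of the stage-wise testing framework; the
within-feature correction method is not uniquely determined by the
source analysis, and Holm was chosen as the framework's standard.  A
feature is differentially expressed when any contrast's stage-wise
adjusted p falls below alpha, and strain-specific when that happens in a
between-strain contrast.

## Expression profiles

For each differentially expressed feature and each strain, the profile is
the fitted normalized condition mean at the six timepoints,
log₂-transformed with a pseudocount of 1 (the source is silent on the
pseudocount; 1 keeps zero means at zero) and z-scaled with the sample
(n−1) SD.  Constant profiles become zero rows and are flagged rather than
dropped, so every DE feature keeps a profile.  The two strain rows of a
feature enter one joint matrix — a feature may fall in different clusters
per strain — which resolves an ambiguity in the source description
("clustered separately (one gene = two rows in the data matrix)") in
favour of the two-rows reading.

Clustering is Lloyd k-means, Euclidean distance, best of 25 random
restarts, deterministic given the seed (delegated to scikit-learn).  The
shipped default is k = 10.  Automated selection takes the k in
2..k_max−1 maximizing the second difference of the WSS curve (maximum
curvature), ties resolving to the smallest k with a flag.  This statistic
identifies the true cluster number only when the WSS curve decays
near-linearly before the kink — i.e. when clusters are roughly
equidistant; with hierarchically separated clusters the largest curvature
sits at the top split (k = 2).  The property tests therefore plant
equidistant archetypes; on real profile data the elbow remains a
heuristic, which is why the fixed k = 10 is the default.

## Over-representation with elim

For each contrast, up- and down-regulated significant genes are tested
separately against the background of expressed genes (restricted to
coding genes with ontology coverage).  Per term the one-sided
hypergeometric tail `P(X ≥ obs)` is computed with `N = |background|`,
`K = |term ∩ background|` (after closing gene annotations upward through
the DAG), `n = |query|`; terms with fewer than 10 background genes are
skipped, with eligibility decided on the original closed sets.

`elim` decorrelation walks terms from the deepest level (longest path to
a root) upward; when a term's p-value on its current gene set falls below
`elim_alpha` (set equal to the reporting level, 0.01), its closed gene
set is removed from every ancestor before ancestors are tested.  Leaf
terms are never altered.

Finalization BH-adjusts the p-values over the run's full tested family
and then reports only records with observed/expected ≥ 2; significance
requires both the ratio and `fdr < 0.01`.  The alternative order —
shrinking the family to high-ratio records before BH — was measured to
inflate the permuted-query null any-significant rate from ~0.2% to ~3%
at a nominal 1%, because the ratio filter selects positively deviating
terms; the full-family adjustment preserves the FDR guarantee while
keeping the ratio rule as the reporting filter.

## ORF benchmarking and composition

A gene counts as recalled when some same-strand ORF overlaps it with
Jaccard similarity strictly above 0.9; an ORF matches when it recalls
some gene; recall and precision are percentages at one decimal.
ORF-vs-gap overlap tables are strand-agnostic (antisense placements are
real observations) and report overlap as a percent of the ORF length,
with each gap categorized by its NPTR and differential-expression status.

CDS translation uses the bacterial genetic code; GTG and TTG initiators
are rendered as Met.  A sequence is complete iff its length is a codon
multiple, it starts with ATG/GTG/TTG, ends with a stop and has no
internal stop; only complete proteins enter composition backgrounds.
Backgrounds are per-amino-acid means and sample (n−1) SDs of per-protein
percent compositions; z-scores are reported at one decimal and flagged
when the unrounded |z| exceeds 2 SD.  The designated skewed proteins
(amylase/PrsA analogues in the simulator) are excluded from backgrounds.
The "top expressed" background takes the ⌈0.10·n⌉ genes by mean
normalized count, ties broken lexicographically by id.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study conditions: 2 strains × 6 timepoints × 3
replicates with 3 round-robin sequencing batches; NB counts with variance
`mu + alpha·mu²` at `alpha = 0.05`; per-sample size factors in
[0.7, 1.4]; batch multipliers within ±0.2 log₂; feature baselines
log-normal around 2⁷ counts; 10% non-null features at |log₂FC| = 1.5,
half as strain effects (all +prsA conditions shifted) and half as step
time effects (later half of the course shifted in both strains); gap
coverages cycled through a configured set that straddles the 4×
threshold; a two-level rooted ontology whose planted terms draw ≥ 80% of
their genes from the DE set; and i.i.d.-composition proteins with skewed
targets constructed to sit a requested number of background SDs above
the mean.

What passing tests show: the implementation recovers exactly the truth it
plants, controls its nominal error rates under its own noise model, and
matches independent oracles on every desk-checkable computation.  What
they do not show: robustness to features real data has and the generator
omits — overdispersion heterogeneity and outliers, correlated counts
along operons, coverage that varies within a gap, ontology annotation
bias, mapping artefacts, or batch effects that interact with condition.
Conclusions about real datasets still require the usual diagnostics.

## Problem sizes and determinism

The default test and acceptance runs use deliberately compact problem
sizes — e.g. 2,000 features for the global-null calibration of the
stage-wise procedure, 500 features for fold-change recovery, 500
permutations for the enrichment null, 100 random layouts for the
gap-extraction oracle — chosen so the full validation remains a
minutes-scale desk exercise while keeping Monte-Carlo standard errors
small relative to the tested bounds.  All stochastic components flow
from integer-seeded numpy `default_rng` streams (the simulator derives
independent substreams per stage from one seed), so every dataset,
cluster assignment and acceptance number is reproducible bit for bit
from the seed.

## Known limitations

* Per-feature dispersions without shrinkage are noisy at 3 replicates;
  the F/t references compensate for calibration but power is below what
  trend-shrunken estimators achieve.
* Step-shaped planted time effects are confirmed by a single informative
  contrast out of 16, so the Holm stage noticeably taxes their power;
  gradual real profiles spread evidence over several contrasts.
* The elim traversal uses one fixed elimination cutoff; there is no
  weighting variant.
* `assign_reads` is a reference implementation over alignment intervals,
  quadratic in the worst case; production-size BAM quantification should
  use a dedicated counter upstream and feed the resulting matrix in.
* OBO parsing is limited to `id:`/`name:`/`is_a:` stanzas (the formats
  the pipeline writes and reads); full OBO 1.4 semantics are out of
  scope.
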