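# Methods

`metaminer` covers the downstream half of an MS metabolomics study: it
starts from an integrated peak table (samples x variables of ion
intensities) and carries it through preprocessing, compound annotation,
reaction-ratio expansion, differential statistics, machine-learning marker
screening, generalized correlation against a microbiome, and pathway
topology/enrichment analysis.  This note documents the models, the
defaults, and the choices made where the design was genuinely open.

## Preprocessing

**Outlier replacement.** Per variable, the mean and sample SD (n-1) are
computed once over the observed values; points with |x - mean| > 3 SD are
replaced by the maximum of the unflagged values.  The rule is deliberately
single-pass (not iterative): re-running it on its own output can flag new
points because the moments change, and the audit report records counts per
variable so that behavior is visible.  An `side="high"` option restricts
flagging to the upper tail for users uncomfortable with replacing low
outliers by a maximum.

**Imputation.** Three strategies with different assumptions:

- `minimum` — the variable's observed minimum; a detection-limit surrogate
  that is biased upward but deterministic.
- `knn` (k = 10, capped at n-1) — unweighted mean of the k nearest samples
  by Euclidean distance over the variables observed in both samples, after
  z-scoring so high-intensity variables do not dominate the metric.
- `qrilc` — quantile regression imputation of left-censored data.  Per
  variable, the observed values are treated as the upper part of a normal
  sample: the sorted values are paired with standard-normal quantiles at
  plotting positions that assume the missing values are the smallest, and
  mean/SD are estimated by least squares on the upper 75 % of positions
  (where censoring cannot distort the fit).  Missing cells are drawn from
  that normal truncated above at the observed minimum (and below at zero,
  since intensities are physical).  Draws are reproducible given a seed.

**Normalization.** `total_intensity` divides each sample by its row sum and
rescales by the median of the original row sums, so values stay on an
intensity-like scale and all row sums become equal.  `internal_standard`
divides by a designated variable.  `qc_rlsc` fits, per variable, a LOESS
curve (degree 1, span 0.75) to the QC-sample intensities as a function of
injection order, interpolates the curve at every sample's order, and
divides it out — the standard QC-based robust LOESS signal correction for
instrumental drift.  At least five QC injections are required.

**Transforms.** Natural log (zeros offset by half the variable's smallest
positive value) and per-variable z-scoring.  The log transform sets a
provenance flag so that downstream fold changes are reported on the raw
scale (`exp` of the log-scale difference).

The workflow order is outliers -> imputation -> normalization -> log,
matching the order in which the pathologies arise (integration artifacts,
censoring, per-sample scale, skew).

## Annotation

LC-MS features are matched by exact mass with the ppm convention
(observed - reference)/reference * 1e6, tolerance 10 ppm (inclusive), after
applying adduct shifts ([M+H]+, [M-H]-, [M+Na]+ by default); candidates are
ranked by |ppm error| with ties broken by |RT error| then compound id, so
output is a deterministic total order.  GC-MS features are matched by
cosine similarity of square-root-intensity-weighted spectra binned at 1 Da
(unit-mass convention); a hit requires similarity strictly greater than 0.7
and, when both retention times are known, |RT difference| strictly below
0.3 min.  Cosine was chosen over weighted dot-product variants and is
isolated in one function (`spectral_similarity`) so the metric can be
swapped without touching the matching logic.

## Reaction-ratio expansion

For every substrate -> product pair in the reaction database whose two
compounds map to measured variables, a `product/substrate` ratio variable
is appended.  When several variables map to one compound the one with the
highest median intensity represents it (deterministic and robust; recorded
in the provenance table).  Ratios are undefined where the substrate is zero
or missing.  Because a ratio cancels any per-sample factor, expansion
commutes with total-intensity normalization — an algebraic property the
tests assert.  Reversible pairs yield one ratio as listed unless
`both_directions` is set.

## Univariate statistics

Welch's t is the default two-group test (robust to unequal variances;
pooled t, Mann-Whitney, paired variants, ANOVA and Kruskal-Wallis are
available).  Correction is Benjamini-Hochberg FDR by default, with
Bonferroni and Holm as alternatives, all delegated to statsmodels and
verified against textbook step procedures in the tests.  The joint
selection rule for differential variables is p < 0.05 AND OPLS-DA VIP > 1,
both strict.

## PCA and (O)PLS-DA

PCA is the SVD of the centered (and by default unit-variance scaled)
matrix; the sign convention (largest-magnitude loading positive) makes it
deterministic.  PLS-DA is NIPALS on a dummy-coded response (tolerance
1e-10, max 500 iterations, initialized from the first response column).
OPLS-DA first removes class-orthogonal components (orthogonal signal
correction) and then fits one predictive component — the standard two-group
formulation.  VIP is computed from the predictive weights and
per-component explained response variance, normalized so mean(VIP^2) = 1.

Model quality is Q2 from 7-fold cross-validation with folds stratified by
group.  The permutation test refits the whole CV pipeline under label
shuffles and reports p = (1 + #{perm Q2 >= observed Q2})/(1 + n_perm)
(add-one estimator, so p is never zero); Q2 rather than R2Y is permuted
because R2Y is optimistic on permuted labels in wide data.

## Machine-learning screens

- **Random forest** importance is the mean decrease in held-out accuracy:
  forests are fitted per stratified CV fold and each variable's importance
  is the accuracy drop when it is permuted in the held-out part.  (On
  training data an overfit forest shows zero drops, which is why the
  estimate must be cross-validated.)  Defaults: 500 trees, mtry = sqrt(p).
- **SVM** ranking uses |weight| for the linear kernel and recursive feature
  elimination (dropping the worst 20 % per step by permutation importance)
  for polynomial/radial/sigmoid kernels; C = 1, gamma scaled.
- **Boruta** appends a row-permuted shadow copy of every candidate, fits a
  forest, and scores a hit when a candidate's importance exceeds the
  maximum shadow importance; a binomial test on the hit count (alpha 0.01,
  Bonferroni over candidates) confirms or rejects, with undecided variables
  tentative at `max_iter` (default 100).  More iterations resolve more
  borderline variables; chance-correlated noise can legitimately be
  confirmed because relevance is judged within the given sample.
- **Collaborative screen**: per bootstrap resample, PLS-DA, random forest
  and linear SVM are fitted and each variable's out-of-bag accuracy drop
  under shuffling recorded; tier A requires a positive drop in
  significantly more than half of the bootstraps (one-sided binomial,
  alpha 0.05).  The final set is the union of tier-A variables across the
  three classifiers.  This implements the collaborative contract with a
  two-tier decision, simpler than the published multi-tier scheme it is
  inspired by.

## Correlation and GRaMM

Classical pairwise methods (Pearson, Spearman, Kendall) use scipy; partial
Spearman rank-transforms both margins *and* the confounders, then
residualizes and correlates the residuals.

The generalized metabolome-microbiome procedure works per metabolite-taxon
pair on the natural scales of each side: log intensities for metabolites
(applied internally unless the table is already log-scale) and centered
log-ratios for taxa (zeros replaced by half the smallest positive value).
Both features are residualized on the known confounders by OLS.  The label
then comes from a two-stage rule: a distance-correlation test of the
*residuals of the linear fit* against the taxon (199 permutations, seeded)
detects curvature beyond any linear component; if significant at 0.05 the
pair is nonlinear and reported with the full distance correlation and its
permutation p, otherwise linear with the Pearson r and p.  This rule keeps
a genuinely curved relationship labeled nonlinear even when it also has an
incidental linear component — a comparison of channel p-values fails there
because the permutation p is floored at 1/(n_perm + 1).  q is FDR across
all pairs.

## Pathway analysis

Each pathway is a directed compound graph; reversible reactions are stored
once and expanded to two arcs for directed measures.  Seven centrality
algorithms are offered.  Conventions: degree and closeness respect
direction (closeness = reciprocal of summed shortest-path distances over
reachable nodes, 0 for isolated nodes); betweenness is computed on the
undirected graph and normalized by (n-1)(n-2)/2 ("relative"); eigenvector
centrality is computed on the undirected graph (a directed eigenvector is
ill-defined on reaction graphs that are not strongly connected) by power
iteration on A + I (the shift guarantees convergence on bipartite graphs)
and scaled to max = 1.  Eigenvector is the default.

Enrichment is the one-sided hypergeometric upper tail P(X >= k) with the
library universe as population (a `universe` argument allows the measured
set instead); q is FDR across pathways.  Pathway impact is the centrality
mass of the hit nodes divided by the total centrality, in [0, 1]; an
edgeless graph falls back to the hit fraction with a warning.  Enrichment p
depends only on set overlaps and impact only on topology, so switching the
centrality algorithm changes impact but leaves the p vector bit-identical —
asserted as a contract.

## Extras

Hierarchical clustering supports seven distances (Minkowski exponent 3 by
default, to be distinct from Euclidean and Manhattan; "binary" is Jaccard
on the nonzero pattern; "maximum" is Chebyshev) and seven linkages through
the Lance-Williams family (ward = ward.D2, mcquitty = WPGMA,
median = WPGMC, centroid = UPGMC).  ROC analysis uses the rank
(Mann-Whitney) AUC with midrank tie correction and reports the
Youden-J-maximizing cutoff.  Power analysis solves noncentral-distribution
equations via statsmodels for two-sample/paired t, one-way ANOVA and two
proportions, with standardized effect sizes (Cohen's d, f, h) and sample
sizes rounded up.  Venn supports 2-6 sets with exact region counts.

## Synthetic data

The generator emulates a two-group MS study: log-normal baseline
intensities (log-scale SD 0.6, per-variable baselines spread with SD 1.5),
additive group effects on the log scale in SD units on a random subset of
variables, optional linear injection-order drift, pooled-QC injections at a
fixed cadence, and missingness that is left-censored by default (values
below the per-variable rate quantile go missing), which makes the QRILC
assumption true by construction.  A companion generator couples a
compositional taxa table to the metabolite table with planted linear
(log-metabolite proportional to log-taxon), quadratic (symmetric, hence
zero asymptotic linear correlation), and confounder-driven pairs.  A third
generator emits random connected pathway graphs together with the exactly
matching reaction-pair database, so ratio expansion and pathway analysis
share one ground truth.

What the generator does **not** emulate: correlated variable blocks,
heavy-tailed or batch-structured noise, adduct/isotope redundancy among
features, and compositional sequencing noise in the taxa table.  Passing
recovery tests therefore demonstrate correctness of the algorithms under
their stated assumptions, not field performance on real studies.

## Problem sizes and numerical choices

The recovery tests use n = 30 per group, p = 200 with 10 planted markers at
1.5 SD across 20 seeds; Boruta runs 50 iterations of 100-tree forests
there, and 100 iterations in the small-p unit tests.  Calibration checks
use 2,000 null variables (univariate), 50 replicates of 39-permutation
OPLS-DA (null permutation p), and 100 null metabolite-taxon pairs (GRaMM).
Permutation defaults: 199 shuffles for distance correlation (p resolution
0.005), 200 label permutations for OPLS-DA.  All stochastic steps take
explicit seeds and are bit-reproducible.

## Known limitations

- Raw-spectra processing (peak picking, deconvolution, alignment) is out of
  scope; the toolkit starts at the peak table.
- OPLS-DA is restricted to two groups and one predictive component;
  multi-block and multi-response variants are not offered.
- The collaborative screen's two-tier decision is a simplification of the
  published multi-tier algorithm.
- GRaMM's channel design (Pearson + distance correlation with the
  residual-nonlinearity arbitration) is one concrete instantiation of the
  generalized-correlation idea; MIC or kernel tests could be substituted
  behind the same interface.
- The hypergeometric universe defaults to all compounds in the species'
  pathway library; with sparse custom libraries the measured-compound
  universe option is usually more appropriate.
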