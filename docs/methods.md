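# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the limitations a user should keep in mind.

## Preprocessing

Expression enters as TPM (each cell's values sum to 10⁶) and is
transformed to log2(TPM+1). Cell types with *fewer than* 50 cells are
excluded (strict inequality: a 50-cell type is retained); the filter is
idempotent and reports dropped types with counts.

**Imputation.** Technical zeros can be filled by one of two
interchangeable methods, both obeying the same contract: only zero
entries may change, every changed entry is flagged in a per-entry mask,
values stay nonnegative, and `none` is the identity.

- `knn_smooth` (default): a cell's zeros are replaced by the mean of its
  k = 10 most correlated cells (Pearson, on log values) within the same
  tissue group and cell type.
- `low_rank`: iterated truncated-SVD completion (hard-impute). Zeros are
  initialized at observed gene means, the block is projected to rank
  r = 10, zero entries refreshed, and the cycle repeated (20 iterations
  or refill convergence at 1e-6). A single SVD of the zero-corrupted
  matrix is biased toward zero; the iteration removes most of that bias
  (median absolute error under 20% of entry scale on rank-3 test
  matrices with 10% masked entries).

The mask is load-bearing: PCA downstream excludes imputed entries from
its covariance.

**Imputation and the permutation null.** Smoothing within cell type
writes the type labels into the data. If the label-permutation test is
run afterwards, the null is anticonservative — in simulations with no
planted effects the fraction of p ≤ 0.05 rose from ~0.05 to ~0.26.
Pooled kNN smoothing (neighbours drawn from all cells) preserves
calibration, as does testing unimputed data. The within-type default is
kept because it is the conservative choice for *estimating* type
programs (no cross-type borrowing), but calibration checks in the test
suite run the permutation test on unimputed data, and users combining
within-type imputation with the permutation test should interpret small
p-values cautiously.

## Pathway activity

For gene *g*, cell type *t*: mean expression E_{g,t}, relative
expression r_{g,t} = E_{g,t} / mean_t' E_{g,t'}. Genes whose mean is
zero in every type have undefined r and are excluded (recorded).
Row-wise, mean_t r_{g,t} = 1 exactly; multiplying one gene's expression
by any c > 0 leaves r unchanged.

Pathway activity is the weighted average of member genes' r with
weights w_g = 1/(number of metabolic pathways containing g), computed
over the metabolic collection only — signature sets such as the
hallmark hypoxia set do not contribute to multiplicity. Outliers are
excluded per pathway × type by Tukey fences on the member r values
(k = 1.5, configurable; fences are skipped below 4 usable members,
where quartiles are not meaningful). Pathways with fewer than
min_genes = 5 usable genes in a type are reported absent, not zero.
The outlier rule and the minimum are deliberate parameters: the
procedure this stage follows states that outliers were removed without
fixing a rule.

**Permutation significance.** The null shuffles the full cell-type
label column (type sizes preserved) and recomputes the entire
aggregation — including outlier fences — each iteration. Two-sided
extremeness is |PA − 1|, since activity is a ratio-like score centred
at 1 and both high and low activities are of interest. The p-value uses
the add-one estimator (1 + exceedances)/(1 + n_perm), which cannot
return 0; permuted scores that are absent (too few genes) count as
non-exceeding. Default n_perm = 1000, seed 1729, both recorded in the
result. A planted 2× program at 200 cells/type is recovered with
PA > 1 and p ≤ 0.05 under these defaults.

## Heterogeneity: PCA scores and preranked GSEA

PCA runs on log2(TPM+1) values of the metabolic genes, centred per
gene. Entries flagged as imputed are excluded by the pairwise-complete
convention: per-gene means use each gene's observed cells, and each
covariance entry averages centred products over cells where both genes
are observed (denominator n_ij − 1). A complete-case mode (drop any
cell with an imputed entry among the selected genes) is available.
Pairwise-complete covariance need not be positive semidefinite;
variance shares are taken over the nonnegative part of the spectrum.

The component selection is the minimal prefix of variance-ordered
components whose cumulative share strictly exceeds 0.80 (the crossing
component included). The per-gene score sums absolute loadings over
that prefix, so it is invariant to component sign flips and to cell
ordering. Ranking is descending by score with lexicographic gene-id
tie-breaks (stable).

GSEA uses the weighted Kolmogorov–Smirnov running sum: walking the
ranked list, hits add |score|^p normalized over the set's hits, misses
subtract 1/(N − N_hit); ES is the extreme running-sum value. The weight
exponent defaults to p = 1 with 1000 permutations, the conventional
defaults of preranked enrichment tools. The null permutes gene labels
(random same-size subsets of the list); NES divides ES by the mean |ES*|
of same-sign permutations and the p-value is the add-one same-sign
exceedance rate. Benjamini–Hochberg adjustment across sets is reported
alongside raw p. If every hit score is zero (possible with p > 0 at the
bottom of a degenerate ranking), hit steps fall back to equal
increments rather than 0/0.

## Per-cell signatures and group comparison

The per-cell-type activity score is undefined for single cells, so
scatter-plot-style analyses use a per-cell signature score: the mean
over the set's genes of per-gene z-scores (each gene contributes
mean 0 / variance 1 across scored cells). Genes absent from the matrix
or constant across cells are skipped and reported; a fully skipped set
is an error. Correlations are computed per cell type between the
hypoxia score and each other signature, Spearman by default (robust to
the skewed score distributions; Pearson available), two-sided p, with
types under 10 cells reported absent.

Tissue-group comparison of individual genes (e.g. the MCT family
SLC16A1/3/7/8) reports log2FC = log2((mean TPM tumor + 1)/(mean TPM
normal + 1)) — pseudocount 1 matching the log2(TPM+1) convention — and a
two-sided Mann–Whitney rank-sum p over cells (exact for small groups
without ties). Dot-plot summaries give per-cluster mean expression
min–max scaled to [0,1] across clusters and the fraction of cells with
expression > 0.

## Clinical immunoreactivity and association

IRS = staining intensity (0–3) × percent-positive grade (1–3); the
attainable values are {0,1,2,3,4,6,9}, so the maximum is 9 and the
minimum 0; expression is "high" iff IRS ≥ 4. Each binary feature forms
a 2×2 table against the class. The two-sided Fisher's exact p-value
follows the point-probability convention — the sum of hypergeometric
probabilities of all same-margin tables whose point probability does
not exceed the observed one — computed in log space via the exact
hypergeometric pmf with a 1e-7 relative tie tolerance (the same device
R uses). This convention was chosen over tail-doubling because it is
the standard R/scipy behaviour; the implementation is verified against
full-margin enumeration with exact integer arithmetic. Zero-margin
tables are uninformative (p = 1 with a warning). Odds ratios are sample
ORs with the Haldane 0.5 correction when any cell is zero. No
multiple-testing correction is applied across features by default
(matching how such tables are conventionally reported); BH adjustment
is available behind a flag.

## Synthetic data

The generator is a stand-in family chosen for closed-form ground truth,
not a fit to any real dataset. Per-gene baselines are log-normal
(median 100 TPM, lognormal sd 1), per-gene dispersions gamma-distributed
(mean = `dispersion`, default 0.5); entry noise is mean-preserving
log-normal; cell-type programs multiply the pre-dropout means of member
genes; columns are renormalized to TPM. Pathways of 10 genes share 20%
of members with their neighbour, exercising the 1/multiplicity weights.
Dropout is Bernoulli with probability falling logistically in the
gene's log-mean, centred at the median so the average rate approximates
`dropout_rate` (default 0.3); dropped entries are recorded, and
post-dropout renormalization is off by default (flagged in the ground
truth either way).

The hypoxia program draws a latent per-cell factor u ~ N(0,1),
multiplies hypoxia genes by exp(s·u) (s = 1.25 by default) and
glycolysis genes by exp(s·v), v = αu + √(1−α²)w. Because expression and
dropout noise attenuate any fixed latent correlation on the observed
scale, α is calibrated by deterministic bisection against the realized
correlation of the final per-cell set means — the quantity `hypoxia_rho`
refers to. Requested correlations outside the achievable range (the
lognormal factors and the noise bound it) fall back to the nearest
endpoint with a warning. At rho = 1 with dispersion and dropout zero
the construction is exactly proportional and the correlation is exactly 1.

IHC cohorts are generated to match requested (yes_high, yes_low,
no_high, no_low) counts exactly; features must agree on the implied
high/low totals, and each patient receives intensity/grade components
drawn uniformly from the combinations consistent with their class.

What the generator does **not** emulate: real gene identities, doublets,
batch effects, ambient RNA, library-size variation, or the empirical
TPM distribution of any particular dataset. Passing tests therefore
demonstrate that the estimators recover effects of the planted form at
the simulated noise levels, not that they would behave identically on
any specific real cohort.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run
comfortably on a single CPU: null calibration pools three independent
simulations of 50 pathways × 6 types (300 cells each, 300 permutations,
≥900 pathway×type pairs); planted-effect recovery uses 600 genes,
3 × 200 cells and 1000 permutations; hypoxia recovery uses 500 cells.
Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by stable hashing of the stage
name, so stages are reproducible independently of execution order, and
identical configs give identical outputs (content-hashed in the run
manifest).

## Known limitations

- Pathway activity is defined on cell-type means; it says nothing about
  within-type substructure.
- The permutation null assumes cells are exchangeable across types;
  within-type imputation violates this (see above), and strong
  sample-level structure would too.
- The GSEA null permutes gene labels, not phenotypes; enrichment
  p-values inherit the usual caveat that inter-gene correlation is
  ignored.
- The Fisher test is exact but unconditional-power considerations
  (mid-p, conditional MLE odds ratios) are out of scope.
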