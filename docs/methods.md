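# Methods

`creland` re-implements, at desk scale, an integrative analysis of
regulatory landscapes across a hematopoietic differentiation panel: a
candidate cis-regulatory element (cCRE) registry is built from nuclease
accessibility peaks and chromatin-state maps, the landscape is summarised
(state coverage, state transitions, meta-profiles, cross-cell-type
comparisons), and gene expression is regressed on chromatin-state
proportions to obtain per-element epigenetic regulatory potential (eRP)
scores and candidate cCRE–target-gene pairs. Because the original
multi-assay datasets cannot be reproduced from scratch, the package ships a
synthetic-data generator with known ground truth; every downstream claim is
tested against that truth or against base-level brute-force oracles.

## The synthetic study

**State maps.** The genome is tiled into `bin_size` (default 200 bp) bins.
The root cell type follows a first-order Markov chain along each
chromosome: with probability `markov_persistence` (0.9) a bin repeats the
previous bin's state, otherwise it redraws from a stationary distribution
that puts `quiescent_target` (0.86) mass on the quiescent state 0 and
spreads the rest uniformly over the remaining 26 states. Every other cell
type copies its parent's state per bin with probability `inherit_prob`
(0.8) and otherwise redraws from the same stationary distribution. This
keeps the marginal state distribution identical in every cell type (so the
quiescent fraction matches the target everywhere) while giving independent
control over along-chromosome persistence and lineage correlation. The
default panel has 20 cell types on a balanced binary "lineage tree".

The default 27-state model (`creland.states`) assigns each state a label,
mean emissions for eight features (ATAC, H3K4me3, H3K4me1, H3K27ac,
H3K36me3, H3K27me3, H3K9me3, CTCF), an accessibility flag (9 open states),
and ground-truth regression coefficients. Promoter-context coefficients are
large for promoter-like states (+3 to +4), moderate for enhancer-like
states, and negative for Polycomb/heterochromatin. Distal-context
coefficients for the accessible states are large (|β| ≈ 4.5–6, including a
negative CTCF-bound open state): each of a gene's five linked elements must
contribute a detectable share of expression variance for link recovery to
be a well-posed problem. We verified by exhaustive subset search that with
weaker effects (|β| ≈ 2) or more expression noise (sd 0.3) the true link
set is *not* identifiable from 12–20 cell types — no method could recover
it — so the shipped effect sizes and noise are deliberate properties of the
study conditions, not estimates of any particular experiment.

**Peaks.** True accessible intervals are maximal runs of accessible-state
bins. Each replicate (default 2) keeps each interval with probability
1 − `peak_dropout` (0.9) and jitters each endpoint by at most one bin.

**Expression.** Gene TSSs are placed uniformly (density is much higher than
a real genome because the genome is scaled to 12 Mb). Each gene links to
`links_per_gene` (5) true cCREs within 1 Mb. On the log2(TPM+1) scale,

    y(g,t) = β0 + Σ_s βp[s]·P_prom(g,t,s) + Σ_s βc[s]·P_pool(g,t,s) + ε,

where `P_prom` is the state-proportion vector of the TSS ± 1 kb window,
`P_pool` the unweighted mean of the linked cCREs' proportion vectors, and
ε ~ N(0, 0.1). The TPM export is 2^y − 1 floored at 0, so log2(TPM+1)
round-trips. The noise default models technical residual noise after
replicate averaging; the noise-sweep tests use 0, 0.5 and 1.0 explicitly.

**Signals.** Per feature, each bin's value is the state's emission mean
plus N(0, `signal_noise_sd`), truncated at 0, exported as bedGraph.

What the generator does **not** emulate: read-level artefacts, mappability,
fragment-length effects, peak-caller behaviour, cell-population
heterogeneity, locus-specific biology (CpG islands, domains), or any
dependence between state assignment and gene position. Because the
marginal state distribution is the same in every cell type by
construction, the generator also does not reproduce the coordinated
decline of active-cCRE and expressed-gene numbers along differentiation
seen in real hematopoiesis — so the expressed-genes-versus-dynamic-cCREs
association and the dominant principal component of accessibility are
near their null values on synthetic data, even though both statistics are
implemented and tested. Passing tests therefore demonstrate correctness
of the pipeline's logic and estimators under the stated generative model,
not performance on real data.

## Registry and landscape conventions

- Coordinates are 0-based, half-open throughout. Book-ended intervals are
  *not* merged when forming discrete elements (peaks, cCREs); base-level
  coverage operations (replicate intersection, multi-catalog union) fuse
  book-ended pieces, since there the unit is the base.
- Replicate reproducibility is the base-level intersection across all
  replicates (strictest reading; exactly checkable against a boolean-AND
  oracle). A single replicate passes through unchanged.
- A merged interval's state in a cell type is its majority-base state,
  ties to the lowest state id. An interval is removed from the registry
  only if it is majority-quiescent in *every* cell type; it is *active* in
  a cell type iff its majority state there is non-quiescent.
- "Dynamic in cell type t" means the element overlaps one of t's
  reproducible peaks by ≥ 1 base.
- Region-level transition matrices reduce each region to its majority
  state per cell type; bin-level matrices tile the genome at `bin_size`.
- Meta-profiles centre on interval midpoints with a ±2 kb window in 20
  position bins by default; bases missing from a sparse track read as 0
  (logged).

## Comparative analytics

Correlation matrices use Pearson or Spearman (average ranks for ties);
constant columns yield NaN entries and are reported, not fatal.
Hierarchical clustering is agglomerative on 1 − r (average linkage by
default). PCA centres each sample (column) and takes the SVD of the
samples × units matrix; variance fractions are normalised squared singular
values and sum to 1. Quantile normalization maps average ranks onto the
cross-column mean of sorted values (ties get the mean of their target
quantiles), which makes the operation idempotent. "Expressed" uses strict
inequality against the TPM threshold.

## The eRP regression

Observations are (gene, cell type) pairs; the response is log2(TPM+1).
Predictors are state proportions in two contexts — the promoter window and
the pooled (unweighted mean) proportions of the gene's selected distal
cCREs. Proportions sum to 1 per context, so the quiescent state is the
reference: its column is dropped and its coefficient fixed at 0, which
makes the fit identifiable with an intercept and the fitted values
invariant to the choice of reference (verified on random instances; the
invariance requires every gene to carry a proper proportion vector, i.e.
at least one selected cCRE). Fitting is ordinary least squares; a
rank-deficient design falls back to the minimum-norm pseudoinverse
solution with a warning — fitted values are unaffected.

The eRP score of element c in cell type t is Σ_s βc[s]·proportion(c,t,s).
Because pooling is an unweighted mean, predicting a gene as intercept +
mean of its pairs' eRP scores is algebraically identical to the pooled
design row; both routes are implemented and asserted equal.

**Candidate screening.** All cCREs with midpoint within 1 Mb of the TSS
(inclusive; promoter-overlapping elements excluded) are candidates. The
screen correlates an activity proxy (the element's eRP under an initial
fit on all pairs, or its non-quiescent proportion before any fit) with the
gene's expression across cell types; pairs below `min_abs_r` (default 0.3)
are dropped, and only the top `max_per_gene` (50) survivors per gene are
kept. With ~12–20 cell types the null |r| has standard deviation ≈ 0.23–
0.30 (inflated further by lineage correlation), so a meaningful threshold
must sit above the null median; the screen is a cost-bounding pre-filter,
not the selection itself.

**Subselection.** The selector iterates (default 4 outer rounds, usually
converging in 2–3): fit the model on the currently selected pairs, score
every candidate element's eRP trajectory under the fitted coefficients,
then re-select each gene's pairs by best-subset search under the model's
own equal-weight pooling: for each candidate subset size k (1 …
`max_links_per_gene`, default 8) a unit-coefficient pursuit approximates
k·(residual after intercept and promoter terms) by a sum of k
trajectories, run from `n_starts` (5) first picks and polished by pairwise
swaps; the size with the lowest sum of squares wins. The equal-weight mean
is the identifying constraint — an unlinked element cannot enter
cheaply because it dilutes the pooled amplitude — whereas purely
correlation-based scores cannot separate a gene's true links from
lineage-correlated bystanders (we measured both the information limit by
exhaustive search and the failure of partial-residual correlation scores
before adopting this design). During selection an element is represented
by its full proportion vector by default; a one-hot majority-state
representation is available (`representation="majority"`) and costs a few
points of recall at 200-bp bins because elements straddle states.
Selection is deterministic; ties break on the lowest candidate index.
Elements with constant trajectories (e.g. reference-state everywhere) are
never selected.

**Evaluation.** Leave-one-cell-type-out: fit on the remaining cell types,
predict the held-out one, report r² = 1 − SSres/SStot over genes and
adjusted r² = 1 − (1 − r²)(n − 1)/(n − p − 1), with n the genes evaluated
and p the fitted coefficients excluding the intercept (undefined when
n ≤ p + 1, reported as NaN). Four gene categories (consistently low,
differentially low, differentially high, consistently high — from a TPM>1
expression call and a log-scale spread threshold of 1) can restrict both
fitting and evaluation. Candidate selection may be re-run inside each
training fold (`selection="pipeline"`); the pipeline default computes the
selection once on the full panel and leaves only the regression
fitting/evaluation to the folds, which is substantially cheaper and
slightly optimistic — the tests that certify recovery use fold-internal
or oracle selections.

**Pair export.** Selected pairs with |eRP| above a threshold in at least
one cell type are exported with per-cell-type scores; when TAD intervals
are supplied, a pair is `same_tad` if a single TAD interval contains both
the element midpoint and the TSS (nested TADs are handled by the
"any containing interval" rule), and the table can be restricted to those.

## Problem sizes and numerics

Default study: 20 cell types, 3 × 4 Mb chromosomes (60k bins), ~6,000
registry cCREs, 2,000 genes. Recovery and evaluation tests use 12 cell
types and 300–2,000 genes; oracle-equivalence tests use ≤ 100 kb toy
genomes where base-level brute force is exact. The regression solves are
dense least squares (≲ 50k × 53); all randomness flows from a single
integer seed through `numpy.random.default_rng`, and two runs with the
same configuration produce byte-identical output files (checksummed in the
run manifest).

## Known limitations

- The pooled predictor is an unweighted (not length-weighted) mean; that
  choice is what makes the mean-of-eRP prediction rule exact.
- Subselection assumes each linked element enters the pooled mean with
  equal weight, mirroring the generative model; under unequal true weights
  the amplitude constraint would be misspecified.
- The registry treats ATAC and DNase peaks interchangeably and does not
  model peak quality.
- Genome-scaled densities (genes and cCREs per Mb) are far above
  mammalian genomes; absolute counts are not comparable to real catalogs.
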