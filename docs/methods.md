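# Methods

`triomics` integrates matched multi-omics profiles (miRNome, peptidome,
proteome measured on the same cohort) for a two-group clinical contrast,
following three complementary strategies. This note describes the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Study design assumed

All workflows operate on an aligned `MultiOmicsSet`: feature x sample
abundance matrices sharing one sample list, plus a two-level annotation
(e.g. non-severe vs severe disease). Sample alignment takes the
lexicographically sorted intersection of annotated sample ids, making the
result independent of block order and of the order of ids in the input
files. The reference design is 18 + 13 = 31 matched samples.

## Strategy 1 — joint dimensionality reduction and factor scoring

Each method decomposes the blocks `X_b` (features x samples) into a shared
factor matrix `F` (samples x k, default k = 2) and per-block weights `W_b`:

* **jnmf** minimizes `sum_b ||X_b - W_b F^T||_F^2` with all entries
  nonnegative, by multiplicative updates; the objective is nonincreasing
  per iteration. Features with negative values are shifted by their minimum
  first (shifts recorded); nonnegative data is factorized unchanged.
  Uniform random initialization under the given seed; stop at relative
  objective change < 1e-6 or 500 iterations.
* **mfa** standardizes features, scales each block by the reciprocal of its
  first singular value (so no block dominates), concatenates feature-wise
  and takes the truncated SVD. For a single block this is exactly PCA.
* **jica** standardizes and concatenates, whitens the sample mode to k
  dimensions and runs symmetric fixed-point ICA with the tanh contrast.
  Sources are unit-variance sample scores; the mixing estimate provides the
  weights. Non-convergence is reported via a flag, not an exception. Note
  that with ~31 samples the contrast is estimated from few observations, so
  different initializations can settle in nearby fixed points; the default
  init seed is 0.

Sign convention everywhere: the largest-magnitude weight per factor is made
positive, so repeated runs produce identical signs.

**Factor scoring.** Each factor's sample scores are clustered 1000 times
with one-dimensional two-cluster Lloyd k-means, initialized from two
distinct data points per run; each run's accuracy is the better of the two
label-to-cluster assignments. The headline statistic is the *mean* accuracy
over runs (the maximum is also reported): the mean is robust to occasional
bad initializations, whereas the maximum of 1000 runs saturates. The
baseline is `max(n1, n2)/n` - 58% for 18/13 - the score of the trivial
single-cluster assignment. Note that a genuine 2-cluster assignment can
score *below* this baseline (the trivial-assignment score is not a lower
bound over all assignments), which is why the score container does not
enforce it. Per method the better of the two factors is kept (ties to the
lower index), and methods are ranked by that accuracy (ties
lexicographically).

**Consensus features.** From each method's chosen factor the top
`ceil(0.05 p)` features by |weight| are selected per block (ties broken by
feature id, so the selection is deterministic and invariant to positive
rescaling). Features selected by at least `required_support` methods
(default: all of them) form the consensus; when empty the threshold relaxes
one step at a time (recording the effective support) - this generalizes the
common situation where no miRNA is shared by all methods but several are
shared by two. Selected peptides are mapped to proteins (deduplicated
count reported) and miRNAs to target-gene unions.

## Strategy 2 — multi-block sparse PLS-DA

Single-block (s)PLS-DA is NIPALS on the standardized block against the
standardized one-hot outcome, with regression deflation of both matrices
per component - the usual discriminant-analysis choice; successive scores
are mutually orthogonal. Sparsity: each component's weight vector is soft
thresholded at the (keepX+1)-th largest magnitude so that exactly `keepX`
loadings are nonzero (ties broken by feature id; a kept entry tied with the
threshold receives a vanishing but nonzero value to honour the exact
count). With full keepX the sparse fit reproduces plain PLS-DA.

The multi-block variant couples all blocks and the outcome: per component,
each block's sparse weight vector is updated in turn to maximize the
design-weighted sum of covariances between its scores and the other
blocks' scores (block-block weight `design_weight`, default 1; outcome
weight fixed at 1), then every block is deflated on its own scores. With
`design_weight = 0` each block decouples to its single-block fit. The
default schedule is 5 components with keepX 50 on component 1, 20 (miRNAs)
or 10 (other blocks) on component 2, and all features afterwards.

Explained variance of component h in block b is
`100 * ||t_h p_h^T||_F^2 / ||X_b||_F^2` on the standardized block; under
regression deflation the rank-1 pieces are orthogonal, so the percentages
sum to 100 over the full rank.

**Similarity network.** For components h <= 2 (default) let `tbar_h` be the
across-block average score. The similarity of features x, z from different
blocks is `sum_h cor(x, tbar_h) cor(z, tbar_h)`; only pairs above the 0.80
threshold (in absolute value) are kept, restricted by default to features
the model actually selected. Note the threshold is demanding: a feature
whose correlation with the latent score is below ~0.9 cannot form an edge
through a single component, so on noisy data the edge list is legitimately
sparse or empty. Network assembly adds miRNA->protein edges from the
target map and peptide->protein edges from the peptide map, with an
optional Smith-Waterman local-alignment fallback (match +2, mismatch -1,
gap -2; accepted at >= 90% identity over the peptide) when sequences are
supplied. Held-out samples are classified by projecting each block through
the deflation loop, averaging block scores and assigning the nearest
class-centroid.

## Strategy 3 — pathway-level miRNA->gene link detection

Pipeline order for intensity data: peptide rows are rolled up to proteins
by geometric mean on the linear scale (equivalently the arithmetic mean of
log2 values - both are implemented and agree), then quantile normalization,
then log2 with a configurable offset (default 1.0, so zeros map to zero).
Quantile normalization uses the average-of-tied-order-statistics dialect;
with ties this intentionally departs from exact equality of column
multisets (the two requirements are incompatible), and is exactly
idempotent on tie-free data.

Per feature, group membership is regressed on the z-scored abundance by
one-predictor logistic regression (IRLS); the p-value is the Wald test of
the slope, falling back to the likelihood-ratio test when complete
separation is detected (|slope| > 15 on the z-scale). The reported effect
size is the log2 fold change computed directly as the difference of group
means on log2 data - a logistic slope is not a fold change, so the two
statistics are deliberately decoupled. Significance is raw p < 0.05 by
default; Benjamini-Hochberg adjustment is available behind a flag but is
off to match the conventional per-feature screening style of this
workflow.

Overrepresentation uses the one-sided hypergeometric test per pathway,
with the background being the measured, mappable genes of each omics (for
miRNAs: the targets of all measured miRNAs) and the query being the
significant subset. A pathway qualifies if p < alpha in at least one
omics. Links are all (miRNA, gene) pairs where the miRNA is significant,
the gene is significant at peptidome (post-rollup) or proteome level, the
pair is in the target map, and the gene sits in a selected pathway; each
link carries a concordance flag (same vs opposite direction). When a gene
is significant in both protein layers, the proteome statistics are
reported and the evidence source marked "both". The default combines
overrepresentation AND link existence; an OR mode (pathway qualifies if it
contains a significant gene or a target of a significant miRNA) is
available behind `mode="or"`.

## Synthetic data

The generator plants a known two-group structure so every stage can be
scored against ground truth: per block `X_b = mu_b + W_b F^T + E_b` on the
log2 scale, with factor 1 of `F` at +/- effect_size/2 per group plus
standard-normal jitter, remaining factors standard normal, sparse loadings
(5% of features, magnitudes U(0.5, 1.5), mixed signs so both up- and
down-regulated features exist), iid Gaussian noise (SD 1.0) and per-feature
baseline intensities U(4, 12). Defaults mirror the reference design -
18 + 13 samples; 100 miRNAs, 400 peptides, 150 proteins, scaled down about
five-fold from a realistic clinical screen so a full run takes seconds.
Peptides are grouped 2-5 per protein and planted protein-wise (all of a
protein's peptides share the loading sign) so rollup preserves the signal.
The knowledge tables are consistent with the truth: the target map contains
every planted miRNA->gene link plus decoy edges; the pathway database has
one "hot" pathway enriched for informative genes and eight backgrounds.
Synthetic proteome feature ids are gene symbols (pre-mapped intensities);
real proteome data with accession ids is supported through an explicit
accession->gene mapping.

With the default effect size (2.0 noise-SD units) the planted factor's
group separation is d = 2, so even a perfectly recovered factor classifies
about 84% of samples on average; observed accuracies on any one realization
scatter around that. What passing tests show is that the pipeline recovers
planted low-rank, sparse, pathway-coherent structure at realistic noise;
they do not show robustness to features of real data the generator omits -
batch effects, missingness patterns, heavy-tailed intensities, correlated
(LD-like) feature blocks, or mass-spec/microarray acquisition artifacts.

## Numerical conventions and limitations

* Determinism: every stochastic step takes a seed; per-factor evaluation
  streams are spawned from one root seed; output files embed the seed and a
  hash of the configuration (excluding the output directory), and repeated
  runs are byte-identical.
* Degenerate inputs: constant features are left centered (flagged) by
  standardization; constant factors score the baseline; empty consensus
  triggers the support fallback; complete separation in the logistic fit is
  flagged, not raised.
* Missing values: features with > 20% missing cells are dropped, the rest
  imputed with the feature minimum (both configurable) - a conservative,
  deterministic default for intensity data where missingness is mostly
  low-abundance.
* Multi-accession protein groups ("P1; P2; P3") keep the first accession by
  default to avoid inflating gene-level counts.
* The jdr registry implements one representative per method family
  (NMF-based, SVD/covariance-based, ICA-based) rather than every published
  joint factorization; externally computed factorizations can be scored
  through the TSV adapter.
* Problem sizes used by the test suite and the acceptance script (default
  generator dimensions, 1000 scoring runs, 20 null replicates) are the
  package's reference desk-scale configuration; all stages accept larger
  inputs unchanged.
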