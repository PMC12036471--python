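# Methods

This note documents the models, parameter choices and known limitations of
the package; everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Eigengene model

The eigengene of a gene panel is the first principal component of the
panel's expression across cells, computed on the weighted correlation
matrix: each gene is standardized by its weighted mean and standard
deviation, and each cell carries weight `N_total / N_type(c)` so that every
cell type contributes the same total weight. This weighting makes the
loadings exactly invariant to duplicating all cells of any one type (the
test suite checks agreement to 1e-8), which is the point of weighting:
abundance differences between cell types should not steer the component.

Choices the underlying procedure leaves open, resolved here:

- **Expression scale.** PCA runs on log2(CPM+1) (the same normalization as
  the DE stage), not raw counts. PCA on raw counts is dominated by a few
  high-mean genes and by library size; variance stabilization plus
  per-gene standardization gives every panel gene comparable influence,
  which is what "weighted average expression" semantics require.
- **Sign.** A principal component is defined up to sign. The score is
  oriented to correlate non-negatively with the mean standardized panel
  expression, so a high eigengene always means high panel expression and
  "overexpressing the eigengene" is well defined. Model comparison
  (`compare_loadings`) re-orients by the sign of the loading sum before
  correlating.
- **Projection norm.** When a fitted model scores a second matrix, the raw
  projected scores are rescaled. The literal equal-Euclidean-norm rule
  makes scores shrink as the validation cell count grows, which would
  distort mean+3·sd thresholds; the default mode therefore matches the
  root-mean-square of the discovery scores (cell-count invariant), and the
  `euclidean` mode implements the literal rule. The choice is recorded in
  the serialized model.
- **Degeneracies.** Constant genes are excluded; a panel needs at least
  two usable genes (one with an explicit flag); exact eigenvalue ties are
  broken toward the eigenvector whose largest-magnitude loading sits on
  the lowest gene index.

## Consensus labeling

Thresholds are the unweighted mean and population (divisor n) standard
deviation of each panel's empirical score distribution in the dataset
being labeled; with ~10^4 cells the sample/population distinction is
negligible. Both comparisons are strict ("more than" / "less than"), so a
cell exactly at a boundary is borderline. For validation matrices the
thresholds are recomputed from the projected score distribution by
default — this keeps labels independent of the projection norm mode — with
the option of carrying discovery thresholds instead. Cell-type enrichment
of senescent cells uses the upper-tail hypergeometric test with all
labeled cells as the population.

## Marker trees

The searched family — a root split `x_g <= t` at an integer threshold,
optionally one further split on one child, at most two distinct genes —
is small, so the learner enumerates it exhaustively and returns the tree
with minimal (optionally class-weighted) training misclassification among
all trees whose leaves hold at least `min_cases` cells. An error-pruned
scan keeps this fast at full scale without changing the optimum. This
replaces the commercial-heritage tree algorithm the original analysis
used; the minCases-style leaf constraint is retained as the device that
keeps trees small, and exhaustive search makes the learner its own
correctness oracle (the suite compares against a naive enumeration on
random instances). Tie-breaks are deterministic: higher information gain,
larger minimum leaf, lexicographically smaller gene name, smaller
threshold. Candidate thresholds are the distinct values observed in the
training column, which realizes every achievable partition; for large raw
matrices an optional per-gene threshold cap thins candidates to evenly
spaced quantiles of the distinct values (the analysis scripts use 16 —
binarized trees, where every threshold is 0, are unaffected).
`min_cases` defaults to 1% of the minority class with a floor of 5, a
data-driven stand-in for the "relatively large" values the original
analysis mentions without stating.

Evaluation reports sensitivity, specificity and standard accuracy
`(TP+TN)/n`, with zero-denominator rates as NaN. The ratio TP/n is
additionally reported as `tp_rate_of_total` because some marker studies
quote that quantity as accuracy; on rare-positive data the two differ
drastically.

## Differential expression

Genes are kept when at least `min_cells` (default 200) cells show a count
of at least `min_count` (default 1); expression is log2(CPM+1), with the
pseudocount of 1 keeping zeros at zero. The minority class is upsampled by
`round(n_major/n_minor)` (half-up; 475 vs 16,871 gives 36).

The **hurdle test** combines a likelihood-ratio test of the group effect
on detection (a 2x2 G-test, the LRT of a binary-covariate logistic model)
with a Gaussian likelihood-ratio test on the positive values, summed as a
chi-square with df = 2 (df reduced when a part is degenerate: detection
identical in both groups, or fewer than two positive cells in a group).
Upsampling enters through per-cell replication weights, exactly equivalent
to row duplication. Under the null (no group effect, no upsampling) the
rejection rate at nominal 0.05 is calibrated — the suite checks it lies in
[0.03, 0.07] on 2,000 null genes at 300 cells per group. With 36x
upsampling the test is anticonservative by construction (replicates are
treated as independent); this mirrors the upstream procedure and is why
calls also require |log2FC| > 6 and confirmation by the second method.
The log2 fold change is the difference of group means of log2(CPM+1) over
all cells including zeros.

The **EMD test** uses the exact first-order Wasserstein distance between
the two empirical distributions (the area between the ECDFs; verified
against a linear-programming optimal-transport oracle to 1e-9). The
p-value is permutational with add-one smoothing, 1,000 permutations by
default, one shared permutation set across genes. Because replication
leaves an ECDF unchanged, upsampling is a no-op for the EMD statistic, and
labels are permuted at the original-cell level. The published EMD score
cutoff of 30 is tied to the internal scaling of the original script,
which is not recoverable; the default configuration therefore uses the
distance in log2-CPM units with a cutoff of 3.0, calibrated once so that
planted effects of |log2FC| >= 6 pass while the coherent-but-weaker panel
upregulation (2 log2 units) does not; the literal 30 is available via the
`published` profile.

Both p-value vectors are BH-adjusted (the upstream tools' default
"adjusted p-value"); calls are intersected and the overlap scored with the
upper-tail hypergeometric test over the tested genes.

## Enrichment statistics

Hypergeometric tails are computed by log-sum-exp over the support, so
extreme significance levels (the published overlap bound corresponds to
log10 p ≈ -397, far below 1e-205) remain finite on the log scale; callers
needing values below the smallest positive double should request the log.
Pathway over-representation intersects each set with the user-supplied
universe (defaulting, for DE enrichment, to the tested genes — standard
over-representation practice) and BH-adjusts across sets. The multi-set
intersection test uses the independent-Bernoulli binomial approximation
(each element survives k uniform draws with probability prod(n_i/N)),
with a seeded Monte Carlo mode for verification; the approximation is
accurate when the n_i/N are small and the suite bounds its error against
Monte Carlo and, for two sets, against the exact hypergeometric tail.

## Synthetic data generator

Counts are gamma-Poisson (negative binomial) with a single dispersion
parameter (size r = 10, mild overdispersion appropriate for UMI data),
per-gene baseline means, and log-normal per-cell library-size factors
(sd 0.15 on the log scale). Defaults describe a 10,000-cell dataset —
7,000 excitatory, 2,000 inhibitory, 1,000 astrocyte — with ~1% of
excitatory cells senescent; ~64 senescent cells at the default seed, a
similar rarity to the labeled populations this analysis is designed for.
Planted structure:

- **Panels** of 22, 48 and 125 genes; 70% of each panel responds with a
  2^2 mean increase in senescent cells, the same responding subset for
  every senescent cell. Panel genes draw baselines from a higher-mean
  gamma (shape 2, scale 5, mean ~10 counts) than background genes (shape
  0.4, scale 25): curated senescence panels consist of well-characterized,
  detectably expressed genes, and a small panel sampled from the sparse
  tail of the transcriptome carries no recoverable eigengene signal at a
  4-fold effect in 0.7% of cells — with these baselines the planted
  component's eigenvalue stands well clear of the Marchenko-Pastur bulk
  even for the 22-gene panel.
- **Markers** (4 genes) are near-binary: a count >= 1 with probability
  0.9 in senescent cells and 0.001 otherwise. Their rarity keeps them
  below the DE detection filter, so they are found by the trees, not the
  DE stage.
- **DE genes** (120) have a fixed low baseline (0.25 counts) multiplied by
  2^6.5 in senescent cells — senescence-induced genes that are near-silent
  in normal neurons. The low baseline also bounds the senescent cells'
  library inflation, keeping the compositional distortion of CPM values
  (which subtracts from every planted log fold change) under ~1 log2 unit.

Gene-level structure (baselines, panel means, responder subsets) is drawn
from a separate `structure_seed`, so replicate datasets with the same
planted structure but independent cells can be generated; per-gene count
substreams make the planted components independent, e.g. adding marker
genes does not perturb unrelated genes' counts. Identical config and seed
reproduce byte-identical datasets.

What the generator does **not** emulate: ambient RNA, doublets, batch or
donor effects, cell-type-specific expression profiles (types differ only
in abundance), gene-gene correlation beyond the planted senescence
program, and the inter-dataset sparsity differences seen across real
cohorts. Passing recovery tests therefore demonstrates the pipeline's
correctness and its behavior under the assumed generative structure, not
robustness to these real-data complications. Within those conditions, one
relationship is worth knowing: the binarized marker-pair tree is usually
the OR-combination of two markers, whose false-positive rate among
consensus non-senescent cells is ~2x the marker leak probability, so with
the default leak of 0.001 the expected specificity sits at ~0.998-1.0
depending on the realized leak draws among the ~10^3 labeled negatives.

## Problem sizes and runtime choices

The default study conditions (10,000 cells x 1,500 genes, 1,000 EMD
permutations) run end-to-end in about a minute on one CPU; oracle
comparisons use instances of up to 300 cells and 25 genes, where naive
enumeration is feasible. These sizes were chosen as the smallest at which
the rare-subpopulation regime (~10^2 senescent cells among ~10^4) is
faithfully represented.
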