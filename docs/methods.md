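# Methods

## Data model and preprocessing

The substrate is a gene × cell-line matrix of CRISPR gene-effect
(dependency) scores, real-valued with explicit missing entries (NaN),
alongside a matched non-negative expression matrix used only for
filtering. Identifiers are opaque, case-sensitive strings; no symbol
aliasing or HGNC resolution is attempted.

Two quality filters run before any correlation:

1. **Expression mask.** A dependency entry whose matched expression value
   is ≤ `zero_tol` (default 0.0, strict zero) is set missing: a gene that
   is not expressed in a line cannot produce a genuine knockout phenotype
   there, so its score is treated as noise. Only the intersection of
   genes and cell lines present in both matrices is evaluated; entries
   without expression data are left untouched and noted in the
   `FilterReport`. The reported masked fraction counts every evaluated
   entry at or below the tolerance, whether or not it was already
   missing — this makes the fraction a property of the expression matrix
   alone and keeps it exact under pre-existing missingness.
2. **Coverage filter.** Genes observed in fewer than `min_lines`
   (default 108) cell lines are removed; the threshold is strict, so a
   gene with exactly 108 observations is retained. Masking runs first, so
   coverage counts reflect post-mask missingness; the alternative order
   would let unexpressed entries prop up a gene's coverage.

Both filters are idempotent and report exactly what they changed.

## Pairwise co-essentiality

The association statistic is the Pearson correlation r of two genes'
dependency profiles over **pairwise-complete** observations (cell lines
where both values are present), with the pair's n reported alongside.
Pairwise deletion keeps the maximum information per pair at the cost of a
different n per pair; a minimum of 3 complete pairs is enforced, and a
constant profile over the complete pairs is an error rather than r = 0.
Spearman rank correlation is available behind a flag but is never the
default: gene-effect scores are approximately continuous and linear
co-variation is the quantity of interest.

The all-pairs engine computes the pairwise-complete statistics with
masked matrix products in one pass. Each gene is pre-centered by its own
global mean first — Pearson r is invariant under a per-gene shift, and
centering keeps the one-pass sums well conditioned. The engine is checked
against a two-pass textbook implementation to 1e-12 on small matrices.

### Permutation-calibrated thresholds

Fixed correlation cutoffs would ignore that the null width depends on the
number of cell lines and the missingness pattern. Instead, each of
`n_permutations` (default 100, minimum 100) rounds shuffles every gene's
profile independently across cell lines — destroying all pairwise
structure while preserving each gene's marginal distribution and
missingness count — and computes r for a random subsample of gene pairs
(default 10,000 per round, capping the quadratic cost). The pooled null
correlations give the cutoffs: `r_pos` at the upper `tail_quantile`
(default 0.005) and `r_neg` at the lower. The estimator refuses to
extrapolate a tail supported by fewer than 10 null values. On an
independent-normal matrix the estimate agrees with the closed-form
Pearson null quantile r = t/√(t² + n − 2) to ±0.02, which is the
calibration test in the suite. The cutoffs are always recomputed from the
supplied matrix, never treated as constants of nature: their magnitude
shrinks with the number of cell lines and widens with missingness.

Everything stochastic in the package flows from a single integer seed via
`numpy.random.default_rng`; identical seeds give bit-identical results.

## Pathway signatures and canonical correlation

Each pathway with at least `min_genes` (default 3) members present in the
filtered matrix is summarized by PCA of its cell-line × member-gene
submatrix: genes are variables, cell lines observations, per-gene
centering. Missing entries are mean-imputed (zero after centering), so
every cell line contributes to every signature and all signatures share
one row space. The number of components kept is
`min(k, #genes − 1, rank)` with `k = 4` by default, reduced further to
the fewest components reaching 80% cumulative variance when that is
smaller — a pathway dominated by one latent program is represented by one
component, while a heterogeneous pathway keeps up to four. Component
signs follow a deterministic convention (the largest-magnitude gene
loading is made positive) so signatures are reproducible across runs.

Two signatures are compared by the **first canonical correlation**
between their component-score blocks: the single score the platform
reports per pathway pair. It is computed from the singular values of the
product of the blocks' orthonormal bases (the QR/SVD formulation used by
standard `canoncorr` implementations). Directions whose singular value
falls below 1e-9 of the block's leading one are truncated, which
regularizes rank-deficient blocks — near-collinear PC scores from heavily
overlapping gene sets — without perturbing full-rank ones: the
self-association of any signature is exactly 1, and a one-component CCA
reduces exactly to |Pearson r| of the two score vectors. An optional
ridge (`ridge > 0`) on each block's covariance is available for users who
prefer shrinkage, at the cost of a small downward bias on all scores.

Member overlap between pathways is *not* removed before CCA; instead the
Jaccard overlap of each pair is reported next to its score so users can
judge inflation from shared genes.

The pathway × pathway score matrix (symmetric, unit diagonal, entries in
[0, 1]) is clustered agglomeratively on distance 1 − score with average
linkage — a middle ground between single linkage's chaining and complete
linkage's sensitivity to one dissimilar pair; the dendrogram exports as
Newick. The **unique-association report** takes a named group of gene
sets and a reference collection and lists, per group member, the
reference pathways scoring ≥ `assoc_cutoff` (default 0.5) with that
member and < cutoff with every other member. The default cutoff sits in
the wide gap the latent-factor model produces between same-factor scores
(≈ 0.9 at the default design) and cross-factor noise (≈ 0.15 at n = 300);
on real data it should be chosen against the score distribution.

CCA runs on PC *scores* (cell-line space), not loadings: similarity of
pathways is defined across cellular contexts, so the shared axis must be
cell lines.

## Literature co-publication index

Given a publication → gene-set annotation (gene2pubmed-style), each
publication contributes exactly 1 to every unordered pair of distinct
genes in its set, regardless of mention frequency. Publications
annotating more than `max_genes_per_pub` (default 500) genes are excluded
with a warning: a single review tagging g genes would otherwise inject
O(g²) co-occurrences. Counts normalize linearly to a 0–100 index,
100 at the corpus-wide maximum pair (the global maximum, not a per-query
one), 0 for never-co-published pairs; the index is computed on demand
from the sparse counts. A threshold-passing pair whose index is ≤
`index_cutoff` (default 5, boundary inclusive) is flagged **novel** —
strong functional evidence with minimal literature precedent. The cutoff
is a screening convenience exposed in config, not a calibrated quantity.

## Network modules

The thresholded graph connects pairs passing `r_pos`/`r_neg`, with r,
n, co-publication index and novelty as edge attributes (GraphML and TSV
edge-list export, round-trip tested). **Reciprocal modules** are the
connected components (≥ 2 members) of the graph whose edge a–b requires
b in a's top-N list *and* a in b's — mutual top-N membership, read
strictly. Ranking uses positive r only by default (the co-functional
interpretation); a flag admits |r|. Components, rather than a community
detection pass, keep the construction transparent; note that with top-N
lists every gene has candidates, so diffuse noise components can appear
alongside planted modules — the planted module is protected because its
members saturate each other's lists. A module of m genes can only fill
its members' lists when m − 1 ≥ top_n; the recovery tests use a 4-gene
module at top_n = 3 for that reason.

## Synthetic-data generators

`simulate_dependency` draws each latent factor as a standard-normal
vector over cell lines and sets gene g's profile to
Σ_f λ_{g,f}·factor_f + N(0, σ²), with uniform missingness optionally
applied. Two genes sharing one factor with common loading λ have expected
correlation λ²/(λ² + σ²), and a gene's marginal variance is Σλ² + σ² —
closed forms the tests verify. Defaults (λ = 1, σ in 0.4–1.0 per fixture,
200–500 cell lines) were chosen so that within-factor structure is strong
but not degenerate and correlations stabilize in seconds of simulation.
The generator emulates the *block-correlation structure* co-essentiality
analysis assumes — it does not mimic real dependency-score features such
as bimodal essential/non-essential distributions, lineage substructure,
or structured missingness, so passing recovery tests demonstrates the
machinery, not performance on real screens.

`simulate_expression` places an exact `round(zero_fraction × entries)`
count of zeros uniformly at random (log-normal elsewhere), so the
expression-mask report reads the planted fraction back exactly.
`simulate_corpus` draws per-publication gene sets of size 1 + Poisson
with Zipf-style gene popularity (weight ∝ rank^−1.2), reproducing the
long right tail of per-gene publication counts; a designated pair is
injected into additional publications until it attains the strict
maximum co-occurrence. `make_etc_fixture` plants the odd-one-out
structure used throughout the pathway tests: four 8-gene "complexes" on
factor F1, one on F2, plus a reference collection of 3 pathways on F2
(the planted unique associations), 6 on F1 and 5 on independent factors,
at 300 cell lines, λ ~ N(1, 0.2²), σ = 0.5.

## Numerical and design notes

- Ranked tables break ties deterministically: |r| descending, then
  partner symbol ascending.
- Correlations are clipped to [−1, 1] after the one-pass computation;
  pairs with < 3 complete observations or zero variance are skipped and
  counted, not silently dropped.
- PCA uses the full SVD solver for determinism; components with
  explained-variance ratio below 1e-12 are treated as numerically null.
- The recovery test suites run 100 seeds each at the fixture scales above
  (seconds per seed); the permutation-calibration check uses a 100-gene ×
  200-line matrix. These sizes are the package's reference conditions —
  large enough for stable tail estimates, small enough to iterate on.
- Known limitations: no lineage-aware correlation or within-lineage
  normalization; no gene-set enrichment semantics; no overlap correction
  in CCA (reported, not removed); the unique-association cutoff is a
  user-facing dial, not an inferential threshold.
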