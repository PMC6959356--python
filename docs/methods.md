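# Methods

## The model

Cell set enrichment analysis asks whether a predefined set of cells S
(typically all cells of one condition) is concentrated at one extreme of
a per-cell scalar signal. It transplants the gene set enrichment
running-sum statistic from genes to cells: the "gene list" becomes a
ranking of cells by signature score, and the "gene set" becomes the
condition's cell set. Because the ranking is computed per cell, the test
is independent of any clustering of the data and is sensitive to
disease-associated subpopulations that spread across clusters or live on
a continuum.

### Signature scores

Scores follow the centred-profile convention: each cell's normalized log
expression vector is z-scored across genes (population SD), and the score
is the mean z-value over the signature's positive genes minus its
negative genes, divided by the number of signature genes present in the
matrix. Consequences that the test suite verifies:

* scores are invariant to any per-cell affine transform of the input
  (library-size rescalings and global shifts cancel);
* the all-genes signature scores exactly zero;
* swapping positive and negative subsets negates every score.

Two normalization choices were genuinely open. We z-score with the
population (n) rather than sample (n−1) SD — only self-consistency
matters, and the population convention makes the all-genes identity
exact. We normalize by the number of signature genes *present in the
matrix* rather than the nominal signature size, so scores remain
comparable across datasets with different gene coverage; attrition is
logged so heavy gene loss is visible.

The fused scorer (`score_signatures`) computes per-cell moments over all
genes and sums only signature columns, using
Σ_{g∈G} z = (Σ_{g∈G} x − |G|·μ_cell)/σ_cell, so sparse matrices are never
densified.

### The enrichment score

With cells ranked by score (descending for the high tail; ties broken by
cell id so results are deterministic), hit and miss running sums are

    P_hit(i)  = Σ_{j∈S, rank(j)≤i} |r_j|^p / N_R,   N_R = Σ_{j∈S} |r_j|^p
    P_miss(i) = #{j∉S : rank(j)≤i} / (N − N_H)

and ES = max_i (P_hit − P_miss) ∈ [0, 1]. The maximum is one-sided; low-tail
enrichment is tested by re-ranking with `direction="low"` rather than by a
signed statistic. At p = 0 the statistic reduces to a one-sided two-sample
KS statistic, which an independent empirical-CDF oracle
(`ks_statistic_oracle`) verifies exhaustively for all partitions of up to
10 cells and on random 200-cell instances.

Numerical details: |r_j|^p uses the cell's own score even under ties;
p = 0 maps every weight to 1 (including r = 0); if p > 0 and all member
scores are zero the weights are degenerate and an error is raised. The
argmax is the *smallest* rank attaining the maximum — the most
conservative leading edge — with a 1e-12 tolerance so cumsum round-off
cannot split exact ties. Cells up to the argmax are the leading edge;
their intersection with S is the leading-edge subset.

### Null models

**Label permutation.** Condition labels are shuffled uniformly
(preserving N_H) `n_permutations` times (default 100) and
p = #{ES_perm ≥ ES_obs}/n. The raw-fraction convention allows p = 0 for
an observed ES beyond every shuffle; an optional add-one correction
gives p = (k+1)/(n+1) ≥ 1/(n+1). Permutations never
re-rank cells (the ranking does not depend on labels), so all shuffles
are evaluated vectorized against one fixed weight vector.

**Matched gene sets.** For each signature gene the 20 genes (configurable)
with the nearest mean expression — computed on the normalized log matrix
over *all* cells, not per condition — form a candidate pool; one candidate
is drawn per gene, without replacement across the set, mirroring the
positive/negative split. Sampling without replacement avoids multiset
"signatures", which are ill-defined for scoring; if pools collide until
empty an error suggests a larger universe or smaller pool. Screening uses
a single matched control per signature; the separate validation routine
(`geneset_null_pvalue`) compares the true ES against 1000 matched sets.
`match_sensitivity` quantifies why matching matters: on count-like data,
fully random control sets produce highly variable ES while tightly
matched sets are stable (pool size 1 is deterministic when nearest
neighbours are unique).

**Screening.** Benjamini–Hochberg correction is applied across signatures
separately within the true and the control p-value families; a signature
is retained when corrected true p < 0.05, corrected control p > 0.05, and
the leading edge is strictly smaller than 1000 cells.

A convention note: permutation p-values are sometimes described as "the
probability that the true ES exceeds the shuffled ES", which inverts the
scale (large values would then mean strong enrichment). We use the
standard convention — the fraction of null ES values at or above the
observed one — so small p-values mean strong enrichment and p = 0 marks
an ES beyond every shuffle.

## Synthetic validation data

Two generative schemes define the conditions under which detection power
is assessed. They emulate the situation the method targets — an outlier
subpopulation of case cells shifted along a continuous cell state — and
deliberately omit batch effects, doublets, multiple lineages and
cluster structure; passing them shows the statistic and its nulls behave
as designed, not that any particular real dataset contains such a signal.

**Scheme A (direct scores).** Control cells draw scores from N(5, 1);
each case cell independently draws from an outlier component
N(mean2, 1) with probability `outlier_frac`, else from the control
component. Bernoulli mixing is the default (a `fixed_outlier_count` flag
draws exactly round(frac·n) outliers instead); realized outlier cells
are recorded so power can be stratified by realized fraction. Note that
`outlier_frac` is a *within-case* proportion; with equal group sizes the
outlier share of the total population is half of it, and the validation
thresholds are reported on that total-population scale.

**Scheme B (counts).** Each cell's latent state z reuses the scheme-A
draw. Counts for gene g follow a negative binomial with log-mean
baseline_g + loading·(z − 5), loading 0.5 for a random 10% of genes
(the DE genes) and 0 otherwise; baselines are drawn from N(0.5, 1) on
the natural-log scale (median mean count ≈ 1.6, right-skewed, giving
libraries of a few hundred counts over 500 genes — a plausible
droplet-style depth); dispersion 10 adds moderate extra-Poisson noise.
The matrix is library-size normalized to the median library and
log1p-transformed. Each cell is scored on the DE-gene signature, and
case/control labels are transferred by rank-matching the trajectory
score to the scheme-A reference (the i-th ranked cell inherits the label
of the i-th ranked reference cell), so group sizes are preserved exactly.
The explicit negative-binomial gene model keeps every knob of the count
layer in `CountSimSpec` instead of delegating to an external single-cell
simulator; at loading 0.5 the latent state is recoverable (Spearman
≈ 0.97 between z and the DE score), so the count layer attenuates but
does not destroy the signal.

## Power evaluation

`power_grid` runs the full pipeline (simulate → score → rank → ES →
permutation p) over a separation × outlier-fraction grid. Replicate r of
cell (i, j) is seeded with SeedSequence([master, i, j, r]), so cells are
independent and individually reproducible. Defaults: 20 replicates,
100 permutations, alpha 0.05 on the raw permutation p (a single
signature is tested per replicate, so no multiplicity correction
applies). "Detected" at a grid value means rejection in more than half
of the replicates; `detection_threshold` returns the start of the
largest suffix of the scanned axis with majority detection everywhere
(+∞ if none), warning when empirical power is non-monotone below the
stable suffix.

Reference problem sizes — chosen as the package's standard validation
conditions and used by `scripts/acceptance.py` — are 1000 cells per group
for scheme A and 300 cells per group × 500 genes for scheme B, with
outlier shares of the total population scanned over
{1, 2, 3, 4, 5, 6, 8, 10, 12}% and separations over {0.5, 1, 1.5, 2, 3}
SD. `null_calibration` checks type-I error with 200 replicates of the
exact null (mean2 = mean1; additionally zero DE loading for scheme B),
comparing the p-value ECDF against uniform with an allowance of
1/n_permutations (discreteness) + 1.36/√replicates (95% KS band).

## Known limitations

* Heavy score ties make the ranking depend on the deterministic
  lexicographic tie-break; ES is then order-dependent only through that
  rule.
* The matched-geneset null matches means only, not variances or
  gene–gene correlation.
* The count scheme models library size and overdispersion but not
  zero-inflation beyond NB sampling, batch structure, or multiple latent
  lineages; thresholds measured under it transfer to other simulators
  only at grid resolution.
* The one-sided statistic tests one tail per run; testing both tails
  requires two runs and, if combined, a user-side multiplicity
  adjustment.
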