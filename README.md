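# csea — cell set enrichment analysis

`csea` tests whether the cells of one condition (say, disease vs. control)
concentrate at one extreme of a per-cell transcriptional signature score —
without any clustering step. It is aimed at single-cell analysts who
suspect that a disease effect lives in a *subset* of cells spread across
clusters (a gradient or a small outlier subpopulation) where per-cluster
composition tests and differential expression both lose power.

## The statistic

Each cell's normalized log expression profile is z-scored across genes,
and a signature score is the mean z-value over the signature's positive
genes minus its negative genes:

    r_j = ( Σ_{g∈P} z_jg − Σ_{g∈N} z_jg ) / (|P| + |N|)

Cells are ranked by r_j (descending for the high tail). For the cell set
S of interest (e.g. all disease cells, N_H of N cells), a weighted
running sum is computed along the ranking:

    P_hit(i)  = Σ_{j∈S, rank(j)≤i} |r_j|^p / N_R ,   N_R = Σ_{j∈S} |r_j|^p
    P_miss(i) = #{ j∉S : rank(j)≤i } / (N − N_H)

    ES = max_i ( P_hit(i) − P_miss(i) )              ∈ [0, 1]

With weight exponent p = 0 this is a one-sided two-sample
Kolmogorov–Smirnov statistic; with p = 1 (the default) set members are
weighted by score magnitude, damping low-magnitude cells. Cells up to the
maximizing rank form the **leading edge**; its intersection with S is the
core subset of cells driving the enrichment.

Significance comes from two complementary nulls:

* **label permutation** — condition labels are shuffled (100 times by
  default); p is the fraction of shuffled ES values ≥ the observed ES;
* **matched gene sets** — control signatures matched in size and per-gene
  mean expression (each gene replaced by one of its 20 nearest-mean
  neighbours) check that the enrichment is specific to the signature's
  genes.

A screened result must have BH-corrected permutation p < 0.05, a
non-significant matched control (corrected p > 0.05), and a leading edge
of fewer than 1000 cells.

## Worked example

`examples/worked_micro_example.py` runs the statistic on six cells with
scores (3, 2, 1, −1, −2, −3) and S = {A, B, F}:

```
ranking (high to low): A B C D E F
weight exponent 1.0: ES = 0.6250 at rank 2, leading-edge subset = ['A', 'B']
weight exponent 0.0: ES = 0.6667 at rank 2, leading-edge subset = ['A', 'B']
```

A and B carry hit weights 3/8 and 2/8, so the running sum peaks at
5/8 = 0.625 after rank 2; at p = 0 the same instance gives the one-sided
KS value 2/3. The other examples cover the full screening pipeline on
simulated count data (`score_and_screen.py`), a small power scan
(`power_and_threshold.py`) and null calibration
(`null_calibration_demo.py`).

## Library and command line

The primary interface is the Python API (`csea.score_signatures`,
`csea.permutation_pvalue`, `csea.matched_geneset`,
`csea.screen_signatures`, `csea.simulate_gaussian`,
`csea.simulate_counts`, `csea.power_grid`, ...). A thin CLI wraps it:

```sh
csea run --expr matrix.mtx --genes genes.tsv --cells cells.tsv \
         --labels labels.tsv --set-label MS --signatures sets.gmt \
         --n-perm 100 --seed 1 --out screen.tsv
csea score    --expr ... --signatures sets.gmt --out scores.tsv
csea simulate gaussian --n-per-group 1000 --mean2 7 --outlier-frac 0.10 --seed 1 --out sim
csea simulate counts   --n-per-group 300 --seed 1 --out sim
csea evaluate power --scheme gaussian --replicates 20 --seed 1 --out pw
csea evaluate null  --scheme counts --replicates 200 --seed 1 --out null.tsv
```

Inputs are Matrix Market triplets with gene/cell sidecar name files
(cellranger-style) or dense TSV/CSV, GMT gene sets (`X_UP`/`X_DN` line
pairs merge into one signed signature), and two-column cell→label tables.

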