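"""Full screening pipeline on simulated count data.

Generates a count matrix whose differentially expressed (DE) genes follow
a continuous latent cell state, scores every cell on the DE signature,
tests whether case cells are enriched at the high-score tail with the
label-permutation null, builds an expression-matched control gene set,
and applies the three-part screening filter.
"""

from csea import (
    CountSimSpec,
    CseaParams,
    GaussianMixtureSpec,
    MatchedGenesetSpec,
    ScoreVector,
    matched_geneset,
    permutation_pvalue,
    score_signatures,
    screen_signatures,
)

sim = CountSimSpec(
    n_per_group=200,
    n_genes=400,
    mixture=GaussianMixtureSpec(n_per_group=200, mean2=7.0, outlier_frac=0.2),
    rng_seed=11,
)
from csea import simulate_counts

data = simulate_counts(sim)
print(f"simulated {data.expr.n_cells} cells x {data.expr.n_genes} genes, "
      f"signature of {len(data.signature)} DE genes")

params = CseaParams(weight_exponent=1.0, n_permutations=100, rng_seed=1)
true_res = permutation_pvalue(data.trajectory, data.partition, params)
print(f"true signature: ES = {true_res.es:.3f}, permutation p = {true_res.p_value}, "
      f"leading edge {len(true_res.leading_edge)} cells "
      f"({len(true_res.leading_edge_subset)} of them case cells)")

control = matched_geneset(data.signature, data.expr, MatchedGenesetSpec(rng_seed=2))
ctrl_scores = ScoreVector(
    score_signatures(data.expr, [control]).iloc[:, 0], signature_name=control.name
)
ctrl_res = permutation_pvalue(ctrl_scores, data.partition, params)
print(f"matched control: ES = {ctrl_res.es:.3f}, permutation p = {ctrl_res.p_value}")

table = screen_signatures([(true_res, ctrl_res)])
print("\nscreening table:")
print(table.to_string(index=False))
print(
    "\nThe signature passes the screen when its BH-corrected p is < 0.05,\n"
    "the expression-matched control's corrected p is > 0.05, and the\n"
    "leading edge stays below 1000 cells - i.e. the enrichment is specific\n"
    "to the signature genes and driven by a bounded core of cells."
)
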