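"""The enrichment statistic on a six-cell toy instance.

Six cells are ranked by score; three of them (A, B, F) form the set of
interest S. The running sum climbs by each member's weighted score and
falls by 1/(N - N_H) at each non-member; its maximum is the enrichment
score (ES).
"""

import pandas as pd

from csea import CellPartition, ScoreVector, enrichment_score, rank_cells

scores = ScoreVector(
    pd.Series({"A": 3.0, "B": 2.0, "C": 1.0, "D": -1.0, "E": -2.0, "F": -3.0}),
    signature_name="toy",
)
partition = CellPartition(
    pd.Series({"A": "MS", "B": "MS", "C": "co", "D": "co", "E": "co", "F": "MS"}),
    set_of_interest="MS",
)

ranked = rank_cells(scores, direction="high")
print("ranking (high to low):", " ".join(ranked))

for p in (1.0, 0.0):
    res = enrichment_score(ranked, scores, partition, weight_exponent=p)
    print(
        f"weight exponent {p}: ES = {res.es:.4f} at rank {res.argmax_rank}, "
        f"leading-edge subset = {sorted(res.leading_edge_subset)}"
    )

print(
    "\nWith p = 1 the two top-ranked members A and B carry weights 3/8 and 2/8\n"
    "of the hit mass, so the running sum peaks at 5/8 = 0.625 after rank 2;\n"
    "with p = 0 the statistic is the one-sided KS value 2/3. The leading-edge\n"
    "subset {A, B} is the core of cells driving the enrichment."
)
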