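"""Rank genes by the total entropy difference ΔS and recover planted markers.

Simulates a 5-type dataset with 20 planted marker genes per type, normalizes
it, and ranks every gene by ΔS = n·ln(AM/GM) of its per-type mean expression.
A large ΔS means the gene's mean differs strongly across types.
"""

import numpy as np

from scibet import (
    SimSpec,
    entropy_delta,
    group_mean_expression,
    normalize_umi,
    select_features,
    simulate_counts,
)

raw, labels, markers = simulate_counts(SimSpec(seed=0))
norm = normalize_umi(raw)
table = entropy_delta(group_mean_expression(norm, labels))

top = select_features(table, k=100)
planted = {g for genes in markers.values() for g in genes}
hits = len(planted & set(top))

print(table.to_frame().head(10).to_string(index=False))
print(f"\nplanted markers recovered in the top 100 genes: {hits}/{len(planted)}")
print("ΔS is in nats; 0 means a gene's mean expression is identical across types.")
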