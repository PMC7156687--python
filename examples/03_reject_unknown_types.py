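"""Reject cells whose type is missing from the reference.

Trains on 5 of 6 simulated types and scores a query containing the sixth.
Each query cell gets a confidence score log C — the log-likelihood ratio of
the pooled reference versus a broad null background on the genes that best
separate the two.  Cells with C below an absolute threshold are left
"unassigned" instead of being forced onto a wrong type.
"""

import numpy as np

from scibet import (
    SimSpec,
    align_genes,
    apply_unassignment,
    confidence_score,
    entropy_delta,
    false_positive_rate,
    group_mean_expression,
    normalize_umi,
    predict,
    select_features,
    simulate_counts,
    train,
)

raw, labels, _ = simulate_counts(SimSpec(n_types=6, seed=2))
norm = normalize_umi(raw)

held_out = "type5"
ref_cells = [c for c, l in zip(labels.cell_names, labels.labels) if l != held_out]
out_cells = [c for c, l in zip(labels.cell_names, labels.labels) if l == held_out]
reference = norm.select_cells(ref_cells)
ref_labels = labels.subset(ref_cells)

features = select_features(entropy_delta(group_mean_expression(reference, ref_labels)), 500)
model = train(reference, ref_labels, features)

query = norm  # all cells, including the type the model has never seen
result = predict(model, align_genes(model.gene_names, query).matrix)
result.confidence_logC = confidence_score(reference, norm, query, k=500)
result = apply_unassignment(result, cutoff=0.05, mode="absolute")

negatives = np.array([c in set(out_cells) for c in query.cell_names])
logC = result.confidence_logC
print(f"mean log C, reference types: {logC[~negatives].mean():8.3f}")
print(f"mean log C, unseen type:     {logC[negatives].mean():8.3f}")
print(f"false positive rate at C < 0.05: {false_positive_rate(negatives, result.unassigned):.3f}")
print("A negative mean log C for the unseen type means the null background")
print("explains those cells better than any reference profile does.")
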