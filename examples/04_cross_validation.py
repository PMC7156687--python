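"""Repeated stratified hold-out benchmarking of the whole pipeline.

Each repeat draws a fresh 7:3 stratified split, selects markers and trains
on the training cells only, then scores the held-out cells.  Reported means
summarize accuracy and balanced accuracy (the unweighted mean of per-type
recalls, robust to class imbalance) over the repeats.
"""

from scibet import SimSpec, cross_validate, normalize_umi, simulate_counts

raw, labels, _ = simulate_counts(SimSpec(seed=3))
norm = normalize_umi(raw)

cv = cross_validate(norm, labels, k_features=500, n_repeats=10, seed=0)
print(cv.to_frame().to_string(index=False))
print(f"\nmean accuracy:          {cv.mean_accuracy:.3f}")
print(f"mean balanced accuracy: {cv.mean_balanced_accuracy:.3f}")
print("Values near 1 show the planted type structure is fully recoverable.")
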