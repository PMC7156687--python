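# Methods

## Model and assumptions

Gene expression in a homogeneous cell type is treated as a Poisson-Gamma
mixture (negative binomial): each cell's rate for a gene is Gamma-distributed
around a type-level mean and the observed count is Poisson around that rate.
Under this family the differential entropy of a gene's expression in type
*j* is ln X_ij plus a gene-specific constant, where X_ij is the type's mean
expression — which is why the whole pipeline operates on per-type means and
never needs per-cell variances.

**E-test.** A pooled null group is given the unweighted average of the
per-type means, X_i0 = (1/n) Σ_j X_ij (types count equally regardless of
size). The total entropy difference

    ΔS_i = Σ_j (S_i0 − S_ij) = Σ_j (ln X_i0 − ln X_ij) = n · ln(AM_i / GM_i)

is zero iff the means are equal across types and positive otherwise (AM–GM
inequality); the gene-specific entropy constant cancels identically and is
never materialized. Genes are ranked by descending ΔS; significance comes
from permuting cell labels and recomputing ΔS.

**Classifier.** Within a type, expression across the selected genes is
modeled as multinomial. The Laplace-smoothed estimator
p̂_ij = (1 + X_ij) / Σ_i (1 + X_ij) keeps every probability strictly inside
(0, 1), so no query cell ever scores −∞. A query cell with weights y is
assigned argmax_j Σ_i y_i ln p̂_ij. The multinomial coefficient is omitted:
it does not depend on j, and dropping it lets non-integer normalized values
serve as weights. Writing q = y/Σy shows the argmax equals
argmin_j KL(q ‖ p_j), which the tests verify on random instances.

**Rejection.** To catch cells whose type the reference lacks, the reference
and a broad null background are each pooled into a single pseudo-type; a
two-group E-test between the two pooled mean profiles picks the k genes
(default 500) that most distinguish reference from background, both
pseudo-types get Laplace fits on those genes, and each query cell receives
log C = Σ_i y_i (ln p̂_ir − ln p̂_in). All likelihood arithmetic stays in log
space; C itself can overflow for large cells and is only exponentiated for
display.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `size_factor` | 10,000 | per-cell library size after UMI scaling, before ln(1+·) |
| `pseudocount` | 1 | added to group means before logs (E-test) and probabilities (training) |
| `k` (features) | 500 | genes kept by ΔS rank for training, and for confidence scoring |
| `ratio` | 0.7 | stratified train fraction (7:3 hold-out) |
| `n_repeats` | 50 | hold-out repeats; per-repeat seed is `seed + repeat` for auditability |
| unassignment `cutoff` | — | quantile mode: fraction of the query batch rejected; absolute mode: threshold on C |

Natural logarithms are used everywhere — "log-normalization" means
ln(1 + x) — and ΔS is reported in nats. TPM normalization takes an optional
gene-length table and degrades to counts-per-million without one; callers
with pre-normalized data declare `state=NORMALIZED_LOG` and skip
normalization. Group means, and therefore both the E-test and the trained
probabilities, are computed on the log-normalized scale, the state the
pipeline is in when means are taken.

## Numerical and design choices

- **Pseudocounts.** ln X is undefined at 0, so group means get +1 before any
  log, mirroring the +1 Laplace smoothing of the trained probabilities. The
  pseudocount is exposed but 1 is the intended operating point.
- **Ties.** Gene ranking breaks ΔS ties by ascending gene name; argmax
  assignment breaks likelihood ties by model type order; batch-quantile
  unassignment breaks score ties by cell name. All deterministic across
  platforms; random tie-breaking was rejected for reproducibility.
- **Degenerate cells.** An all-zero query cell has identical (zero)
  log-likelihood under every type; it is assigned the first type and flagged
  `degenerate`.
- **Permutation p-values** use the add-one estimator
  (1 + #{ΔS* ≥ ΔS}) / (1 + n_perm), so p is never 0 and the smallest
  attainable value is 1/(1+n_perm).
- **Splits.** Stratified splits use round-half-up on `ratio·n_type` with a
  floor of one cell on each side; single-cell types are rejected by name.
- **Unassignment modes.** The batch-quantile mode rejects the ⌊cutoff·n⌋
  lowest-scoring cells of a query batch — natural when a fixed rejection
  budget is wanted. The absolute mode thresholds the likelihood ratio C
  itself (reject C < cutoff), which is the right tool when the query's
  composition of known and unknown types is itself the quantity under study:
  a quantile can reject at most that fraction of cells however many
  foreign cells are present, whereas the absolute threshold adapts. The
  false-positive-control tests use the absolute mode for exactly this
  reason.
- **Gene alignment.** Queries are reordered to the model's gene list; model
  genes absent from the query become zero rows (not dropped), so stored
  models remain comparable across queries. The missing fraction is reported
  and warned about above 20%. Name matching is exact and case-sensitive.
- **Serialization.** Models are TSV (genes × types of ln p̂) with a JSON
  header line, probabilities printed at 17 significant digits and re-parsed
  with correctly-rounded float conversion, giving bit-exact round-trips; a
  100-type × 1000-gene model is ~2 MB.
- **Metrics.** Accuracy and balanced accuracy delegate to scikit-learn;
  "unassigned" predictions count as wrong for cells that have a true
  reference type. Confusion matrices can be normalized per origin label in
  either orientation.

## What the simulator does and does not emulate

`simulate_counts` draws negative-binomial counts (Gamma-Poisson, mean μ,
variance μ + φμ²) with disjoint blocks of planted markers whose mean is
elevated `marker_fold`-fold in their type. Defaults — 5 types × 200 cells,
2000 genes, 20 markers/type at fold 8, base mean 0.5, dispersion 0.5 — give
sparse, overdispersed UMI-scale data with a strong but not degenerate type
signal, and the simulator returns the planted-marker ground truth for
recovery scoring. It deliberately omits library-size gradients, batch
effects, zero inflation beyond the NB's own zeros, and correlated gene
programs. Passing tests therefore demonstrate that the statistics and the
pipeline behave as derived on data satisfying the model's own assumptions;
they do not certify accuracy on any particular real tissue, where
normalization quality, batch structure and label noise dominate.

Test and acceptance runs use scaled problem sizes chosen to keep the suite
quick on one CPU: 20 simulation seeds for marker recovery, 10 hold-out
repeats for classification recovery, 50 seeds for the held-out-type
rejection study, and a 500-gene × 50,000-cell matrix for the throughput
exercise. These sizes are the package's own benchmark conditions; the
statistics they probe are size-stable.

## Known limitations

- The E-test assumes the negative-binomial entropy form; heavy zero
  inflation or strong batch structure breaks the "entropy from the mean"
  shortcut.
- The null-background score is only as broad as the background supplied;
  a query type missing from both reference and background can still score
  well if it resembles a reference type.
- Cross-species mapping keeps only one-to-one orthologs; paralog families
  are dropped rather than summed.
- Training uses group means only; within-type heterogeneity (doublets,
  gradients) is invisible to the model and should be handled upstream.
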