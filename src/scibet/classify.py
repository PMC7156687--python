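"""Cell scoring, maximum-likelihood assignment and null-background rejection.

A query cell with expression weights y is scored against each type model by
the multinomial log-likelihood L_j = Σ_i y_i ln p̂_ij (the multinomial
coefficient is constant across types and dropped, which also lets
non-integer normalized values act as weights).  The argmax over types is
equivalent to minimizing KL(q ‖ p_j) for the cell's normalized profile q.

Cells whose type is absent from the reference are caught with a likelihood
ratio against a broad null background: C = ∏_i p_ir^{y_i} / ∏_i p_in^{y_i},
computed and stored in log space.  Low-C cells are marked "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixState, ValidationError, align_genes
from .etest import GroupMeans, entropy_delta, select_features
from .model import SciBetModel, train_from_means

__all__ = [
    "PredictionResult",
    "UNASSIGNED_LABEL",
    "score_loglik",
    "predict",
    "build_null_model",
    "confidence_score",
    "apply_unassignment",
]

UNASSIGNED_LABEL = "unassigned"


@dataclass
class PredictionResult:
    """Per-cell log-likelihoods, assigned labels and optional confidence."""

    cell_names: list[str]
    type_names: list[str]
    loglik: np.ndarray  # cells × types
    assigned_type: list[str]
    degenerate: np.ndarray  # all-zero cells: ties over every type
    confidence_logC: np.ndarray | None = None
    unassigned: np.ndarray | None = None

    @property
    def labels(self) -> list[str]:
        """Final labels with unassignment applied (if any)."""
        if self.unassigned is None:
            return list(self.assigned_type)
        return [
            UNASSIGNED_LABEL if u else a
            for a, u in zip(self.assigned_type, self.unassigned)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell": self.cell_names,
                "assigned_type": self.labels,
                "log_likelihood_best": self.loglik.max(axis=1),
            }
        )
        if self.confidence_logC is not None:
            df["log_C"] = self.confidence_logC
        if self.unassigned is not None:
            df["unassigned"] = self.unassigned
        return df


def _check_aligned(model: SciBetModel, query: ExpressionMatrix) -> None:
    if list(query.gene_names) != list(model.gene_names):
        raise ValidationError(
            "query gene space differs from the model's; apply align_genes first"
        )
    if query.state is not MatrixState.NORMALIZED_LOG:
        raise ValidationError("query must be log-normalized before scoring")


def score_loglik(
    model: SciBetModel,
    query: ExpressionMatrix,
    query_normalization: str | None = None,
) -> np.ndarray:
    """Cells × types matrix of Σ_i y_ci ln p̂_ij over the model's genes.

    If the query's normalization mode is declared and differs from the one
    recorded in the model's metadata, a warning is raised (scores from
    mismatched normalizations are not comparable across datasets).
    """
    _check_aligned(model, query)
    trained_mode = model.metadata.get("normalization")
    if (
        query_normalization is not None
        and trained_mode not in (None, "unknown")
        and query_normalization != trained_mode
    ):
        warnings.warn(
            f"query normalization {query_normalization!r} differs from the "
            f"model's training normalization {trained_mode!r}",
            stacklevel=2,
        )
    if not np.isfinite(query.values).all():
        raise ValidationError("query contains non-finite values")
    return query.values.T @ model.log_prob.T


def predict(model: SciBetModel, query: ExpressionMatrix) -> PredictionResult:
    """Assign each cell the maximum-likelihood type.

    Ties (in particular all-zero cells, whose log-likelihood is 0 for every
    type) resolve to the first type in model order; such cells are flagged
    degenerate.
    """
    L = score_loglik(model, query)
    idx = np.argmax(L, axis=1)  # first max wins: deterministic tie-break
    assigned = [model.type_names[i] for i in idx]
    degenerate = np.asarray(query.values.sum(axis=0) == 0)
    return PredictionResult(
        list(query.cell_names), list(model.type_names), L, assigned, degenerate
    )


def _pooled_mean(m: ExpressionMatrix) -> np.ndarray:
    if m.n_cells == 0:
        raise ValidationError("empty expression matrix")
    return m.values.mean(axis=1)


def build_null_model(background: ExpressionMatrix, pseudocount: float = 1.0) -> SciBetModel:
    """Fit the background mixture as a single pseudo cell type."""
    if background.state is not MatrixState.NORMALIZED_LOG:
        raise ValidationError("background must be log-normalized")
    means = GroupMeans(["null"], list(background.gene_names), _pooled_mean(background)[None, :])
    return train_from_means(means, pseudocount, {"normalization": "unknown"})


def confidence_score(
    reference: ExpressionMatrix,
    null: ExpressionMatrix,
    query: ExpressionMatrix,
    k: int = 500,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-cell log C: log-likelihood ratio of reference vs null background.

    The reference and the null are each pooled into one pseudo cell type.  A
    two-group E-test between the two pooled mean profiles picks the ``k``
    genes that best separate reference from background; on those genes both
    pseudo-types get Laplace-smoothed multinomial fits, and
    ``log C_c = Σ_i y_ci (ln p̂_ir − ln p̂_in)``.
    """
    for m, what in ((reference, "reference"), (null, "null"), (query, "query")):
        if m.state is not MatrixState.NORMALIZED_LOG:
            raise ValidationError(f"{what} must be log-normalized")
    shared = [g for g in reference.gene_names if g in set(null.gene_names)]
    if not shared:
        raise ValidationError("reference and null share no genes")
    if k > len(shared):
        warnings.warn(
            f"k={k} exceeds the {len(shared)} shared genes; clamping", stacklevel=2
        )
        k = len(shared)
    ref_mean = align_genes(shared, reference).matrix.values.mean(axis=1)
    null_mean = align_genes(shared, null).matrix.values.mean(axis=1)
    means = GroupMeans(["reference", "null"], shared, np.vstack([ref_mean, null_mean]))
    genes = select_features(entropy_delta(means, pseudocount), k)
    sel = pd.Index(shared).get_indexer(genes)
    log_pr = np.log(ref_mean[sel] + pseudocount) - np.log((ref_mean[sel] + pseudocount).sum())
    log_pn = np.log(null_mean[sel] + pseudocount) - np.log((null_mean[sel] + pseudocount).sum())
    y = align_genes(genes, query).matrix.values  # genes × cells
    return y.T @ (log_pr - log_pn)


def apply_unassignment(
    result: PredictionResult,
    cutoff: float,
    mode: str = "quantile",
) -> PredictionResult:
    """Mark low-confidence cells unassigned.

    ``mode="quantile"``: the ``⌊cutoff·n⌋`` cells with the lowest log C in
    the batch are unassigned (ties broken by cell name).  ``mode="absolute"``:
    cells with ``C < cutoff`` (i.e. ``log C < ln cutoff``) are unassigned.
    """
    if result.confidence_logC is None:
        raise ValidationError("confidence scores must be computed before unassignment")
    logC = result.confidence_logC
    if mode == "quantile":
        if not 0.0 < cutoff < 1.0:
            raise ValidationError("quantile cutoff must lie in (0, 1)")
        n_drop = int(np.floor(cutoff * len(result.cell_names)))
        order = np.lexsort((np.asarray(result.cell_names), logC))
        unassigned = np.zeros(len(result.cell_names), dtype=bool)
        unassigned[order[:n_drop]] = True
    elif mode == "absolute":
        if cutoff <= 0.0:
            raise ValidationError("absolute cutoff must be a positive likelihood ratio")
        unassigned = logC < np.log(cutoff)
    else:
        raise ValidationError(f"unknown unassignment mode {mode!r}")
    return replace(result, unassigned=unassigned)
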