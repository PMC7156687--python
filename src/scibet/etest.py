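"""Entropy-based supervised marker selection (E-test).

For each gene the per-type mean expression is summarized by a differential
entropy that, under a Poisson-Gamma (negative-binomial) expression model, is
the log of the mean plus a gene-specific constant.  The total entropy
difference ΔS between a pooled null group and the observed groups reduces to

    ΔS_i = n · ln( AM_i / GM_i )

where AM/GM are the arithmetic and geometric means of the (pseudocounted)
per-type means of gene i over the n types.  By the AM–GM inequality ΔS ≥ 0,
with equality iff the means are identical across types — so large ΔS flags
type-specific genes.  Significance comes from a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, LabelVector, MatrixState, ValidationError

__all__ = [
    "GroupMeans",
    "EntropyTable",
    "group_mean_expression",
    "entropy_delta",
    "select_features",
    "permutation_pvalues",
]


@dataclass
class GroupMeans:
    """Per-type mean expression: the sufficient statistic for E-test and training.

    ``X[j, i]`` is the mean normalized expression of gene ``gene_names[i]``
    over cells of type ``type_names[j]``; shape ``(n_types, n_genes)``.
    """

    type_names: list[str]
    gene_names: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.type_names), len(self.gene_names)):
            raise ValidationError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.type_names)} types × {len(self.gene_names)} genes"
            )
        if (self.X < 0).any():
            raise ValidationError("group means contain negative entries")

    @property
    def n_types(self) -> int:
        return len(self.type_names)


@dataclass
class EntropyTable:
    """Per-gene ΔS (nats) with a deterministic ranking and optional p-values."""

    gene_names: list[str]
    delta_S: np.ndarray
    p_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_S = np.asarray(self.delta_S, dtype=np.float64)
        # descending ΔS, ties broken by ascending gene name for reproducibility
        self._order = np.lexsort((np.asarray(self.gene_names), -self.delta_S))

    @property
    def ranked_genes(self) -> list[str]:
        return [self.gene_names[i] for i in self._order]

    def to_frame(self) -> pd.DataFrame:
        rank = np.empty(len(self.gene_names), dtype=int)
        rank[self._order] = np.arange(1, len(self.gene_names) + 1)
        df = pd.DataFrame(
            {"gene": self.gene_names, "delta_S": self.delta_S, "rank": rank}
        )
        if self.p_value is not None:
            df["p_value"] = self.p_value
        return df.sort_values("rank").reset_index(drop=True)


def _group_indicator(labels: np.ndarray) -> tuple[list[str], np.ndarray]:
    """One-hot cells × types indicator for vectorized group means."""
    types = sorted(set(labels.tolist()))
    codes = pd.Categorical(labels, categories=types).codes
    ind = np.zeros((labels.size, len(types)))
    ind[np.arange(labels.size), codes] = 1.0
    return types, ind


def group_mean_expression(m: ExpressionMatrix, labels: LabelVector) -> GroupMeans:
    """Arithmetic mean of normalized expression per (gene, cell type)."""
    if m.state is not MatrixState.NORMALIZED_LOG:
        raise ValidationError("group means are computed on log-normalized expression")
    lab = labels.labels_for(m)
    types, ind = _group_indicator(lab)
    counts = ind.sum(axis=0)
    if (counts == 0).any():
        empty = [t for t, c in zip(types, counts) if c == 0]
        raise ValidationError(f"empty cell groups: {empty}")
    X = (m.values @ ind / counts).T  # types × genes
    return GroupMeans(types, list(m.gene_names), X)


def delta_entropy(X: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Vectorized ΔS over the rows=types axis of a (n_types, n_genes) array."""
    n = X.shape[0]
    if n < 2:
        raise ValidationError("ΔS needs at least 2 cell groups")
    M = X + pseudocount
    if (M <= 0).any():
        raise ValidationError(
            "pseudocounted group means must be positive (ln 0 undefined); "
            "use a positive pseudocount"
        )
    ln_am = np.log(M.mean(axis=0))
    ln_gm = np.log(M).mean(axis=0)
    return n * (ln_am - ln_gm)


def entropy_delta(g: GroupMeans, pseudocount: float = 1.0) -> EntropyTable:
    """Total entropy difference ΔS_i = n·(ln AM_i − ln GM_i) per gene.

    Group means are pseudocounted (default +1) before the logs, mirroring the
    Laplace smoothing used in model training; the pooled null mean weights
    every type equally regardless of its cell count.
    """
    return EntropyTable(list(g.gene_names), delta_entropy(g.X, pseudocount))


def select_features(t: EntropyTable, k: int = 500) -> list[str]:
    """Top-``k`` genes by descending ΔS (clamped to the gene count)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    return t.ranked_genes[: min(k, len(t.gene_names))]


def permutation_pvalues(
    m: ExpressionMatrix,
    labels: LabelVector,
    n_perm: int,
    seed: int,
    pseudocount: float = 1.0,
) -> EntropyTable:
    """Label-permutation p-values for ΔS.

    Cell labels are shuffled ``n_perm`` times; for each gene the p-value is
    the add-one estimator ``(1 + #{ΔS* ≥ ΔS_obs}) / (1 + n_perm)``, so the
    smallest attainable p is ``1/(1+n_perm)`` and p is never exactly zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    lab = labels.labels_for(m)
    types, ind = _group_indicator(lab)
    counts = ind.sum(axis=0)
    obs = delta_entropy((m.values @ ind / counts).T, pseudocount)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(m.n_genes, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(ind.shape[0])
        ds = delta_entropy((m.values @ ind[perm] / counts).T, pseudocount)
        exceed += ds >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return EntropyTable(list(m.gene_names), obs, p_value=p)
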