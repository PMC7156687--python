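"""Per-type multinomial expression models and their portable on-disk form.

Each cell type is modeled as a multinomial distribution over the selected
genes.  Its parameters are estimated in closed form from the type's mean
normalized expression with Laplace smoothing:

    p̂_ij = (1 + X_ij) / Σ_i (1 + X_ij)

The "+1" guarantees every gene a strictly positive probability, so held-out
cells expressing a gene unseen in training never get a −∞ log-likelihood.
Models are tiny (n_types × n_genes log-probabilities) and serialize to a
single TSV with a JSON metadata header line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, LabelVector, ValidationError
from .etest import GroupMeans, group_mean_expression

__all__ = [
    "SciBetModel",
    "ModelFormatError",
    "train",
    "train_from_means",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1
_HEADER_PREFIX = "# scibet-model "


class ModelFormatError(ValueError):
    """A model file is truncated, inconsistent or of an unknown version."""


@dataclass
class SciBetModel:
    """Trained classifier: selected genes, type names and ln p̂_ij.

    ``log_prob`` has shape ``(n_types, n_genes)``; each row exponentiates to
    a probability vector summing to 1.
    """

    type_names: list[str]
    gene_names: list[str]
    log_prob: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log_prob = np.asarray(self.log_prob, dtype=np.float64)
        if self.log_prob.shape != (len(self.type_names), len(self.gene_names)):
            raise ValidationError(
                f"log_prob shape {self.log_prob.shape} does not match "
                f"{len(self.type_names)} types × {len(self.gene_names)} genes"
            )
        if not np.isfinite(self.log_prob).all():
            raise ValidationError("log_prob contains non-finite entries")
        sums = np.exp(self.log_prob).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-10, rtol=0):
            raise ValidationError("per-type probabilities do not sum to 1")

    @property
    def n_types(self) -> int:
        return len(self.type_names)


def _laplace_log_prob(X: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    M = X + pseudocount
    return np.log(M) - np.log(M.sum(axis=1, keepdims=True))


def train_from_means(g: GroupMeans, pseudocount: float = 1.0, metadata: dict | None = None) -> SciBetModel:
    """Closed-form fit from group means (training is a pure function of them)."""
    meta = {
        "format_version": FORMAT_VERSION,
        "normalization": "unknown",
        "pseudocount": pseudocount,
        "n_features": len(g.gene_names),
        "type_names": list(g.type_names),
    }
    if metadata:
        meta.update(metadata)
    return SciBetModel(
        list(g.type_names), list(g.gene_names), _laplace_log_prob(g.X, pseudocount), meta
    )


def train(
    m: ExpressionMatrix,
    labels: LabelVector,
    features: Sequence[str],
    pseudocount: float = 1.0,
    normalization: str = "umi",
) -> SciBetModel:
    """Fit one multinomial per cell type on the selected feature genes.

    Restricts the matrix to ``features`` (order preserved), averages each
    type's cells, and applies the Laplace estimator.  At least two cell types
    are required — a single type makes classification degenerate.
    """
    sub = m.select_genes(list(features))
    means = group_mean_expression(sub, labels)
    if means.n_types < 2:
        raise ValidationError("training needs at least 2 cell types")
    return train_from_means(
        means, pseudocount, {"normalization": normalization, "n_features": len(features)}
    )


def save_model(model: SciBetModel, path: str | Path) -> None:
    """Write a model as TSV (rows=genes, columns=types) with a JSON header line.

    Log-probabilities are printed with 17 significant digits, enough for a
    bit-exact float64 round-trip through decimal text.
    """
    path = Path(path)
    meta = dict(model.metadata)
    meta["format_version"] = FORMAT_VERSION
    meta["type_names"] = list(model.type_names)
    meta["n_features"] = len(model.gene_names)
    df = pd.DataFrame(
        model.log_prob.T, index=model.gene_names, columns=model.type_names
    )
    with open(path, "w") as fh:
        fh.write(_HEADER_PREFIX + json.dumps(meta) + "\n")
        df.to_csv(fh, sep="\t", index_label="gene", float_format="%.17g")


def load_model(path: str | Path) -> SciBetModel:
    """Read a model written by :func:`save_model`, validating shape and version."""
    path = Path(path)
    text = path.read_text()
    first, _, rest = text.partition("\n")
    if not first.startswith(_HEADER_PREFIX):
        raise ModelFormatError(f"{path} is not a model file (missing header)")
    try:
        meta = json.loads(first[len(_HEADER_PREFIX):])
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupt model header in {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format_version {meta.get('format_version')!r}"
        )
    try:
        df = pd.read_csv(
            StringIO(rest), sep="\t", index_col=0, float_precision="round_trip"
        ).astype(np.float64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ModelFormatError(f"corrupt model table in {path}: {exc}") from exc
    if list(df.columns) != list(meta.get("type_names", [])):
        raise ModelFormatError(f"type names in {path} disagree with header")
    if len(df) != meta.get("n_features"):
        raise ModelFormatError(
            f"{path} holds {len(df)} genes but header declares {meta.get('n_features')}"
        )
    try:
        return SciBetModel(list(df.columns), list(df.index), df.to_numpy().T, meta)
    except ValidationError as exc:
        raise ModelFormatError(f"invalid model in {path}: {exc}") from exc
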