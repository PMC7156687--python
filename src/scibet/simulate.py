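"""Synthetic labeled scRNA-seq counts with planted type-specific markers.

Gene expression follows the Poisson-Gamma mixture the classifier assumes:
each cell's rate for a gene is Gamma-distributed around a type-level mean
μ_ij and the observed count is Poisson around that rate, i.e. counts are
negative-binomial with mean μ_ij and variance μ_ij + dispersion·μ_ij².
Every type gets a disjoint block of marker genes whose mean is elevated by
``marker_fold``; all other means equal ``base_mean``.  The planted marker
map is returned so selection and classification can be scored against a
known ground truth.

Defaults (5 types × 200 cells, 2000 genes, 20 markers/type at 8-fold,
base mean 0.5, dispersion 0.5) give sparse, overdispersed UMI-scale counts
with a clear but not trivial type signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, LabelVector, MatrixState, ValidationError

__all__ = ["SimSpec", "simulate_counts", "simulate_speed_matrix"]


@dataclass
class SimSpec:
    """Parameters of the Poisson-Gamma simulator; see the module docstring."""

    n_types: int = 5
    n_genes: int = 2000
    cells_per_type: int | list[int] = 200
    n_markers_per_type: int = 20
    marker_fold: float = 8.0
    base_mean: float = 0.5
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.n_genes < 1:
            raise ValidationError("n_types and n_genes must be positive")
        cpt = self.cells_per_type
        self._cells = [cpt] * self.n_types if isinstance(cpt, int) else list(cpt)
        if len(self._cells) != self.n_types or any(c < 1 for c in self._cells):
            raise ValidationError("cells_per_type must be positive, one per type")
        if self.n_markers_per_type < 0:
            raise ValidationError("n_markers_per_type must be >= 0")
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValidationError("more planted markers than genes")
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("base_mean and dispersion must be positive")

    @property
    def cell_counts(self) -> list[int]:
        return list(self._cells)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + dispersion·mu²."""
    shape = 1.0 / dispersion
    rates = rng.gamma(shape, mu * dispersion)
    return rng.poisson(rates)


def simulate_counts(spec: SimSpec) -> tuple[ExpressionMatrix, LabelVector, dict[str, list[str]]]:
    """Draw a labeled raw-count matrix plus the true marker assignment."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    types = [f"type{j}" for j in range(spec.n_types)]
    marker_map: dict[str, list[str]] = {}
    mu_by_type = np.full((spec.n_types, spec.n_genes), spec.base_mean)
    for j, t in enumerate(types):
        lo = j * spec.n_markers_per_type
        hi = lo + spec.n_markers_per_type
        marker_map[t] = genes[lo:hi]
        mu_by_type[j, lo:hi] *= spec.marker_fold

    cell_names: list[str] = []
    blocks: list[np.ndarray] = []
    for j, (t, n_cells) in enumerate(zip(types, spec.cell_counts)):
        mu = np.broadcast_to(mu_by_type[j][:, None], (spec.n_genes, n_cells))
        blocks.append(_nb_counts(rng, mu, spec.dispersion))
        cell_names.extend(f"{t}.c{c:04d}" for c in range(n_cells))
    values = np.concatenate(blocks, axis=1).astype(np.float64)
    labels = LabelVector(
        cell_names,
        [t for t, n in zip(types, spec.cell_counts) for _ in range(n)],
    )
    matrix = ExpressionMatrix(genes, cell_names, values, MatrixState.RAW_COUNTS)
    return matrix, labels, marker_map


def simulate_speed_matrix(
    n_genes: int = 500, n_cells: int = 1000, seed: int = 0
) -> ExpressionMatrix:
    """Unlabeled count matrix at throughput-benchmark shapes.

    Values are plain negative-binomial draws with no type structure — any
    non-degenerate counts exercise the scoring path equally.
    """
    rng = np.random.default_rng(seed)
    mu = np.full((n_genes, n_cells), 1.0)
    values = _nb_counts(rng, mu, 0.5).astype(np.float64)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cells = [f"cell{c:06d}" for c in range(n_cells)]
    return ExpressionMatrix(genes, cells, values, MatrixState.RAW_COUNTS)
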