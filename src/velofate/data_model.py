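"""Core typed containers shared by every pipeline stage.

The pipeline operates on a cell-by-gene expression matrix ``X`` (normalized,
log-scaled or imputed values) paired with a velocity matrix ``V`` of identical
shape holding per-cell, per-gene time derivatives of expression. Cells and
genes are identified positionally; the id lists are metadata carried along for
I/O and reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, name in enumerate(ids):
        if name in seen:
            raise ValidationError(
                f"duplicate {what} id {name!r} at positions {seen[name]} and {i}"
            )
        seen[name] = i


@dataclass
class ExpressionMatrix:
    """N x G matrix of normalized (log-scaled or imputed) expression values."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        n, g = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 cells, got {n}")
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            i, j = bad[0]
            raise ValidationError(
                f"non-finite expression value at cell {self.cell_ids[i]!r} "
                f"(row {i}), gene {self.gene_ids[j]!r} (col {j}); "
                f"{len(bad)} offending entries total"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class VelocityField:
    """N x G matrix of expression time derivatives paired with an
    :class:`ExpressionMatrix`.

    ``missing_mask`` flags genes for which no velocity estimate exists (for
    instance genes with almost no unspliced counts); such genes are excluded
    from every per-cell correlation computation rather than imputed.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("velocity values must be a 2-D array")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValidationError("velocity id lists do not match matrix shape")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(g, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (g,):
                raise ValidationError("missing_mask must have one flag per gene")
        present = self.values[:, ~self.missing_mask]
        if not np.isfinite(present).all():
            cols = np.flatnonzero(~self.missing_mask)
            bad = np.argwhere(~np.isfinite(present))
            i, j = bad[0]
            raise ValidationError(
                f"non-finite velocity at cell {self.cell_ids[i]!r} (row {i}), "
                f"gene {self.gene_ids[cols[j]]!r} (col {cols[j]}); "
                f"{len(bad)} offending entries total"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class PseudotimeVector:
    """Per-cell pseudotemporal ordering, non-negative, arbitrary units."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        if not np.isfinite(self.tau).all():
            raise ValidationError("pseudotime contains non-finite values")
        if (self.tau < 0).any():
            raise ValidationError("pseudotime must be non-negative")
        if np.ptp(self.tau) == 0:
            raise ValidationError("pseudotime is constant across cells")


@dataclass
class ClusterLabels:
    """Per-cell categorical labels (used for macrostate annotation and for
    restricting driver-gene correlations to a region of the manifold)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")

    def indices_of(self, names) -> np.ndarray:
        names = set(np.atleast_1d(names).tolist())
        return np.flatnonzero(np.isin(self.labels, list(names)))


def validate_paired_inputs(
    expr: ExpressionMatrix, vel: VelocityField
) -> tuple[ExpressionMatrix, VelocityField]:
    """Validate that an expression matrix and a velocity field are a pair.

    Returns the pair unchanged iff shapes match and the id orders are
    identical; values were already checked finite at construction.
    """
    if expr.values.shape != vel.values.shape:
        raise ValidationError(
            f"shape mismatch: expression {expr.values.shape} vs "
            f"velocity {vel.values.shape}"
        )
    if expr.cell_ids != vel.cell_ids:
        bad = [
            i for i, (a, b) in enumerate(zip(expr.cell_ids, vel.cell_ids))
            if a != b
        ]
        raise ValidationError(f"cell id order mismatch at positions {bad[:10]}")
    if expr.gene_ids != vel.gene_ids:
        bad = [
            j for j, (a, b) in enumerate(zip(expr.gene_ids, vel.gene_ids))
            if a != b
        ]
        raise ValidationError(f"gene id order mismatch at positions {bad[:10]}")
    return expr, vel
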