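"""File formats: dense TSV/CSV matrices, Matrix Market sparse matrices with
sidecar id files, per-cell vectors and labels, and run configuration.

Conventions: delimited matrices carry gene ids in the header row and cell
ids in the first column; MTX files are 1-based on disk (Matrix Market
standard) and 0-based in memory, with ``<stem>.rows.txt`` and
``<stem>.cols.txt`` sidecars holding the ids.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from .data_model import (
    ClusterLabels,
    ExpressionMatrix,
    PseudotimeVector,
    ValidationError,
    VelocityField,
)
from .kernels import TransitionMatrix


@dataclass
class RunConfig:
    """All pipeline defaults in one place."""

    k_neighbors: int = 30
    n_pcs: int = 30
    lambda_weight: float = 0.2
    mode: str = "stochastic"
    sigma: float | None = None
    n_samples: int = 1000
    n_macrostates: int | None = None      # None => eigengap heuristic
    max_macrostates: int = 10
    si_threshold: float = 0.96
    n_initial: int = 1
    f_cells: int = 30
    weight_clip: float = 0.01
    n_test_points: int = 200
    backward: bool = False
    density_normalize: bool = False
    similarity: str = "fuzzy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.n_pcs < 1:
            raise ValidationError("n_pcs must be >= 1")
        if not 0 <= self.lambda_weight <= 1:
            raise ValidationError("lambda_weight must lie in [0, 1]")
        if self.mode not in ("deterministic", "stochastic", "sampling"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 < self.si_threshold <= 1:
            raise ValidationError("si_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# matrices


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_matrix(
    path: str | Path, fmt: str | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix with ids; returns (values, row_ids, col_ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "mtx":
        values = np.asarray(mmread(path).todense(), dtype=float)
        rows_file = path.with_suffix(".rows.txt")
        cols_file = path.with_suffix(".cols.txt")
        row_ids = (
            rows_file.read_text().split()
            if rows_file.exists()
            else [f"row_{i}" for i in range(values.shape[0])]
        )
        col_ids = (
            cols_file.read_text().split()
            if cols_file.exists()
            else [f"col_{j}" for j in range(values.shape[1])]
        )
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    if len(set(row_ids)) != len(row_ids):
        dupes = pd.Series(row_ids)
        raise ValidationError(
            f"duplicate row ids: {dupes[dupes.duplicated()].unique()[:5].tolist()}"
        )
    if len(set(col_ids)) != len(col_ids):
        dupes = pd.Series(col_ids)
        raise ValidationError(
            f"duplicate column ids: {dupes[dupes.duplicated()].unique()[:5].tolist()}"
        )
    return values, row_ids, col_ids


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
    fmt: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _detect_format(path, fmt)
    if fmt == "mtx":
        mmwrite(path, sp.coo_matrix(values))
        path.with_suffix(".rows.txt").write_text("\n".join(row_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(col_ids) + "\n")
    else:
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(
            path, sep=sep, float_format="%.17g"
        )


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    values, rows, cols = read_matrix(path, fmt)
    return ExpressionMatrix(values=values, cell_ids=rows, gene_ids=cols)


def read_velocity(path: str | Path, fmt: str | None = None) -> VelocityField:
    values, rows, cols = read_matrix(path, fmt)
    missing = np.isnan(values).all(axis=0)
    if missing.any():
        values = values.copy()
        values[:, missing] = 0.0
    return VelocityField(
        values=values, cell_ids=rows, gene_ids=cols, missing_mask=missing
    )


def read_vector(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """One value per cell, TSV with cell id in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=None)
    return df.iloc[:, 0].to_numpy(), [str(i) for i in df.index]


def write_vector(path: str | Path, values, ids: list[str]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.Series(np.asarray(values), index=ids).to_csv(
        path, sep="\t", header=False
    )


def read_pseudotime(path: str | Path) -> PseudotimeVector:
    values, _ = read_vector(path)
    return PseudotimeVector(tau=values.astype(float))


def read_labels(path: str | Path) -> ClusterLabels:
    values, _ = read_vector(path)
    return ClusterLabels(labels=values)


# ---------------------------------------------------------------------------
# transition matrices with sidecar metadata


def write_transition_matrix(path: str | Path, tm: TransitionMatrix) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(path, tm.probs.tocoo())
    meta = {
        "backward": tm.backward,
        "recipe": tm.provenance,
        "params": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in tm.params.items()
        },
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_transition_matrix(path: str | Path) -> TransitionMatrix:
    path = Path(path)
    probs = sp.csr_matrix(mmread(path))
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TransitionMatrix(
        probs=probs,
        backward=bool(meta.get("backward", False)),
        provenance=meta.get("recipe", ""),
        params=meta.get("params", {}),
    )
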