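"""Symmetrized KNN graph over cells in PCA space.

The graph constrains all transitions to the phenotypic manifold: a cell may
only step to one of its nearest neighbors in expression space. The similarity
adjacency built on the graph feeds both the connectivity kernel and the
density-normalization option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .data_model import ExpressionMatrix, ValidationError

DEFAULT_K = 30
DEFAULT_L = 30


@dataclass
class PCRepresentation:
    """Principal-component coordinates of cells with explained variances."""

    coords: np.ndarray            # N x L
    explained_variance: np.ndarray  # length L, non-increasing


@dataclass
class NeighborGraph:
    """Union-symmetrized KNN graph.

    ``distances`` holds Euclidean distances on graph edges, ``adjacency``
    similarity weights in (0, 1]; both are symmetric sparse matrices with
    identical sparsity pattern and no self loops.
    """

    distances: sp.csr_matrix
    adjacency: sp.csr_matrix | None
    K: int

    @property
    def n_cells(self) -> int:
        return self.distances.shape[0]

    def neighbor_indices(self, i: int) -> np.ndarray:
        return self.distances.indices[
            self.distances.indptr[i]: self.distances.indptr[i + 1]
        ]

    def connectivity_report(self) -> dict:
        n_comp, labels = connected_components(self.distances, directed=False)
        sizes = np.bincount(labels)
        return {
            "n_components": int(n_comp),
            "component_labels": labels,
            "component_sizes": sizes.tolist(),
        }


def project_pca(
    expr: ExpressionMatrix, L: int = DEFAULT_L, scale: bool = False
) -> PCRepresentation:
    """Mean-centered PCA projection onto the first ``L`` components.

    Components are computed by exact SVD and are deterministic up to sign;
    signs are fixed so the largest-magnitude loading of each component is
    positive. ``scale=True`` additionally divides each gene by its standard
    deviation before projection (constant genes are left untouched).
    """
    X = np.asarray(expr.values, dtype=float)
    n, g = X.shape
    if L < 1:
        raise ValidationError("L must be >= 1")
    if L > min(n, g):
        raise ValidationError(f"L={L} exceeds min(N, G)={min(n, g)}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    # exact thin SVD; randomized variants are unnecessary at desk scale
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix sign: largest-|loading| entry of each component made positive
    for k in range(L):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    coords = U[:, :L] * s[:L]
    explained = (s[:L] ** 2) / max(n - 1, 1)
    return PCRepresentation(coords=coords, explained_variance=explained)


def build_knn(pc: PCRepresentation, K: int = DEFAULT_K) -> NeighborGraph:
    """Euclidean KNN in PC space, symmetrized by union.

    Cells i and j are neighbors if either is among the other's K nearest;
    every cell therefore ends up with at least K neighbors. Distance ties
    (including exact duplicates) are broken by ascending cell index, which is
    the order scikit-learn's exhaustive search returns them in.
    """
    X = pc.coords
    n = X.shape[0]
    if not 1 <= K < n:
        raise ValidationError(f"need 1 <= K < N, got K={K}, N={n}")
    nn = NearestNeighbors(n_neighbors=K + 1, algorithm="brute").fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self (duplicate points can push self off the first column)
    rows, cols, vals = [], [], []
    for i in range(n):
        mask = idx[i] != i
        keep = np.flatnonzero(mask)[:K]
        rows.extend([i] * len(keep))
        cols.extend(idx[i, keep])
        vals.extend(dist[i, keep])
    # duplicate points produce distance-0 edges; floor them at a tiny value
    # so sparse operations cannot prune the edge
    vals = np.maximum(vals, 1e-300)
    D = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # union symmetrization: keep an edge if present in either direction
    D_sym = D.maximum(D.T)
    D_sym.sort_indices()
    return NeighborGraph(distances=D_sym, adjacency=None, K=K)


def _fuzzy_similarities(D: sp.csr_matrix) -> sp.csr_matrix:
    """Local-scale exponential kernel with smooth-k normalization, symmetrized
    by the probabilistic t-conorm a + b - ab.

    Per cell, distances are shifted by the nearest-neighbor distance rho_i and
    scaled by a bandwidth sigma_i chosen by bisection so that the kernel mass
    sums to log2(k_i + 1) — a smooth analogue of "k neighbors at full weight".
    """
    n = D.shape[0]
    rows, cols, vals = [], [], []
    for i in range(n):
        sl = slice(D.indptr[i], D.indptr[i + 1])
        nbrs = D.indices[sl]
        d = D.data[sl].copy()
        if len(nbrs) == 0:
            raise ValidationError(f"cell {i} has an empty neighborhood")
        rho = d.min()
        target = np.log2(len(nbrs) + 1.0)
        shifted = np.maximum(d - rho, 0.0)
        if shifted.max() == 0:
            sim = np.ones_like(d)
        else:
            lo, hi = 1e-12, shifted.max() * 64
            for _ in range(64):
                mid = 0.5 * (lo + hi)
                mass = np.exp(-shifted / mid).sum()
                if mass > target:
                    hi = mid
                else:
                    lo = mid
            sim = np.exp(-shifted / (0.5 * (lo + hi)))
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs)
        vals.extend(sim)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Wt = W.T.tocsr()
    A = W + Wt - W.multiply(Wt)
    A.sort_indices()
    return A.tocsr()


def _gaussian_similarities(D: sp.csr_matrix) -> sp.csr_matrix:
    """Adaptive-bandwidth Gaussian kernel, symmetrized by the mean.

    Each cell's bandwidth is its median neighbor distance, so the kernel
    width scales with local sampling density.
    """
    n = D.shape[0]
    bw = np.empty(n)
    for i in range(n):
        d = D.data[D.indptr[i]: D.indptr[i + 1]]
        if len(d) == 0:
            raise ValidationError(f"cell {i} has an empty neighborhood")
        bw[i] = max(np.median(d), 1e-12)
    rows, cols = D.nonzero()
    d = np.asarray(D[rows, cols]).ravel()
    sig2 = bw[rows] * bw[cols]  # geometric pairing of the two local scales
    vals = np.exp(-(d ** 2) / (2.0 * sig2))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = (W + W.T) * 0.5
    A.sort_indices()
    return A.tocsr()


def compute_similarities(
    graph: NeighborGraph, method: str = "fuzzy"
) -> NeighborGraph:
    """Fill the similarity adjacency of a KNN graph.

    ``fuzzy`` (default) uses per-cell local scaling with smooth-k
    normalization; ``gaussian`` an adaptive-bandwidth Gaussian kernel. Both
    give symmetric similarities in (0, 1] that decrease with distance within
    each neighborhood.
    """
    if method == "fuzzy":
        A = _fuzzy_similarities(graph.distances)
    elif method == "gaussian":
        A = _gaussian_similarities(graph.distances)
    else:
        raise ValidationError(f"unknown similarity method {method!r}")
    return NeighborGraph(distances=graph.distances, adjacency=A, K=graph.K)


def build_graph(
    expr: ExpressionMatrix,
    K: int = DEFAULT_K,
    L: int = DEFAULT_L,
    method: str = "fuzzy",
    scale: bool = False,
) -> NeighborGraph:
    """Convenience wrapper: PCA -> KNN -> similarities."""
    L_eff = min(L, expr.n_cells, expr.n_genes)
    if L_eff < L:
        warnings.warn(f"L reduced from {L} to {L_eff} to fit the data")
    pc = project_pca(expr, L=L_eff, scale=scale)
    graph = build_knn(pc, K=min(K, expr.n_cells - 1))
    return compute_similarities(graph, method=method)
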