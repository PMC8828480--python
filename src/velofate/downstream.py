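"""Fate-probability-derived analyses.

Circular fate embeddings place terminal states evenly on the unit circle
and each cell at the fate-probability-weighted average of the vertices.
Priming (lineage commitment) is quantified by the entropy of a cell's fate
distribution and by its KL divergence from the dataset-mean fate. Putative
driver genes are ranked by Pearson correlation of expression with a fate
column. Gene expression trends along a lineage are fit by weighted
penalized cubic-spline regression against pseudotime, each cell weighted by
its fate probability, with a residual-s.d. uncertainty band; smoothed
trends can be clustered into regulatory programs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .data_model import ExpressionMatrix, ValidationError
from .fate import FateMatrix
from .neighbors import NeighborGraph

N_TEST_POINTS = 200
WEIGHT_CLIP = 0.01


@dataclass
class CircularEmbedding:
    angles: np.ndarray        # n_t lineage angles (radians)
    coords: np.ndarray        # N x 2
    ordering: list[int]       # permutation of lineage indices


@dataclass
class PrimingScores:
    entropy: np.ndarray
    kl: np.ndarray
    mean_fate: np.ndarray


@dataclass
class TrendFit:
    test_grid: np.ndarray
    fitted: np.ndarray
    band: np.ndarray
    coefficients: np.ndarray
    knots: np.ndarray
    penalty: float
    weights: np.ndarray
    residuals: np.ndarray
    fitted_cells: np.ndarray  # indices of the cells that entered the fit


@dataclass
class DriverRanking:
    genes: list[str]
    correlations: np.ndarray  # NaN for undefined (constant) genes
    order: np.ndarray         # gene indices sorted by descending correlation

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return [
            (self.genes[i], float(self.correlations[i]))
            for i in self.order[:k]
        ]


# ---------------------------------------------------------------------------
# circular embedding


def _cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _ordering_score(F: np.ndarray, perm: tuple[int, ...]) -> float:
    return sum(
        _cosine_similarity(F[:, perm[i]], F[:, perm[(i + 1) % len(perm)]])
        for i in range(len(perm))
    )


def circular_projection(
    F: FateMatrix | np.ndarray, max_exhaustive: int = 8
) -> CircularEmbedding:
    """Project fate probabilities onto the unit disk.

    Lineages are placed at evenly spaced angles; the circular order is
    chosen to maximize the summed cosine similarity of adjacent fate
    columns (exhaustive over circular permutations with the first lineage
    fixed and reflections deduplicated for n_t <= max_exhaustive, greedy
    insertion beyond). Each cell lands at the convex combination of the
    lineage vertices weighted by its fate row.
    """
    Fm = F.probs if isinstance(F, FateMatrix) else np.asarray(F, dtype=float)
    n_t = Fm.shape[1]
    if n_t < 2:
        raise ValidationError("circular projection needs at least 2 lineages")
    if n_t <= max_exhaustive:
        best, best_score = None, -np.inf
        for rest in itertools.permutations(range(1, n_t)):
            perm = (0,) + rest
            if n_t > 2 and perm[1] > perm[-1]:
                continue  # reflection duplicate
            score = _ordering_score(Fm, perm)
            if score > best_score:
                best, best_score = perm, score
        ordering = list(best)
    else:
        ordering = [0]
        remaining = list(range(1, n_t))
        while remaining:
            best_gain, best_pair = -np.inf, None
            for lineage in remaining:
                for pos in range(len(ordering) + 1):
                    cand = ordering[:pos] + [lineage] + ordering[pos:]
                    score = _ordering_score(Fm, tuple(cand))
                    if score > best_gain:
                        best_gain, best_pair = score, (lineage, pos)
            lineage, pos = best_pair
            ordering.insert(pos, lineage)
            remaining.remove(lineage)
    angles = np.empty(n_t)
    slots = 2 * np.pi * np.arange(n_t) / n_t
    for slot, lineage in enumerate(ordering):
        angles[lineage] = slots[slot]
    coords = np.column_stack([Fm @ np.cos(angles), Fm @ np.sin(angles)])
    return CircularEmbedding(angles=angles, coords=coords, ordering=ordering)


# ---------------------------------------------------------------------------
# priming scores


def priming_entropy(F: FateMatrix | np.ndarray) -> np.ndarray:
    """Per-cell entropy S_i = -sum_t F_it ln F_it (natural log)."""
    Fm = F.probs if isinstance(F, FateMatrix) else np.asarray(F, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Fm > 0, Fm * np.log(Fm), 0.0)
    return -terms.sum(axis=1)


def priming_kl(F: FateMatrix | np.ndarray) -> PrimingScores:
    """KL(F_i || F_bar) of each cell from the mean fate distribution."""
    Fm = F.probs if isinstance(F, FateMatrix) else np.asarray(F, dtype=float)
    mean_fate = Fm.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Fm > 0, Fm / mean_fate, 1.0)
        kl = np.where(Fm > 0, Fm * np.log(ratio), 0.0).sum(axis=1)
    return PrimingScores(
        entropy=priming_entropy(Fm), kl=kl, mean_fate=mean_fate
    )


# ---------------------------------------------------------------------------
# driver genes


def rank_drivers(
    expr: ExpressionMatrix,
    fate_column: np.ndarray,
    restrict_to: np.ndarray | None = None,
) -> DriverRanking:
    """Pearson correlation of every gene with a lineage's fate probability.

    ``restrict_to`` (cell indices) limits the computation to a region of the
    manifold, e.g. the cluster where the fate decision occurs. Genes with
    zero expression variance are flagged NaN and ranked last.
    """
    X = expr.values
    y = np.asarray(fate_column, dtype=float)
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to)
        if len(restrict_to) < 3:
            raise ValidationError("restriction must keep at least 3 cells")
        X = X[restrict_to]
        y = y[restrict_to]
    yc = y - y.mean()
    ny = np.linalg.norm(yc)
    Xc = X - X.mean(axis=0)
    nx = np.linalg.norm(Xc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (nx * ny)
    r[nx == 0] = np.nan
    if ny == 0:
        r[:] = np.nan
    order = np.argsort(np.where(np.isnan(r), -np.inf, r))[::-1]
    return DriverRanking(
        genes=list(expr.gene_ids), correlations=r, order=order
    )


# ---------------------------------------------------------------------------
# gene trends


def clip_weights(
    fate_column: np.ndarray, threshold: float = WEIGHT_CLIP
) -> np.ndarray:
    """Raise fate weights below the threshold to it (trend fitting only)."""
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    return np.maximum(np.asarray(fate_column, dtype=float), threshold)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    cw /= ws.sum()
    return np.interp(q, cw, xs)


def fit_trend(
    y: np.ndarray,
    tau: np.ndarray,
    weights: np.ndarray,
    n_test: int = N_TEST_POINTS,
    n_knots: int = 8,
    penalty_grid: np.ndarray | None = None,
    band_n_from_cells: bool = False,
) -> TrendFit:
    """Weighted penalized cubic-spline regression of expression on pseudotime.

    Only cells with weight > 0 enter the fit. The basis is a cubic B-spline
    with ``n_knots`` interior knots at weighted pseudotime quantiles; a ridge
    penalty on second differences of the coefficients is selected by
    generalized cross-validation over a fixed log-spaced grid (including 0,
    so exactly representable trends are recovered without bias). Predictions
    are made at ``n_test`` equally spaced points spanning the contributing
    cells' pseudotime range, with the residual-s.d. band

        sigma_p = sqrt(sum_j r_j^2 / (n - 2))
                  * sqrt(1 + 1/n + (tau_p - tau_bar)^2 / sum_j (tau_j - tau_bar)^2)

    where by default n is the number of test points; ``band_n_from_cells``
    switches to the conventional n = number of fitted cells.
    """
    y = np.asarray(y, dtype=float).ravel()
    tau = np.asarray(tau, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    keep = np.flatnonzero(w > 0)
    if len(keep) < 4:
        raise ValidationError("need at least 4 cells with positive weight")
    yk, tk, wk = y[keep], tau[keep], w[keep]
    if np.ptp(tk) == 0:
        raise ValidationError("all contributing cells share one pseudotime")
    lo, hi = tk.min(), tk.max()
    interior = _weighted_quantile(
        tk, wk, np.linspace(0, 1, n_knots + 2)[1:-1]
    )
    interior = interior[(interior > lo) & (interior < hi)]
    knots = np.concatenate([[lo] * 4, np.unique(interior), [hi] * 4])
    n_coef = len(knots) - 4
    design = BSpline.design_matrix(tk, knots, 3, extrapolate=False).toarray()
    D2 = np.diff(np.eye(n_coef), n=2, axis=0)
    BtWB = design.T @ (design * wk[:, None])
    BtWy = design.T @ (wk * yk)
    P2 = D2.T @ D2
    scale = np.trace(BtWB) / max(np.trace(P2), 1e-300)
    if penalty_grid is None:
        penalty_grid = np.concatenate([[0.0], np.logspace(-8, 3, 23)]) * scale
    best = None
    n_obs = len(yk)
    for alpha in penalty_grid:
        M = BtWB + alpha * P2
        try:
            coef = np.linalg.solve(M, BtWy)
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        fitted_obs = design @ coef
        rss = float(wk @ (yk - fitted_obs) ** 2)
        edf = float(np.trace(Minv @ BtWB))
        denom = max(n_obs - edf, 1e-8) ** 2
        gcv = n_obs * rss / denom
        if best is None or gcv < best[0]:
            best = (gcv, alpha, coef, fitted_obs)
    if best is None:
        raise ValidationError("penalized solve failed for every penalty")
    _, alpha, coef, fitted_obs = best
    grid = np.linspace(lo, hi, n_test)
    basis_grid = BSpline.design_matrix(
        np.clip(grid, lo, hi), knots, 3, extrapolate=False
    ).toarray()
    fitted = basis_grid @ coef
    residuals = yk - fitted_obs
    band = trend_band(
        residuals, tk, grid,
        n_override=len(keep) if band_n_from_cells else None,
    )
    return TrendFit(
        test_grid=grid, fitted=fitted, band=band, coefficients=coef,
        knots=knots, penalty=float(alpha), weights=wk, residuals=residuals,
        fitted_cells=keep,
    )


def trend_band(
    residuals: np.ndarray,
    tau: np.ndarray,
    test_grid: np.ndarray,
    n_override: int | None = None,
) -> np.ndarray:
    """Residual-s.d. prediction band along the test grid.

    n defaults to the number of test points; tau_bar and the spread term use
    the fitted cells' pseudotimes.
    """
    residuals = np.asarray(residuals, dtype=float)
    tau = np.asarray(tau, dtype=float)
    test_grid = np.asarray(test_grid, dtype=float)
    n = int(n_override) if n_override is not None else len(test_grid)
    if n < 3:
        raise ValidationError("need at least 3 test points for the band")
    s = np.sqrt((residuals ** 2).sum() / (n - 2))
    tbar = tau.mean()
    spread = ((tau - tbar) ** 2).sum()
    if spread == 0:
        raise ValidationError("pseudotime spread is zero")
    return s * np.sqrt(1.0 + 1.0 / n + (test_grid - tbar) ** 2 / spread)


# ---------------------------------------------------------------------------
# trend clustering


def cluster_trends(
    trends: np.ndarray,
    n_pcs: int = 50,
    K: int = 30,
    resolution: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Cluster smoothed gene trends into regulatory programs.

    Trends (genes x grid points) are z-transformed per gene, reduced by PCA,
    embedded in a KNN graph and partitioned by seeded modularity
    optimization (Leiden with a Louvain-style resolution parameter).
    Returns labels and, per cluster, the pointwise (mean, s.d.) trend.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    T = np.asarray(trends, dtype=float)
    if T.shape[0] < 2:
        raise ValidationError("need at least 2 genes to cluster")
    mean = T.mean(axis=1, keepdims=True)
    sd = T.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (T - mean) / sd
    n_comp = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    X = PCA(n_components=n_comp, random_state=seed).fit_transform(Z)
    k_eff = min(K, X.shape[0] - 1)
    A = kneighbors_graph(X, n_neighbors=k_eff, mode="connectivity")
    A = A.maximum(A.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(A.row, A.col) if i < j]
    g = ig.Graph(n=X.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    summaries = {
        int(c): (T[labels == c].mean(axis=0), T[labels == c].std(axis=0))
        for c in np.unique(labels)
    }
    return labels, summaries


# ---------------------------------------------------------------------------
# neighbor-average smoothing (plumbing stand-in for external imputation)


def smooth_expression(
    expr: ExpressionMatrix, graph: NeighborGraph, steps: int = 1
) -> ExpressionMatrix:
    """Average each cell's expression with its graph neighbors ``steps``
    times (a row-stochastic smoothing operator)."""
    if steps == 0:
        return expr
    n = expr.n_cells
    B = (graph.distances != 0).astype(float) + sp.identity(n, format="csr")
    B = sp.diags(1.0 / np.asarray(B.sum(axis=1)).ravel()) @ B
    X = expr.values
    for _ in range(steps):
        X = B @ X
    return ExpressionMatrix(
        values=np.asarray(X), cell_ids=expr.cell_ids, gene_ids=expr.gene_ids
    )
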