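"""Transition-matrix kernels: from graph + velocity field to a row-stochastic
Markov chain over cells.

For each cell i with velocity vector v_i, the state-change vectors
s_ik = x_k - x_i toward its graph neighbors are correlated (Pearson) with
v_i; a softmax with inverse temperature sigma turns the correlation vector
into a categorical transition distribution:

    p_ik = exp(sigma * c_ik) / sum_l exp(sigma * c_il).

sigma defaults to 1 / median(|c_ik|) over all graph edges. The velocity
kernel P_v is blended with the similarity kernel P_s (row-normalized
adjacency) as P = (1 - lambda) P_v + lambda P_s.

Velocity uncertainty is modeled per cell as a diagonal multivariate normal
whose moments are estimated from the neighborhood; the expected transition
row is approximated to second order,

    E[h_i(v)] ~= h_i(mu) + 1/2 sum_j H^(i)_jj Var[v_j],

with analytic Hessian diagonals of the softmax-of-correlation map (mode
"stochastic"), or estimated by Monte-Carlo draws (mode "sampling").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_model import ExpressionMatrix, ValidationError, VelocityField
from .neighbors import NeighborGraph

ROW_SUM_TOL = 1e-10


@dataclass
class KernelParams:
    """Parameters of the velocity kernel.

    sigma: softmax inverse temperature; ``None`` means the median heuristic.
    lambda_weight: weight of the similarity kernel in the final blend, in [0, 1].
    mode: "deterministic", "stochastic" (analytic second-order expectation)
        or "sampling" (Monte-Carlo expectation).
    n_samples: Monte-Carlo draws for mode="sampling".
    backward: reverse the chain by negating every velocity vector.
    density_normalize: apply the double kernel-density correction to the
        adjacency before row normalization (off by default).
    """

    sigma: float | None = None
    lambda_weight: float = 0.2
    mode: str = "deterministic"
    n_samples: int = 1000
    backward: bool = False
    density_normalize: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValidationError("lambda_weight must lie in [0, 1]")
        if self.mode not in ("deterministic", "stochastic", "sampling"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")


@dataclass
class VelocityMoments:
    """Neighborhood mean and per-gene variance of the velocity vectors."""

    mu: np.ndarray   # N x G
    var: np.ndarray  # N x G, >= 0


@dataclass
class TransitionMatrix:
    """Row-stochastic N x N sparse transition matrix over cells."""

    probs: sp.csr_matrix
    backward: bool = False
    provenance: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = sp.csr_matrix(self.probs)
        if self.probs.shape[0] != self.probs.shape[1]:
            raise ValidationError("transition matrix must be square")
        if (self.probs.data < 0).any():
            raise ValidationError("negative transition probabilities")
        rs = np.asarray(self.probs.sum(axis=1)).ravel()
        if np.abs(rs - 1.0).max() > ROW_SUM_TOL:
            i = int(np.argmax(np.abs(rs - 1.0)))
            raise ValidationError(
                f"row {i} sums to {rs[i]:.12f}, not 1 within {ROW_SUM_TOL}"
            )

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# correlations and softmax


def velocity_correlations(
    x_i: np.ndarray, v_i: np.ndarray, neighbor_expr: np.ndarray
) -> np.ndarray:
    """Pearson correlation of a velocity vector with each state-change vector.

    ``neighbor_expr`` is K x G; the state-change vectors are its rows minus
    ``x_i``. Both sides are mean-centered over the genes supplied (genes
    flagged missing in the velocity field must be excluded by the caller).
    Pairs with a constant state-change vector get correlation 0 (no
    directional information); a constant velocity vector yields NaN for the
    whole row, signalling an undefined direction.
    """
    S = neighbor_expr - x_i[None, :]
    if S.shape[1] < 2:
        return np.full(S.shape[0], np.nan)
    _, _, _, c, _ = _row_geometry(np.asarray(v_i, dtype=float), S)
    return c


def softmax_transform(c: np.ndarray, sigma: float) -> np.ndarray:
    """Numerically stable softmax of sigma * c."""
    if len(c) == 0:
        raise ValidationError("empty neighbor set")
    z = sigma * np.asarray(c, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def estimate_sigma(correlations: np.ndarray) -> float:
    """Median heuristic: sigma = 1 / median(|c|) over all defined edges.

    Falls back to sigma = 1 with a warning when the median is zero or no
    correlation is defined.
    """
    c = np.asarray(correlations, dtype=float)
    c = c[np.isfinite(c)]
    if len(c) == 0:
        warnings.warn("no defined correlations; falling back to sigma = 1")
        return 1.0
    med = float(np.median(np.abs(c)))
    if med == 0:
        warnings.warn("median |correlation| is 0; falling back to sigma = 1")
        return 1.0
    return 1.0 / med


# ---------------------------------------------------------------------------
# uncertainty propagation


def estimate_velocity_moments(
    vel: VelocityField, graph: NeighborGraph
) -> VelocityMoments:
    """Per-cell, per-gene mean and variance of velocities over the cell's
    neighborhood (the cell itself included, which stabilizes singleton
    neighborhoods). Variances are clipped at zero."""
    V = vel.values
    n = V.shape[0]
    B = (graph.distances != 0).astype(float) + sp.identity(n, format="csr")
    counts = np.asarray(B.sum(axis=1)).ravel()
    mu = (B @ V) / counts[:, None]
    second = (B @ (V * V)) / counts[:, None]
    var = np.maximum(second - mu * mu, 0.0)
    # zero out catastrophic-cancellation dust so constant neighborhoods
    # report exactly zero variance
    var[var < 1e-14 * np.maximum(second, 1e-300)] = 0.0
    return VelocityMoments(mu=mu, var=var)


def _row_geometry(v: np.ndarray, S: np.ndarray):
    """Centered/normalized quantities reused by the correlation map and its
    derivatives: r (centered v), its norm, U (unit centered state-change
    vectors; zero rows for degenerate pairs) and the correlations c."""
    g = S.shape[1]
    r = v - v.mean()
    nrm = np.linalg.norm(r)
    Sc = S - S.mean(axis=1, keepdims=True)
    s_nrm = np.linalg.norm(Sc, axis=1)
    U = np.zeros_like(Sc)
    ok = s_nrm > 0
    U[ok] = Sc[ok] / s_nrm[ok, None]
    if nrm > 0:
        c = np.clip((U @ r) / nrm, -1.0, 1.0)
    else:
        c = np.full(S.shape[0], np.nan)
    return r, nrm, U, c, g


def softmax_correlation_row(
    v: np.ndarray, S: np.ndarray, sigma: float
) -> np.ndarray:
    """The map h: velocity -> transition row (softmax of Pearson
    correlations against the rows of S). Exposed for oracle tests."""
    _, nrm, U, c, _ = _row_geometry(v, S)
    if nrm == 0:
        raise ValidationError("constant velocity vector: row undefined")
    return softmax_transform(c, sigma)


def hessian_diag_row(
    v: np.ndarray, S: np.ndarray, sigma: float
) -> np.ndarray:
    """Analytic diagonal Hessian entries H^(i)_jj of h_i(v) at v.

    Returns a K x G array: entry (i, j) is the second derivative of
    transition probability i with respect to velocity component j. Derived
    by chaining the softmax Hessian through the Jacobian and the diagonal
    second derivatives of the Pearson-correlation map.
    """
    r, nrm, U, c, g = _row_geometry(v, S)
    if nrm == 0:
        raise ValidationError("constant velocity vector: Hessian undefined")
    p = softmax_transform(c, sigma)
    # dc_k/dv_j and d^2c_k/dv_j^2 (centering projector folded in; centered
    # vectors make the projector act as the identity on the relevant terms)
    J = (U - c[:, None] * (r / nrm)[None, :]) / nrm
    cdd = (
        -2.0 * U * (r / nrm ** 3)[None, :]
        + 3.0 * c[:, None] * (r ** 2 / nrm ** 4)[None, :]
        - c[:, None] * ((1.0 - 1.0 / g) / nrm ** 2)
    )
    m = p @ J                 # sum_k p_k dc_k/dv_j
    q = p @ (J * J)
    t = p @ cdd
    H = (
        sigma ** 2 * p[:, None] * ((J - m[None, :]) ** 2 + (m ** 2 - q)[None, :])
        + sigma * p[:, None] * (cdd - t[None, :])
    )
    return H


def propagate_uncertainty(
    mu_v: np.ndarray, S: np.ndarray, sigma: float, var_v: np.ndarray
) -> np.ndarray:
    """Second-order expectation of a transition row under v ~ N(mu, diag var).

    E[h_i] ~= h_i(mu) + 1/2 sum_j H^(i)_jj Var[v_j]; the corrected row is
    clipped at zero and renormalized (the Taylor correction does not preserve
    the simplex exactly). Falls back to the deterministic row if the
    correction is non-finite.
    """
    p = softmax_correlation_row(mu_v, S, sigma)
    corr = 0.5 * (hessian_diag_row(mu_v, S, sigma) @ var_v)
    if not corr.any():
        return p  # zero variance: the Taylor term vanishes exactly
    if not np.isfinite(corr).all():
        warnings.warn("non-finite Hessian correction; using deterministic row")
        return p
    row = np.maximum(p + corr, 0.0)
    tot = row.sum()
    if tot <= 0:
        warnings.warn("degenerate corrected row; using deterministic row")
        return p
    return row / tot


def _sampled_row(
    mu_v: np.ndarray,
    S: np.ndarray,
    sigma: float,
    var_v: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    draws = rng.normal(
        mu_v[None, :], np.sqrt(var_v)[None, :], size=(n_samples, len(mu_v))
    )
    Sc = S - S.mean(axis=1, keepdims=True)
    s_nrm = np.linalg.norm(Sc, axis=1)
    U = np.zeros_like(Sc)
    ok = s_nrm > 0
    U[ok] = Sc[ok] / s_nrm[ok, None]
    R = draws - draws.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(R, axis=1)
    valid = nrm > 0
    if not valid.any():
        raise ValidationError("all sampled rows degenerate")
    C = np.clip((R[valid] @ U.T) / nrm[valid, None], -1.0, 1.0)
    Z = sigma * C
    Z -= Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    rows = E / E.sum(axis=1, keepdims=True)
    return rows.mean(axis=0)


# ---------------------------------------------------------------------------
# kernels


def velocity_kernel(
    expr: ExpressionMatrix,
    vel: VelocityField,
    graph: NeighborGraph,
    params: KernelParams | None = None,
) -> TransitionMatrix:
    """Velocity-directed transition matrix P_v on the KNN graph.

    sigma, unless given, is estimated once from the deterministic
    correlations (the median heuristic) and shared across modes. Rows whose
    correlations are undefined (constant velocity vector) fall back to a
    uniform distribution over the neighbors; a field with no directional
    information anywhere yields an all-uniform (similarity-free) chain with
    a warning.
    """
    params = params or KernelParams()
    X = expr.values
    V = vel.values.copy()
    used = ~vel.missing_mask
    if used.sum() < 2:
        raise ValidationError("fewer than 2 genes with velocity estimates")
    if params.backward:
        V = -V
    n = X.shape[0]

    neighbor_lists = [graph.neighbor_indices(i) for i in range(n)]
    det_corr = [
        velocity_correlations(
            X[i][used], V[i][used], X[neighbor_lists[i]][:, used]
        )
        for i in range(n)
    ]
    sigma = params.sigma
    if sigma is None:
        sigma = estimate_sigma(np.concatenate(det_corr))

    moments = None
    if params.mode in ("stochastic", "sampling"):
        vel_eff = vel if not params.backward else VelocityField(
            values=V, cell_ids=vel.cell_ids, gene_ids=vel.gene_ids,
            missing_mask=vel.missing_mask,
        )
        moments = estimate_velocity_moments(vel_eff, graph)

    rng = np.random.default_rng(params.seed)
    rows, cols, vals = [], [], []
    n_fallback = 0
    for i in range(n):
        nbrs = neighbor_lists[i]
        if len(nbrs) == 0:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            n_fallback += 1
            continue
        S = X[nbrs][:, used] - X[i][used][None, :]
        if params.mode == "deterministic":
            c = det_corr[i]
            if np.isnan(c).any():
                p = np.full(len(nbrs), 1.0 / len(nbrs))
                n_fallback += 1
            else:
                p = softmax_transform(c, sigma)
        elif not moments.var[i][used].any():
            # zero neighborhood variance: the expectation reduces to the
            # deterministic row exactly (and mu equals the cell's velocity)
            c = det_corr[i]
            if np.isnan(c).any():
                p = np.full(len(nbrs), 1.0 / len(nbrs))
                n_fallback += 1
            else:
                p = softmax_transform(c, sigma)
        else:
            mu_i = moments.mu[i][used]
            var_i = moments.var[i][used]
            if np.linalg.norm(mu_i - mu_i.mean()) == 0:
                p = np.full(len(nbrs), 1.0 / len(nbrs))
                n_fallback += 1
            elif params.mode == "stochastic":
                p = propagate_uncertainty(mu_i, S, sigma, var_i)
            else:
                p = _sampled_row(mu_i, S, sigma, var_i, params.n_samples, rng)
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs)
        vals.extend(p)
    if n_fallback:
        warnings.warn(
            f"{n_fallback} cells with undefined velocity direction fell back "
            "to a uniform row over their neighbors"
        )
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(
        probs=P,
        backward=params.backward,
        provenance=f"velocity[mode={params.mode}]",
        params={"sigma": sigma, "mode": params.mode},
    )


def density_normalize(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Double density normalization W' = Dg^-1 W Dg^-1 with Dg the diagonal
    of row sums; removes the influence of sampling density on the kernel."""
    W = sp.csr_matrix(adjacency)
    deg = np.asarray(W.sum(axis=1)).ravel()
    if (deg == 0).any():
        raise ValidationError(
            f"zero-degree nodes: {np.flatnonzero(deg == 0)[:10].tolist()}"
        )
    Dinv = sp.diags(1.0 / deg)
    return sp.csr_matrix(Dinv @ W @ Dinv)


def connectivity_kernel(
    graph: NeighborGraph, density_normalize_first: bool = False,
    backward: bool = False,
) -> TransitionMatrix:
    """Similarity kernel P_s: row-normalized adjacency.

    Isolated cells (zero similarity row) receive a self-loop with warning.
    """
    if graph.adjacency is None:
        raise ValidationError("similarity adjacency not computed")
    A = graph.adjacency
    if density_normalize_first:
        A = density_normalize(A)
    A = sp.lil_matrix(A)
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if len(isolated):
        warnings.warn(
            f"{len(isolated)} isolated cells received self-loops"
        )
        for i in isolated:
            A[i, i] = 1.0
        deg[isolated] = 1.0
    P = sp.csr_matrix(sp.diags(1.0 / deg) @ sp.csr_matrix(A))
    return TransitionMatrix(
        probs=P, backward=backward, provenance="connectivity"
    )


def combine_kernels(
    kernels: list[TransitionMatrix], weights: list[float]
) -> TransitionMatrix:
    """Convex combination of transition matrices (same shape and direction)."""
    if len(kernels) != len(weights) or not kernels:
        raise ValidationError("kernels and weights must align and be non-empty")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
        raise ValidationError("weights must be non-negative and sum to 1")
    shape = kernels[0].probs.shape
    backward = kernels[0].backward
    for k in kernels[1:]:
        if k.probs.shape != shape:
            raise ValidationError("kernel shapes differ")
        if k.backward != backward:
            raise ValidationError("cannot combine forward and backward kernels")
    P = sum(wi * k.probs for wi, k in zip(w, kernels))
    recipe = " + ".join(
        f"{wi:g}*{k.provenance or 'kernel'}" for wi, k in zip(w, kernels)
    )
    merged: dict = {}
    for k in kernels:
        merged.update(k.params)
    return TransitionMatrix(
        probs=sp.csr_matrix(P), backward=backward, provenance=recipe,
        params=merged,
    )


def transition_matrix(
    expr: ExpressionMatrix,
    vel: VelocityField,
    graph: NeighborGraph,
    params: KernelParams | None = None,
) -> TransitionMatrix:
    """Full recipe P = (1 - lambda) P_v + lambda P_s."""
    params = params or KernelParams()
    pv = velocity_kernel(expr, vel, graph, params)
    ps = connectivity_kernel(
        graph,
        density_normalize_first=params.density_normalize,
        backward=params.backward,
    )
    lam = params.lambda_weight
    if lam == 0:
        return pv
    if lam == 1:
        return ps
    return combine_kernels([pv, ps], [1.0 - lam, lam])
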