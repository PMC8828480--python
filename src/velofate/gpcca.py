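"""Coarse-graining of the cell-cell Markov chain into macrostates.

The chain's transition matrix P is generally non-reversible, so its
eigenvectors are complex; real invariant subspaces are instead spanned by
the leading columns of a sorted real Schur decomposition P = Q R Q^T, where
R is quasi-upper triangular (1x1 blocks for real eigenvalues, 2x2 blocks for
conjugate pairs). Keeping conjugate pairs together, the first n_s Schur
vectors Q~ span an invariant subspace; memberships are chi = Q~ A for an
invertible rotation A chosen to minimize

    f(A) = n_s - trace(D~^-1 chi^T D chi)

subject to chi >= 0 and chi 1 = 1 (partition of unity). The optimum makes
macrostates maximally crisp (non-overlapping, metastable). The chain is then
projected onto the macrostates via P_c = (chi^T D chi)^-1 (chi^T D P chi),
an invariant-subspace projection that commutes with propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import lapack, schur as _dense_schur
from scipy.optimize import minimize

from .data_model import ValidationError
from .kernels import TransitionMatrix


class SplitConjugatePairError(ValueError):
    """Requested subspace size would cut a 2x2 Schur block in half."""

    def __init__(self, n_s: int):
        self.n_s = n_s
        super().__init__(
            f"selecting {n_s} Schur vectors would split a complex-conjugate "
            f"pair; use {n_s - 1} or {n_s + 1}"
        )


@dataclass
class SchurDecomposition:
    """Leading m columns of a sorted real Schur decomposition of P."""

    Q: np.ndarray             # N x m orthonormal
    R: np.ndarray             # m x m quasi-upper triangular
    eigenvalues: np.ndarray   # all N eigenvalues, sorted by the same key
    sort: str                 # "metastability" or "cyclicity"

    @property
    def m(self) -> int:
        return self.Q.shape[1]


@dataclass
class MembershipMatrix:
    """Soft assignment of cells to macrostates; rows on the simplex."""

    chi: np.ndarray
    macrostate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if (self.chi < -1e-10).any():
            raise ValidationError("membership entries below -1e-10")
        self.chi = np.maximum(self.chi, 0.0)
        rs = self.chi.sum(axis=1)
        if np.abs(rs - 1.0).max() > 1e-8:
            raise ValidationError("membership rows do not sum to 1")
        if self.macrostate_names is None:
            self.macrostate_names = [
                f"macro_{j}" for j in range(self.chi.shape[1])
            ]

    @property
    def n_states(self) -> int:
        return self.chi.shape[1]

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.chi, axis=1)


@dataclass
class GPCCAResult:
    chi: MembershipMatrix
    rotation: np.ndarray
    P_c: np.ndarray
    xi: float                 # crispness, in (0, 1]
    min_chi: float
    objective: float
    weight_vector: np.ndarray
    n_s: int
    eigenvalues: np.ndarray | None = None


# ---------------------------------------------------------------------------
# sorted real Schur


def _block_starts(T: np.ndarray) -> list[tuple[int, int]]:
    """(start, size) of the diagonal blocks of a real Schur form."""
    n = T.shape[0]
    blocks = []
    k = 0
    while k < n:
        if k + 1 < n and T[k + 1, k] != 0.0:
            blocks.append((k, 2))
            k += 2
        else:
            blocks.append((k, 1))
            k += 1
    return blocks


def _block_eigvals(T: np.ndarray, start: int, size: int) -> np.ndarray:
    if size == 1:
        return np.array([T[start, start]], dtype=complex)
    a, b = T[start, start], T[start, start + 1]
    c, d = T[start + 1, start], T[start + 1, start + 1]
    tr, det = a + d, a * d - b * c
    disc = tr * tr / 4 - det
    root = np.sqrt(complex(disc))
    return np.array([tr / 2 + root, tr / 2 - root], dtype=complex)


def _sort_key(ev: complex, sort: str) -> float:
    return float(ev.real) if sort == "metastability" else float(abs(ev))


def sorted_real_schur(
    P: TransitionMatrix | np.ndarray | sp.spmatrix,
    m: int,
    sort: str = "metastability",
) -> SchurDecomposition:
    """Leading-m sorted real Schur decomposition of a transition matrix.

    A dense Schur factorization is computed and its diagonal blocks are
    reordered (LAPACK ``dtrexc``) so the m leading columns correspond to the
    eigenvalues with largest real part ("metastability") or largest modulus
    ("cyclicity"). If the cut at m would split a conjugate pair the leading
    block set is extended by one column and a warning is emitted.
    """
    if sort not in ("metastability", "cyclicity"):
        raise ValidationError(f"unknown sort criterion {sort!r}")
    A = P.probs if isinstance(P, TransitionMatrix) else P
    A = np.asarray(A.todense() if sp.issparse(A) else A, dtype=float)
    n = A.shape[0]
    if not 1 <= m <= n:
        raise ValidationError(f"need 1 <= m <= N, got m={m}, N={n}")
    T, Z = _dense_schur(A, output="real")
    T = np.asfortranarray(T)
    Z = np.asfortranarray(Z)

    pos = 0
    while pos < m:
        blocks = _block_starts(T)
        candidates = [(s, sz) for s, sz in blocks if s >= pos]
        best = max(
            candidates,
            key=lambda b: max(
                _sort_key(ev, sort) for ev in _block_eigvals(T, *b)
            ),
        )
        if best[0] != pos:
            T, Z, info = lapack.dtrexc(T, Z, best[0] + 1, pos + 1, wantq=1)
            if info < 0:
                raise RuntimeError(f"dtrexc failed with info={info}")
            if info == 1:
                warnings.warn(
                    "ill-conditioned block swap during Schur reordering; "
                    "the factorization was slightly perturbed"
                )
            T = np.asfortranarray(T)
            Z = np.asfortranarray(Z)
        # size of the block that now sits at `pos`
        size = 2 if pos + 1 < n and T[pos + 1, pos] != 0.0 else 1
        pos += size
    if pos > m:
        warnings.warn(
            f"m={m} would split a conjugate pair; extended to {pos}"
        )
        m = pos

    all_eigs = np.concatenate(
        [_block_eigvals(T, s, sz) for s, sz in _block_starts(T)]
    )
    order = np.argsort([-_sort_key(ev, sort) for ev in all_eigs], kind="stable")
    return SchurDecomposition(
        Q=np.ascontiguousarray(Z[:, :m]),
        R=np.ascontiguousarray(T[:m, :m]),
        eigenvalues=all_eigs[order],
        sort=sort,
    )


def select_invariant_subspace(schur: SchurDecomposition, n_s: int) -> np.ndarray:
    """First n_s sorted Schur vectors; refuses to split a 2x2 block."""
    if n_s > schur.m:
        raise ValidationError(
            f"requested {n_s} Schur vectors but only {schur.m} computed"
        )
    if n_s < schur.m and schur.R[n_s, n_s - 1] != 0.0:
        raise SplitConjugatePairError(n_s)
    return schur.Q[:, :n_s]


def _d_orthonormal_basis(Q: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Basis Q~ of span(Q) with Q~^T D Q~ = I and first column all ones.

    The constant vector must lie in the span (true when the subspace
    contains the unit right eigenvector of a row-stochastic P).
    """
    n, k = Q.shape
    d = np.asarray(d, dtype=float)
    d = d / d.sum()  # unit total weight => the ones vector has D-norm 1
    ones = np.ones(n)
    coef, res, *_ = np.linalg.lstsq(Q, ones, rcond=None)
    if np.linalg.norm(Q @ coef - ones) > 1e-6 * np.sqrt(n):
        raise ValidationError(
            "constant vector not contained in the selected invariant "
            "subspace; is P row-stochastic and the unit eigenvalue leading?"
        )
    basis = np.column_stack([ones, Q[:, :]])
    out = np.empty((n, k))
    filled = 0
    for j in range(basis.shape[1]):
        v = basis[:, j].copy()
        for i in range(filled):
            v -= (out[:, i] * d) @ v * out[:, i]
        nrm = np.sqrt((v * d) @ v)
        if nrm > 1e-10:
            out[:, filled] = v / nrm
            filled += 1
        if filled == k:
            break
    if filled < k:
        raise ValidationError("selected Schur vectors are rank deficient")
    # scale so the first column is exactly the ones vector
    out /= out[0, 0]
    return out


def initialize_rotation(Qtilde: np.ndarray) -> np.ndarray:
    """Initial rotation by an inner-simplex vertex search.

    Greedily picks the n_s rows of Q~ that span the largest simplex: the
    first vertex is the row farthest from the origin after removing the
    constant direction; each next vertex is the row farthest from the span
    of those already chosen (Gram-Schmidt deflation). A0 is the inverse of
    the selected vertex submatrix, so chi0 = Q~ A0 is the identity at the
    vertices.
    """
    n, k = Qtilde.shape
    if k == 1:
        return np.ones((1, 1))
    ortho = Qtilde.copy()
    # remove the constant direction (first column is ones)
    ortho[:, 0] = 0.0
    index = np.empty(k, dtype=int)
    # first vertex: row farthest from the origin; then translate so it sits
    # at the origin and greedily pick rows farthest from the current span
    index[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[index[0]]
    for j in range(1, k):
        norms = np.linalg.norm(ortho, axis=1)
        index[j] = int(np.argmax(norms))
        nv = norms[index[j]]
        if nv < 1e-12:
            raise ValidationError(
                "degenerate vertex search: rows are rank deficient"
            )
        v = ortho[index[j]] / nv
        ortho = ortho - np.outer(ortho @ v, v)
    vertices = Qtilde[index, :]
    if abs(np.linalg.det(vertices)) < 1e-300:
        raise ValidationError("vertex submatrix is singular")
    return np.linalg.inv(vertices)


def _fill_constraints(A: np.ndarray, Qtilde: np.ndarray) -> np.ndarray:
    """Reconstruct row 1 and column 1 of A from the feasibility equations.

    Column 1 enforces partition of unity (rows of A sum to delta_i1), row 1
    enforces positivity of chi = Q~ A; the matrix is finally rescaled so the
    first row sums to one.
    """
    k = A.shape[0]
    A = A.copy()
    A[1:, 0] = -A[1:, 1:].sum(axis=1)
    A[0, :] = -(Qtilde[:, 1:] @ A[1:, :]).min(axis=0)
    s = A[0, :].sum()
    if s <= 0 or not np.isfinite(s):
        raise ValidationError("infeasible rotation: first row sums to <= 0")
    return A / s


def _objective(A: np.ndarray) -> float:
    """f(A) = n_s - trace(S) with trace(S) = sum_j (A^T A)_jj / A[0, j]."""
    k = A.shape[0]
    return k - float(((A * A).sum(axis=0) / A[0, :]).sum())


def optimize_rotation(
    Qtilde: np.ndarray,
    A0: np.ndarray,
    weight_vector: np.ndarray | None = None,
    maxfun: int = 10_000,
) -> GPCCAResult:
    """Optimize the rotation with derivative-free Nelder-Mead.

    Only the (n_s - 1)^2 trailing entries of A are free; the first row and
    column are reconstructed from the constraint equations after every
    candidate step, turning each infeasible iterate into a feasible one.
    """
    n, k = Qtilde.shape
    d = (
        np.full(n, 1.0 / n)
        if weight_vector is None
        else np.asarray(weight_vector, dtype=float)
    )
    if k == 1:
        chi = MembershipMatrix(np.ones((n, 1)))
        return GPCCAResult(
            chi=chi, rotation=np.ones((1, 1)), P_c=np.ones((1, 1)),
            xi=1.0, min_chi=0.0, objective=0.0, weight_vector=d, n_s=1,
        )
    minchi = float((Qtilde @ A0).min())

    def cost(free: np.ndarray) -> float:
        A = A0.copy()
        A[1:, 1:] = free.reshape(k - 1, k - 1)
        try:
            A = _fill_constraints(A, Qtilde)
        except ValidationError:
            return 1e10
        return _objective(A)

    x0 = A0[1:, 1:].ravel()
    res = minimize(
        cost, x0, method="Nelder-Mead",
        options={"maxfev": maxfun, "xatol": 1e-8, "fatol": 1e-8},
    )
    if not res.success:
        warnings.warn(
            f"rotation optimization stopped early ({res.message}); "
            "returning the best feasible point"
        )
    best = res.x if res.fun <= cost(x0) else x0
    A = A0.copy()
    A[1:, 1:] = best.reshape(k - 1, k - 1)
    A = _fill_constraints(A, Qtilde)
    chi_raw = Qtilde @ A
    chi_raw = np.maximum(chi_raw, 0.0)
    chi_raw /= chi_raw.sum(axis=1, keepdims=True)
    chi = MembershipMatrix(chi_raw)
    return GPCCAResult(
        chi=chi, rotation=A, P_c=np.empty((0, 0)),
        xi=crispness(chi_raw, d), min_chi=minchi,
        objective=_objective(A), weight_vector=d, n_s=k,
    )


def coarse_grain_transition(
    P: TransitionMatrix | np.ndarray | sp.spmatrix,
    chi: np.ndarray | MembershipMatrix,
    weight_vector: np.ndarray | None = None,
    negative_tol: float = 1e-2,
) -> np.ndarray:
    """Invariant-subspace projection P_c = (chi^T D chi)^-1 (chi^T D P chi).

    Entries below -negative_tol raise (macrostates overlap too much: change
    n_s). Weakly metastable macrostates — initial states in particular —
    routinely produce harmless negatives of order 1e-4 even at the correct
    n_s, so the hard error only fires at the percent scale; smaller
    negatives are clipped with a warning and rows renormalized.
    """
    A = P.probs if isinstance(P, TransitionMatrix) else P
    chi = chi.chi if isinstance(chi, MembershipMatrix) else np.asarray(chi)
    n = chi.shape[0]
    d = (
        np.full(n, 1.0 / n)
        if weight_vector is None
        else np.asarray(weight_vector, dtype=float)
    )
    Dchi = chi * d[:, None]
    W = chi.T @ Dchi
    if np.linalg.cond(W) > 1e12:
        raise ValidationError("chi^T D chi is singular: collapsed macrostates")
    PC = np.linalg.solve(W, Dchi.T @ (A @ chi))
    if PC.min() < -negative_tol:
        raise ValidationError(
            f"coarse transition matrix has entry {PC.min():.3e} < "
            f"-{negative_tol}; choose a different number of macrostates"
        )
    if PC.min() < -1e-8:
        warnings.warn(
            f"clipping small negative coarse-transition entries "
            f"(min {PC.min():.2e})"
        )
    PC = np.maximum(PC, 0.0)
    PC /= PC.sum(axis=1, keepdims=True)
    return PC


def crispness(
    chi: np.ndarray | MembershipMatrix, weight_vector: np.ndarray | None = None
) -> float:
    """xi = trace(D~^-1 chi^T D chi) / n_s in (0, 1]; 1 for hard labels."""
    chi = chi.chi if isinstance(chi, MembershipMatrix) else np.asarray(chi)
    n, k = chi.shape
    d = (
        np.full(n, 1.0 / n)
        if weight_vector is None
        else np.asarray(weight_vector, dtype=float)
    )
    W = chi.T @ (chi * d[:, None])
    return float((np.diag(W) / W.sum(axis=1)).sum() / k)


def min_chi(Qtilde: np.ndarray, A0: np.ndarray) -> float:
    """Most negative entry of the unoptimized membership chi0 = Q~ A0."""
    return float((Qtilde @ A0).min())


def run_gpcca(
    P: TransitionMatrix | np.ndarray | sp.spmatrix,
    n_s: int,
    weight_vector: np.ndarray | None = None,
    schur: SchurDecomposition | None = None,
    sort: str = "metastability",
) -> GPCCAResult:
    """Full coarse-graining: Schur -> subspace -> rotation -> P_c."""
    A = P.probs if isinstance(P, TransitionMatrix) else P
    n = A.shape[0]
    if schur is None:
        schur = sorted_real_schur(P, min(n_s + 1, n), sort=sort)
    try:
        Qsel = select_invariant_subspace(schur, n_s)
    except SplitConjugatePairError:
        raise
    d = (
        np.full(n, 1.0 / n)
        if weight_vector is None
        else np.asarray(weight_vector, dtype=float)
    )
    Qtilde = _d_orthonormal_basis(Qsel, d)
    if n_s == 1:
        result = optimize_rotation(Qtilde, np.ones((1, 1)), d)
    else:
        A0 = initialize_rotation(Qtilde)
        result = optimize_rotation(Qtilde, A0, d)
    result.P_c = coarse_grain_transition(P, result.chi, d)
    result.eigenvalues = schur.eigenvalues
    return result


def suggest_n_states(
    schur: SchurDecomposition,
    P: TransitionMatrix | np.ndarray | sp.spmatrix | None = None,
    strategy: str = "eigengap",
    candidates: range | list[int] | None = None,
    weight_vector: np.ndarray | None = None,
    minchi_tol: float = 0.05,
) -> int:
    """Choose the number of macrostates.

    "eigengap": n_s at the largest drop in sorted eigenvalue real parts.
    "crispness_scan": run the full optimization per candidate, keep max xi.
    "minchi_then_crispness": prefilter candidates by |minChi| <= minchi_tol,
    then crispness scan over the survivors.
    Candidates that would split a conjugate pair are pruned automatically.
    """
    m = schur.m
    if candidates is None:
        candidates = range(2, m + 1)
    cands = [n for n in candidates if 2 <= n <= m]
    # prune pair-splitting candidates
    cands = [
        n for n in cands
        if n == m or schur.R[n, n - 1] == 0.0
    ]
    if not cands:
        raise ValidationError("no admissible candidate numbers of macrostates")
    if strategy == "eigengap":
        re = np.real(schur.eigenvalues)
        gaps = {n: re[n - 1] - re[n] for n in cands if n < len(re)}
        if not gaps:
            return cands[0]
        best_gap = max(gaps.values())
        return min(n for n, gv in gaps.items() if gv == best_gap)
    if P is None:
        raise ValidationError(f"strategy {strategy!r} needs the matrix P")
    if strategy == "minchi_then_crispness":
        n = schur.Q.shape[0]
        d = (
            np.full(n, 1.0 / n)
            if weight_vector is None
            else np.asarray(weight_vector, dtype=float)
        )
        kept = []
        for ns in cands:
            Qt = _d_orthonormal_basis(schur.Q[:, :ns], d)
            try:
                mc = min_chi(Qt, initialize_rotation(Qt))
            except ValidationError:
                continue
            if abs(mc) <= minchi_tol:
                kept.append(ns)
        cands = kept or cands
        strategy = "crispness_scan"
    if strategy == "crispness_scan":
        best_ns, best_xi = None, -np.inf
        for ns in cands:
            try:
                res = run_gpcca(P, ns, weight_vector, schur=schur)
            except (ValidationError, SplitConjugatePairError):
                continue
            if res.xi > best_xi:
                best_ns, best_xi = ns, res.xi
        if best_ns is None:
            raise ValidationError("no candidate produced a feasible solution")
        return best_ns
    raise ValidationError(f"unknown strategy {strategy!r}")
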