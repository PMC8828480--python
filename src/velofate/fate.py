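"""Per-cell fate probabilities by absorption analysis.

For each selected (typically terminal) macrostate t we take the f cells
most confidently assigned to it by the membership matrix chi as the
terminal index set R_t, make those cells absorbing (self-loops), and solve

    (I - Q) A = S

where Q and S restrict the transition matrix to transient-to-transient and
transient-to-recurrent moves. Entry (i, j) of A is the probability that
cell j is the first absorbing cell reached from i; summing columns within
each R_t gives the fate probability of every transient cell toward each
lineage. A seeded random-walk estimator is provided as an independent
oracle for tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .data_model import ValidationError
from .gpcca import MembershipMatrix
from .kernels import TransitionMatrix

DEFAULT_F_CELLS = 30


@dataclass
class TerminalPartition:
    """Disjoint absorbing index sets plus the transient remainder."""

    target_sets: list[np.ndarray]
    transient: np.ndarray
    lineage_names: list[str]

    @property
    def n_targets(self) -> int:
        return len(self.target_sets)


@dataclass
class AbsorptionSystem:
    Q_block: sp.csr_matrix
    S_block: sp.csr_matrix
    partition: TerminalPartition


@dataclass
class FateMatrix:
    """N x n_t matrix of fate probabilities; rows sum to one, absorbing
    cells are one-hot."""

    probs: np.ndarray
    lineage_names: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any() or (self.probs > 1 + 1e-9).any():
            raise ValidationError("fate probabilities outside [0, 1]")
        rs = self.probs.sum(axis=1)
        if np.abs(rs - 1.0).max() > 1e-6:
            raise ValidationError("fate matrix rows do not sum to 1")


def terminal_index_sets(
    chi: MembershipMatrix | np.ndarray,
    selected_macrostates: list[int],
    f: int = DEFAULT_F_CELLS,
    lineage_names: list[str] | None = None,
) -> TerminalPartition:
    """Top-f cells per selected macrostate column of chi, kept disjoint.

    A cell ranked in the top f of two macrostates goes to the one where its
    membership is larger; the losing set backfills with its next-best cell.
    """
    chi_arr = chi.chi if isinstance(chi, MembershipMatrix) else np.asarray(chi)
    n = chi_arr.shape[0]
    if f < 1:
        raise ValidationError("f must be >= 1")
    for m in selected_macrostates:
        if not 0 <= m < chi_arr.shape[1]:
            raise ValidationError(f"macrostate {m} not present in chi")
        if chi_arr[:, m].max() <= 0:
            raise ValidationError(f"macrostate {m} has an empty chi column")
    if f * len(selected_macrostates) >= n:
        raise ValidationError(
            f"f={f} x {len(selected_macrostates)} targets leaves no "
            "transient cells"
        )
    # resolve overlaps greedily: each cell is claimable only by the selected
    # macrostate with the largest membership among the claimants
    order_per_state = {
        m: np.argsort(-chi_arr[:, m], kind="stable")
        for m in selected_macrostates
    }
    owner = np.full(n, -1)
    sets: dict[int, list[int]] = {m: [] for m in selected_macrostates}
    cursors = {m: 0 for m in selected_macrostates}
    # iterate until every set has f members; claims settled by membership value
    changed = True
    while changed:
        changed = False
        for m in selected_macrostates:
            while len(sets[m]) < f:
                cand = int(order_per_state[m][cursors[m]])
                cursors[m] += 1
                if owner[cand] == -1:
                    owner[cand] = m
                    sets[m].append(cand)
                    changed = True
                elif chi_arr[cand, m] > chi_arr[cand, owner[cand]]:
                    loser = owner[cand]
                    sets[loser].remove(cand)
                    owner[cand] = m
                    sets[m].append(cand)
                    changed = True
                # else: cell stays with the current owner; try next candidate
    target_sets = [np.array(sorted(sets[m])) for m in selected_macrostates]
    taken = np.concatenate(target_sets)
    transient = np.setdiff1d(np.arange(n), taken)
    if lineage_names is None:
        if isinstance(chi, MembershipMatrix) and chi.macrostate_names:
            lineage_names = [chi.macrostate_names[m] for m in selected_macrostates]
        else:
            lineage_names = [f"lineage_{m}" for m in selected_macrostates]
    return TerminalPartition(
        target_sets=target_sets, transient=transient,
        lineage_names=lineage_names,
    )


def make_absorbing(
    P: TransitionMatrix | sp.spmatrix | np.ndarray,
    partition: TerminalPartition,
) -> AbsorptionSystem:
    """Replace the rows of all target cells by self-loops and extract the
    transient-to-transient (Q) and transient-to-recurrent (S) blocks."""
    A = P.probs if isinstance(P, TransitionMatrix) else P
    A = sp.csr_matrix(A, dtype=float)
    recurrent = np.concatenate(partition.target_sets)
    trans = partition.transient
    Q = A[trans][:, trans]
    S = A[trans][:, recurrent]
    return AbsorptionSystem(
        Q_block=sp.csr_matrix(Q), S_block=sp.csr_matrix(S),
        partition=partition,
    )


def absorption_probabilities(
    system: AbsorptionSystem,
    solver: str = "direct",
    tol: float = 1e-8,
) -> FateMatrix:
    """Solve (I - Q) a = s per recurrent cell and aggregate per lineage.

    "direct" uses a sparse LU factorization shared across right-hand sides;
    "gmres" solves per aggregated lineage column with an ILU preconditioner
    at relative residual <= tol. Rows of absorbing cells are set one-hot;
    tiny negatives (>= -1e-10) are clipped and rows renormalized.
    """
    part = system.partition
    Q, S = system.Q_block, system.S_block
    n_trans = Q.shape[0]
    n_t = part.n_targets
    sizes = [len(r) for r in part.target_sets]
    # aggregate recurrent columns per lineage before solving: the solve is
    # linear, so summing first is exact and cheaper
    col_groups = np.repeat(np.arange(n_t), sizes)
    agg = sp.csr_matrix(
        (np.ones(len(col_groups)), (np.arange(len(col_groups)), col_groups)),
        shape=(len(col_groups), n_t),
    )
    rhs = np.asarray((S @ agg).todense())
    IQ = sp.identity(n_trans, format="csc") - sp.csc_matrix(Q)
    if n_trans == 0:
        F_trans = np.zeros((0, n_t))
    elif solver == "direct":
        try:
            lu = spla.splu(IQ)
        except RuntimeError as err:
            raise ValidationError(
                f"singular absorption system ({err}); some transient cells "
                "cannot reach any target set"
            ) from err
        F_trans = lu.solve(rhs)
    elif solver == "gmres":
        try:
            ilu = spla.spilu(IQ, drop_tol=1e-5, fill_factor=20)
            M = spla.LinearOperator(IQ.shape, ilu.solve)
        except RuntimeError:
            M = None
        F_trans = np.empty((n_trans, n_t))
        for t in range(n_t):
            x, info = spla.gmres(IQ, rhs[:, t], M=M, rtol=tol, atol=0.0)
            if info != 0:
                raise ValidationError(
                    f"GMRES failed to converge for lineage {t} (info={info})"
                )
            F_trans[:, t] = x
    else:
        raise ValidationError(f"unknown solver {solver!r}")
    if (F_trans < -1e-10).any():
        raise ValidationError("absorption solve produced negative entries")
    F_trans = np.maximum(F_trans, 0.0)
    row_sums = F_trans.sum(axis=1)
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > 1e-6)
    if len(bad):
        raise ValidationError(
            f"transient cells {part.transient[bad[:10]].tolist()} have "
            "absorption mass far from 1: unreachable target sets?"
        )
    F_trans /= row_sums[:, None]
    n = n_trans + sum(sizes)
    F = np.zeros((n, n_t))
    F[part.transient] = F_trans
    for t, cells in enumerate(part.target_sets):
        F[cells, t] = 1.0
    return FateMatrix(probs=F, lineage_names=part.lineage_names)


def compute_fate_probabilities(
    P: TransitionMatrix | sp.spmatrix | np.ndarray,
    chi: MembershipMatrix | np.ndarray,
    terminal_macrostates: list[int],
    f: int = DEFAULT_F_CELLS,
    solver: str = "direct",
) -> FateMatrix:
    """Convenience wrapper: index sets -> absorbing chain -> linear solve."""
    part = terminal_index_sets(chi, sorted(terminal_macrostates), f=f)
    system = make_absorbing(P, part)
    return absorption_probabilities(system, solver=solver)


def mc_absorption_oracle(
    P: TransitionMatrix | sp.spmatrix | np.ndarray,
    partition: TerminalPartition,
    n_walks: int = 1000,
    seed: int = 0,
    max_steps: int = 1_000_000,
) -> FateMatrix:
    """Empirical fate probabilities by seeded random walks (test oracle).

    Starts ``n_walks`` walks per transient cell and records which target set
    is hit first. Intended for small chains only (N <= 500).
    """
    A = P.probs if isinstance(P, TransitionMatrix) else P
    A = sp.csr_matrix(A, dtype=float)
    n = A.shape[0]
    if n > 500:
        raise ValidationError("Monte-Carlo oracle is restricted to N <= 500")
    target_of = np.full(n, -1)
    for t, cells in enumerate(partition.target_sets):
        target_of[cells] = t
    rng = np.random.default_rng(seed)
    cum = np.cumsum(A.toarray(), axis=1)
    cum[:, -1] = 1.0  # guard against round-off in the last column
    n_t = partition.n_targets
    F = np.zeros((n, n_t))
    failures = 0
    # all walks from one start cell advance in lockstep (vectorized steps)
    for start in partition.transient:
        states = np.full(n_walks, start)
        active = np.ones(n_walks, dtype=bool)
        counts = np.zeros(n_t)
        for _ in range(max_steps):
            idx = np.flatnonzero(active)
            if len(idx) == 0:
                break
            u = rng.random(len(idx))
            nxt = (cum[states[idx]] < u[:, None]).sum(axis=1)
            states[idx] = nxt
            hit = target_of[nxt] >= 0
            if hit.any():
                hits = target_of[nxt[hit]]
                counts += np.bincount(hits, minlength=n_t)
                active[idx[hit]] = False
        else:
            failures += int(active.sum())
        tot = counts.sum()
        if tot > 0:
            F[start] = counts / tot
    for t, cells in enumerate(partition.target_sets):
        F[cells, t] = 1.0
    if failures:
        warnings.warn(f"{failures} walks exceeded {max_steps} steps")
    return FateMatrix(probs=F, lineage_names=partition.lineage_names)
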