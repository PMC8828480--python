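"""Classification of macrostates as initial, terminal or intermediate.

Terminal states are macrostates with a high stability index SI (their
self-transition probability in the coarse-grained chain, diag(P_c));
SI >= 0.96 by default. Initial states are the macrostates the chain spends
the least long-run time in: the smallest entries of the coarse-grained
stationary distribution pi_c = chi^T pi, where pi is the stationary
distribution of the fine chain (left unit eigenvector of P). Reducible
chains (disconnected KNN graphs) are handled by excluding outlier
macrostates that exchange no probability with the rest, then computing pi
on the remaining irreducible part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .data_model import ExpressionMatrix, ValidationError, VelocityField
from .gpcca import MembershipMatrix
from .kernels import KernelParams, TransitionMatrix

DEFAULT_SI_THRESHOLD = 0.96


class ReducibleChainError(ValidationError):
    """The chain has several closed communicating classes; exclude outliers
    with :func:`handle_reducible` before asking for a stationary
    distribution."""


@dataclass
class StationaryDistribution:
    pi: np.ndarray
    pi_coarse: np.ndarray | None = None


@dataclass
class StateClassification:
    terminal: set[int]
    initial: set[int]
    intermediate: set[int]
    outlier: set[int]
    stability_index: np.ndarray
    pi_coarse: np.ndarray | None
    si_threshold: float
    n_initial: int

    def label_of(self, j: int) -> str:
        for name in ("terminal", "initial", "intermediate", "outlier"):
            if j in getattr(self, name):
                return name
        return "unclassified"


def stationary_distribution(
    P: TransitionMatrix | sp.spmatrix | np.ndarray,
) -> StationaryDistribution:
    """Left eigenvector of P for eigenvalue 1, normalized to sum one.

    Raises :class:`ReducibleChainError` when the chain has more than one
    strongly connected closed class (the stationary distribution is then
    not unique).
    """
    A = P.probs if isinstance(P, TransitionMatrix) else P
    A = sp.csr_matrix(A)
    n = A.shape[0]
    n_comp, _ = connected_components(A, directed=True, connection="strong")
    if n_comp > 1:
        raise ReducibleChainError(
            f"chain is reducible ({n_comp} strongly connected components); "
            "run handle_reducible first"
        )
    if n <= 2000:
        w, vl = np.linalg.eig(A.toarray().T)
        idx = int(np.argmax(w.real))
        pi = np.abs(np.real(vl[:, idx]))
    else:
        from scipy.sparse.linalg import eigs

        w, vl = eigs(A.T.tocsc(), k=1, which="LM", v0=np.full(n, 1.0 / n))
        pi = np.abs(np.real(vl[:, 0]))
    pi = pi / pi.sum()
    resid = np.abs(pi @ A - pi).sum()
    if resid > 1e-8:
        raise ValidationError(
            f"stationary residual {resid:.2e} exceeds 1e-8; chain may be "
            "nearly reducible"
        )
    return StationaryDistribution(pi=pi)


def coarse_stationary(
    chi: MembershipMatrix | np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Coarse-grained stationary distribution pi_c = chi^T pi."""
    chi = chi.chi if isinstance(chi, MembershipMatrix) else np.asarray(chi)
    return chi.T @ np.asarray(pi, dtype=float)


def classify_terminal(
    P_c: np.ndarray, si_threshold: float = DEFAULT_SI_THRESHOLD
) -> tuple[set[int], np.ndarray]:
    """Threshold the stability index SI = diag(P_c)."""
    si = np.diag(np.asarray(P_c, dtype=float)).copy()
    terminal = set(int(j) for j in np.flatnonzero(si >= si_threshold))
    if not terminal:
        warnings.warn(
            f"no macrostate has SI >= {si_threshold}; lower the threshold or "
            "assign terminal states manually"
        )
    return terminal, si


def classify_initial(
    pi_coarse: np.ndarray,
    n_initial: int = 1,
    exclude: set[int] | None = None,
) -> set[int]:
    """The n_initial macrostates with smallest coarse stationary mass among
    the non-excluded candidates. Ties are broken by lower index, with a
    warning."""
    pi_c = np.asarray(pi_coarse, dtype=float)
    exclude = exclude or set()
    candidates = [j for j in range(len(pi_c)) if j not in exclude]
    if n_initial > len(candidates):
        raise ValidationError(
            f"n_initial={n_initial} exceeds the {len(candidates)} available "
            "macrostates"
        )
    order = sorted(candidates, key=lambda j: (pi_c[j], j))
    chosen = order[:n_initial]
    if len(order) > n_initial and pi_c[order[n_initial - 1]] == pi_c[order[n_initial]]:
        warnings.warn("tie in coarse stationary mass broken by lower index")
    return set(int(j) for j in chosen)


def handle_reducible(
    P: TransitionMatrix | sp.spmatrix | np.ndarray,
    chi: MembershipMatrix | np.ndarray | None = None,
    P_c: np.ndarray | None = None,
    flow_tol: float = 1e-12,
) -> dict:
    """Component analysis of a possibly reducible chain.

    Returns a report with the weakly connected components, the outlier
    macrostates (zero coarse in- and out-flow, when chi/P_c are supplied)
    and, if the main component is irreducible, the stationary distribution
    supported on it (zeros elsewhere).
    """
    A = P.probs if isinstance(P, TransitionMatrix) else P
    A = sp.csr_matrix(A)
    n = A.shape[0]
    n_weak, weak = connected_components(A, directed=True, connection="weak")
    sizes = np.bincount(weak, minlength=n_weak)
    main = int(np.argmax(sizes))

    excluded_macrostates: set[int] = set()
    if n_weak > 1 and chi is not None:
        # outliers: macrostates living entirely outside the main component;
        # zero coarse in-/out-flow in P_c confirms the call when available
        chi_arr = chi.chi if isinstance(chi, MembershipMatrix) else chi
        labels = np.argmax(chi_arr, axis=1)
        for j in range(chi_arr.shape[1]):
            members = np.flatnonzero(labels == j)
            if len(members) == 0 or (weak[members] == main).any():
                continue
            if P_c is not None:
                out_flow = P_c[j, :].sum() - P_c[j, j]
                in_flow = P_c[:, j].sum() - P_c[j, j]
                if out_flow > flow_tol or in_flow > flow_tol:
                    continue
            excluded_macrostates.add(j)

    pi = np.zeros(n)
    main_cells = np.flatnonzero(weak == main)
    sub = A[main_cells][:, main_cells]
    rs = np.asarray(sub.sum(axis=1)).ravel()
    stationary_ok = False
    if np.abs(rs - 1.0).max() < 1e-9:
        try:
            pi_sub = stationary_distribution(sub).pi
            pi[main_cells] = pi_sub
            stationary_ok = True
        except ValidationError:
            pass
    return {
        "n_components": int(n_weak),
        "component_labels": weak,
        "component_sizes": sizes.tolist(),
        "main_component": main,
        "excluded_macrostates": excluded_macrostates,
        "stationary": pi if stationary_ok else None,
    }


def classify_states(
    P_c: np.ndarray,
    pi_coarse: np.ndarray | None,
    si_threshold: float = DEFAULT_SI_THRESHOLD,
    n_initial: int = 1,
    outliers: set[int] | None = None,
    terminal_override: set[int] | None = None,
) -> StateClassification:
    """Full classification from the coarse chain and its stationary mass.

    ``terminal_override`` adds manually promoted terminal macrostates (for
    populations known to be terminal despite a sub-threshold SI). Terminal
    macrostates and outliers are excluded from the initial-state candidates.
    """
    outliers = set(outliers or set())
    terminal, si = classify_terminal(P_c, si_threshold)
    terminal |= set(terminal_override or set())
    terminal -= outliers
    initial: set[int] = set()
    if pi_coarse is not None:
        exclude = terminal | outliers
        if len(exclude) < P_c.shape[0]:
            n_avail = P_c.shape[0] - len(exclude)
            initial = classify_initial(
                pi_coarse, min(n_initial, n_avail), exclude=exclude
            )
    intermediate = (
        set(range(P_c.shape[0])) - terminal - initial - outliers
    )
    return StateClassification(
        terminal=terminal,
        initial=initial,
        intermediate=intermediate,
        outlier=outliers,
        stability_index=si,
        pi_coarse=pi_coarse,
        si_threshold=si_threshold,
        n_initial=n_initial,
    )


def recover_initial_by_reversal(
    expr: ExpressionMatrix,
    vel: VelocityField,
    graph,
    params: KernelParams | None = None,
    n_s: int = 3,
    si_threshold: float = DEFAULT_SI_THRESHOLD,
):
    """Run the coarse-graining pipeline on the reversed chain.

    The velocity arrows are flipped (backward=True), so terminal macrostates
    of the reversed chain mark the initial states of the forward dynamics.
    Returns (classification, gpcca_result, transition_matrix) of the
    reversed chain; its `terminal` set is the forward chain's initial states.
    """
    from dataclasses import replace

    from .gpcca import run_gpcca
    from .kernels import transition_matrix

    params = params or KernelParams()
    params = replace(params, backward=True)
    P_back = transition_matrix(expr, vel, graph, params)
    result = run_gpcca(P_back, n_s)
    terminal, si = classify_terminal(result.P_c, si_threshold)
    classification = StateClassification(
        terminal=terminal,
        initial=set(),
        intermediate=set(range(n_s)) - terminal,
        outlier=set(),
        stability_index=si,
        pi_coarse=None,
        si_threshold=si_threshold,
        n_initial=0,
    )
    return classification, result, P_back
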