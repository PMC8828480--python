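"""End-to-end orchestration: graph -> kernel -> coarse-graining ->
state classification -> fate probabilities, with artifacts and a
machine-readable run report."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    ClusterLabels,
    ExpressionMatrix,
    PseudotimeVector,
    ValidationError,
    VelocityField,
    validate_paired_inputs,
)
from .fate import FateMatrix, compute_fate_probabilities
from .gpcca import (
    GPCCAResult,
    SplitConjugatePairError,
    run_gpcca,
    sorted_real_schur,
    suggest_n_states,
)
from .io import RunConfig, write_transition_matrix
from .kernels import KernelParams, TransitionMatrix, transition_matrix
from .neighbors import NeighborGraph, build_graph
from .states import (
    StateClassification,
    classify_states,
    coarse_stationary,
    handle_reducible,
    stationary_distribution,
)


@dataclass
class PipelineResult:
    graph: NeighborGraph
    P: TransitionMatrix
    gpcca: GPCCAResult
    classification: StateClassification
    fate: FateMatrix | None
    pi: np.ndarray | None
    pi_coarse: np.ndarray | None
    report: dict = field(default_factory=dict)


def run_pipeline(
    expr: ExpressionMatrix,
    vel: VelocityField,
    config: RunConfig | None = None,
    pseudotime: PseudotimeVector | None = None,
    labels: ClusterLabels | None = None,
    out_dir: str | Path | None = None,
    terminal_override: set[int] | None = None,
) -> PipelineResult:
    """Execute the full fate-mapping pipeline on validated inputs.

    When ``out_dir`` is given, every intermediate artifact (transition
    matrix, memberships, coarse chain, classification, fate matrix) and a
    JSON run report are written there.
    """
    config = config or RunConfig()
    validate_paired_inputs(expr, vel)

    graph = build_graph(
        expr, K=config.k_neighbors, L=config.n_pcs,
        method=config.similarity,
    )
    connectivity = graph.connectivity_report()

    params = KernelParams(
        sigma=config.sigma,
        lambda_weight=config.lambda_weight,
        mode=config.mode,
        n_samples=config.n_samples,
        backward=config.backward,
        density_normalize=config.density_normalize,
        seed=config.seed,
    )
    P = transition_matrix(expr, vel, graph, params)

    m = min(config.max_macrostates + 1, expr.n_cells)
    schur = sorted_real_schur(P, m)
    if config.n_macrostates is None:
        n_s = suggest_n_states(schur, P, strategy="eigengap")
    else:
        n_s = config.n_macrostates
    try:
        gp = run_gpcca(P, n_s, schur=schur)
    except SplitConjugatePairError as err:
        gp = run_gpcca(P, err.n_s + 1, schur=schur)
        n_s = err.n_s + 1

    reducibility = handle_reducible(P, chi=gp.chi, P_c=gp.P_c)
    outliers = reducibility["excluded_macrostates"]
    if reducibility["n_components"] == 1:
        pi = stationary_distribution(P).pi
    else:
        pi = reducibility["stationary"]
    pi_coarse = coarse_stationary(gp.chi, pi) if pi is not None else None

    classification = classify_states(
        gp.P_c, pi_coarse,
        si_threshold=config.si_threshold,
        n_initial=config.n_initial,
        outliers=outliers,
        terminal_override=terminal_override,
    )

    fate = None
    n_terminal = len(classification.terminal)
    if n_terminal >= 1 and config.f_cells * n_terminal < expr.n_cells:
        fate = compute_fate_probabilities(
            P, gp.chi, sorted(classification.terminal), f=config.f_cells
        )

    report = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "n_cells": expr.n_cells,
        "n_genes": expr.n_genes,
        "sigma": gp_params_sigma(P),
        "n_macrostates": n_s,
        "crispness": gp.xi,
        "min_chi": gp.min_chi,
        "eigenvalues_real": np.real(gp.eigenvalues[:m]).tolist()
        if gp.eigenvalues is not None else None,
        "stability_index": classification.stability_index.tolist(),
        "coarse_stationary": (
            pi_coarse.tolist() if pi_coarse is not None else None
        ),
        "terminal": sorted(classification.terminal),
        "initial": sorted(classification.initial),
        "intermediate": sorted(classification.intermediate),
        "outlier": sorted(classification.outlier),
        "graph_components": connectivity["n_components"],
    }

    result = PipelineResult(
        graph=graph, P=P, gpcca=gp, classification=classification,
        fate=fate, pi=pi, pi_coarse=pi_coarse, report=report,
    )
    if out_dir is not None:
        _write_artifacts(result, expr, Path(out_dir))
    return result


def gp_params_sigma(P: TransitionMatrix) -> float | None:
    s = P.params.get("sigma")
    return float(s) if s is not None else None


def _write_artifacts(
    result: PipelineResult, expr: ExpressionMatrix, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_transition_matrix(out / "transition_matrix.mtx", result.P)
    chi = result.gpcca.chi
    pd.DataFrame(
        chi.chi, index=expr.cell_ids, columns=chi.macrostate_names
    ).to_csv(out / "memberships.tsv", sep="\t")
    pd.DataFrame(
        result.gpcca.P_c,
        index=chi.macrostate_names,
        columns=chi.macrostate_names,
    ).to_csv(out / "coarse_transition_matrix.tsv", sep="\t")
    cls = result.classification
    rows = []
    for j, name in enumerate(chi.macrostate_names):
        rows.append({
            "macrostate": name,
            "stability_index": cls.stability_index[j],
            "coarse_stationary": (
                result.pi_coarse[j] if result.pi_coarse is not None else np.nan
            ),
            "class": cls.label_of(j),
        })
    pd.DataFrame(rows).to_csv(out / "state_classification.tsv", sep="\t",
                              index=False)
    if result.fate is not None:
        pd.DataFrame(
            result.fate.probs, index=expr.cell_ids,
            columns=result.fate.lineage_names,
        ).to_csv(out / "fate_probabilities.tsv", sep="\t")
    if result.pi is not None:
        pd.Series(result.pi, index=expr.cell_ids).to_csv(
            out / "stationary_distribution.tsv", sep="\t", header=False
        )
    (out / "run_report.json").write_text(
        json.dumps(result.report, indent=2, default=float)
    )
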