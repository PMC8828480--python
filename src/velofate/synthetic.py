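"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline end to end without any external data:
planted block-stochastic Markov chains (ground-truth macrostates), branching
velocity fields (smooth differentiation trajectories with a known source,
bifurcation and attractors), and noisy gene-trend families (known smooth
templates for trend fitting and clustering). All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_model import ExpressionMatrix, ValidationError, VelocityField


@dataclass
class PlantedChain:
    P: sp.csr_matrix
    block_assignment: np.ndarray
    leak: float
    topology: str
    seed: int

    @property
    def n_blocks(self) -> int:
        return int(self.block_assignment.max()) + 1


@dataclass
class BranchingField:
    """Cells sampled along smooth bifurcating curves in gene space.

    Expression follows cubic Bezier curves that share their root segment and
    tangent, then diverge toward well-separated attractors; velocities are
    the exact derivatives of the generating curves under a speed profile
    t (1 - t)^2 that vanishes at both ends: the source is a quasi-steady
    progenitor pool (a repelling fixed point of the flow) and each branch
    end an attractor with inward-decaying speed. Source cells sit at t ~ 0,
    attractor cells at t ~ 1.
    """

    expr: ExpressionMatrix
    vel: VelocityField
    true_time: np.ndarray
    branch: np.ndarray
    source_cells: np.ndarray
    attractor_cells: list[np.ndarray]   # one array per branch
    bifurcation_time: float
    params: dict = field(default_factory=dict)


def simulate_planted_chain(
    block_sizes: list[int],
    leak: float = 1e-3,
    seed: int = 0,
    block_topology: str = "line",
) -> PlantedChain:
    """Block-stochastic chain: rows uniform within their block carrying mass
    1 - leak; the leak flows per the block-level topology.

    Topologies: "line" (block i leaks to i+1; the final block is closed),
    "cycle" (i leaks to i+1 mod B; irreducible for leak > 0), "all" (leak
    spread uniformly over the other blocks; irreducible) and "uniform"
    (leak spread over every state including the own block, making the chain
    doubly stochastic so stationary block masses are proportional to block
    sizes).
    """
    if not 0 <= leak < 0.5:
        raise ValidationError("leak must lie in [0, 0.5)")
    if any(s < 2 for s in block_sizes):
        raise ValidationError("block sizes must be >= 2")
    if block_topology not in ("line", "cycle", "all", "uniform"):
        raise ValidationError(f"unknown topology {block_topology!r}")
    n_blocks = len(block_sizes)
    starts = np.concatenate([[0], np.cumsum(block_sizes)])
    n = int(starts[-1])
    assignment = np.concatenate(
        [np.full(s, b) for b, s in enumerate(block_sizes)]
    )
    if block_topology == "uniform":
        P = np.full((n, n), leak / n)
        for b, size in enumerate(block_sizes):
            members = slice(starts[b], starts[b + 1])
            P[members, members] += (1.0 - leak) / size
        return PlantedChain(
            P=sp.csr_matrix(P), block_assignment=assignment, leak=leak,
            topology=block_topology, seed=seed,
        )
    targets: list[list[int]] = []
    for b in range(n_blocks):
        if block_topology == "line":
            targets.append([b + 1] if b + 1 < n_blocks else [])
        elif block_topology == "cycle":
            targets.append([(b + 1) % n_blocks] if n_blocks > 1 else [])
        else:
            targets.append([j for j in range(n_blocks) if j != b])
    rows, cols, vals = [], [], []
    for b, size in enumerate(block_sizes):
        members = np.arange(starts[b], starts[b + 1])
        out_blocks = targets[b]
        within = (1.0 - leak) if (out_blocks and leak > 0) else 1.0
        for i in members:
            rows.extend([i] * size)
            cols.extend(members)
            vals.extend([within / size] * size)
            if out_blocks and leak > 0:
                per_block = leak / len(out_blocks)
                for tb in out_blocks:
                    tgt = np.arange(starts[tb], starts[tb + 1])
                    rows.extend([i] * len(tgt))
                    cols.extend(tgt)
                    vals.extend([per_block / len(tgt)] * len(tgt))
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return PlantedChain(
        P=P, block_assignment=assignment, leak=leak,
        topology=block_topology, seed=seed,
    )


def _bezier(t: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Cubic Bezier curve; ctrl is 4 x d."""
    t = t[:, None]
    return (
        (1 - t) ** 3 * ctrl[0]
        + 3 * (1 - t) ** 2 * t * ctrl[1]
        + 3 * (1 - t) * t ** 2 * ctrl[2]
        + t ** 3 * ctrl[3]
    )


def _bezier_deriv(t: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (
        3 * (1 - t) ** 2 * (ctrl[1] - ctrl[0])
        + 6 * (1 - t) * t * (ctrl[2] - ctrl[1])
        + 3 * t ** 2 * (ctrl[3] - ctrl[2])
    )


def simulate_branching_field(
    n_cells: int = 1000,
    n_genes: int = 20,
    n_branches: int = 2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> BranchingField:
    """Branching differentiation trajectory with exact tangent velocities.

    Latent 3-D cubic Bezier curves share the first two control points (one
    root segment and tangent), then fan out at evenly spread angles toward
    distant endpoints; the latent curves are embedded into gene space by a
    seeded random orthonormal map. Expression and velocity both receive
    i.i.d. Gaussian noise of the given standard deviation (in log-expression
    units; the curve scale is of order 4).
    """
    if n_genes < 3:
        raise ValidationError("need at least 3 genes")
    if n_branches < 1:
        raise ValidationError("need at least 1 branch")
    rng = np.random.default_rng(seed)
    d = 3
    p0 = np.zeros(d)
    p1 = np.array([1.5, 0.0, 0.0])
    if n_branches == 1:
        angles = np.array([0.0])
    else:
        angles = np.linspace(-np.pi / 4, np.pi / 4, n_branches)
    controls = []
    for b in range(n_branches):
        u = np.array([np.cos(angles[b]), np.sin(angles[b]), 0.0])
        jitter = rng.normal(0, 0.05, size=d)
        p2 = p1 + 1.5 * u + jitter
        p3 = p1 + 3.0 * u + jitter
        controls.append(np.stack([p0, p1, p2, p3]))

    t = rng.uniform(0.0, 1.0, size=n_cells)
    branch = rng.integers(0, n_branches, size=n_cells)
    latent_x = np.empty((n_cells, d))
    latent_v = np.empty((n_cells, d))
    for b in range(n_branches):
        mask = branch == b
        latent_x[mask] = _bezier(t[mask], controls[b])
        # speed profile 3 t (1-t)^2: zero at the progenitor fixed point,
        # peaks mid-trajectory, decays into the attractor
        speed = 3.0 * t[mask] * (1 - t[mask]) ** 2
        latent_v[mask] = _bezier_deriv(t[mask], controls[b]) * speed[:, None]
    # seeded orthonormal embedding of the latent space into gene space
    embed, _ = np.linalg.qr(rng.normal(size=(n_genes, d)))
    X = latent_x @ embed.T + rng.normal(0, noise_sd, size=(n_cells, n_genes))
    V = latent_v @ embed.T + rng.normal(0, noise_sd, size=(n_cells, n_genes))
    cell_ids = [f"cell_{i}" for i in range(n_cells)]
    gene_ids = [f"gene_{j}" for j in range(n_genes)]
    expr = ExpressionMatrix(values=X, cell_ids=cell_ids, gene_ids=gene_ids)
    vel = VelocityField(values=V, cell_ids=cell_ids, gene_ids=gene_ids)
    source = np.flatnonzero(t < 0.1)
    attractors = [
        np.flatnonzero((branch == b) & (t > 0.9)) for b in range(n_branches)
    ]
    return BranchingField(
        expr=expr, vel=vel, true_time=t, branch=branch,
        source_cells=source, attractor_cells=attractors,
        bifurcation_time=0.3,
        params={
            "n_cells": n_cells, "n_genes": n_genes,
            "n_branches": n_branches, "noise_sd": noise_sd, "seed": seed,
        },
    )


TREND_SHAPES = ("linear", "sigmoid", "peak")


def trend_template(shape: str, tau: np.ndarray) -> np.ndarray:
    """Named smooth trend templates on tau in [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    if shape == "linear":
        return tau.copy()
    if shape == "sigmoid":
        return 1.0 / (1.0 + np.exp(-10.0 * (tau - 0.5)))
    if shape == "peak":
        return np.exp(-((tau - 0.5) ** 2) / (2 * 0.15 ** 2))
    raise ValidationError(f"unknown trend shape {shape!r}")


def simulate_trend_families(
    n_genes_per_family: int = 50,
    shapes: tuple[str, ...] = ("linear", "peak"),
    n_cells: int = 300,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Genes drawn from smooth shape templates with amplitude jitter.

    Returns (expression N x n_genes, pseudotime, family labels, true curves
    per gene evaluated at the cells).
    """
    if not shapes:
        raise ValidationError("need at least one family shape")
    rng = np.random.default_rng(seed)
    tau = np.sort(rng.uniform(0.0, 1.0, size=n_cells))
    genes, labels, truths = [], [], []
    for fam, shape in enumerate(shapes):
        base = trend_template(shape, tau)
        for _ in range(n_genes_per_family):
            amp = rng.uniform(0.8, 1.2)
            truth = amp * base
            genes.append(truth + rng.normal(0, noise_sd, size=n_cells))
            labels.append(fam)
            truths.append(truth)
    Y = np.column_stack(genes)
    return Y, tau, np.asarray(labels), np.column_stack(truths)
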