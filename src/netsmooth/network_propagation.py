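"""Laplacian normalization and iterative diffusion over the interaction network.

Given a weighted graph G = (V, E, w), the normalized weight matrix is
W' = D^-1/2 W D^-1/2 with D the diagonal of weighted degrees. A prior
vector Y over V is smoothed by iterating

    F(t) = alpha * W' F(t-1) + (1 - alpha) * Y,   F(0) = Y,

until ||F(t) - F(t-1)||_2 < epsilon. Because the spectral radius of W' is at
most 1, the iteration converges for alpha < 1 to the fixed point
(I - alpha W')^-1 (1 - alpha) Y, which :func:`propagate_closed_form`
computes directly (dense; used as an oracle on small networks).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    BINARY,
    CONTINUOUS,
    GeneMatrix,
    GeneSet,
    NormalizedNetwork,
    PriorVector,
    PropagationConfig,
    WeightedNetwork,
)
from .errors import ConvergenceError, ValidationError


def laplacian_normalize(net: WeightedNetwork) -> NormalizedNetwork:
    """Compute W'[i,j] = W[i,j] / sqrt(deg_i * deg_j) on the sorted node order.

    Nodes with zero weighted degree get all-zero rows and columns, so the
    diffusion leaves (1-alpha)*Y on their coordinates.
    """
    nodes = tuple(net.nodes)
    adjacency = nx_to_csr(net, nodes)
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(degrees)
    nonzero = degrees > 0
    inv_sqrt[nonzero] = 1.0 / np.sqrt(degrees[nonzero])
    scaling = sp.diags(inv_sqrt)
    normalized = (scaling @ adjacency @ scaling).tocsr()
    return NormalizedNetwork(nodes=nodes, matrix=normalized)


def nx_to_csr(net: WeightedNetwork, nodes: tuple[str, ...]) -> sp.csr_matrix:
    import networkx as nx

    return nx.to_scipy_sparse_array(net.graph, nodelist=list(nodes), weight="weight", format="csr")


def build_prior(genes: GeneSet, net: WeightedNetwork | NormalizedNetwork) -> PriorVector:
    """Binary prior Y[v] = 1 iff v is both in the gene set and in the network.

    Set members absent from the network are silently excluded; their count is
    recorded on the returned vector. An empty intersection yields an all-zero
    prior with a warning (propagation then returns zeros).
    """
    nodes = tuple(net.nodes) if isinstance(net, WeightedNetwork) else net.nodes
    node_set = set(nodes)
    present = genes.genes & node_set
    excluded = len(genes.genes) - len(present)
    values = np.fromiter((1.0 if n in present else 0.0 for n in nodes), dtype=float, count=len(nodes))
    if not present:
        warnings.warn(
            f"gene set {genes.name!r} has no genes in the network; prior is all-zero",
            stacklevel=2,
        )
    return PriorVector(nodes=nodes, values=values, n_excluded=excluded)


def propagate(net: NormalizedNetwork, prior: PriorVector, cfg: PropagationConfig | None = None) -> PriorVector:
    """Iteratively smooth ``prior`` over the network until the L2 change
    between successive iterates drops below ``cfg.epsilon``."""
    cfg = cfg or PropagationConfig()
    if prior.nodes != net.nodes:
        raise ValidationError("prior node order does not match network node order")
    y = prior.values
    if cfg.alpha == 0.0 or not np.any(y):
        return PriorVector(nodes=net.nodes, values=y.copy(), n_iter=0 if not np.any(y) else 1)
    base = (1.0 - cfg.alpha) * y
    current = y.copy()
    for iteration in range(1, cfg.max_iter + 1):
        nxt = cfg.alpha * (net.matrix @ current) + base
        residual = float(np.linalg.norm(nxt - current))
        current = nxt
        if residual < cfg.epsilon:
            return PriorVector(nodes=net.nodes, values=current, n_iter=iteration)
    raise ConvergenceError("propagation did not converge", residual=residual, n_iter=cfg.max_iter)


def propagate_closed_form(net: NormalizedNetwork, prior: PriorVector, alpha: float) -> PriorVector:
    """Solve (I - alpha W') F = (1 - alpha) Y directly (dense).

    Intended as an exact small-network oracle for :func:`propagate`; cost is
    cubic in |V|.
    """
    if prior.nodes != net.nodes:
        raise ValidationError("prior node order does not match network node order")
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must be in [0,1), got {alpha}")
    n = len(net.nodes)
    system = np.eye(n) - alpha * net.matrix.toarray()
    try:
        solution = np.linalg.solve(system, (1.0 - alpha) * prior.values)
    except np.linalg.LinAlgError as exc:  # cannot occur for alpha < 1
        raise ValidationError(f"singular propagation system: {exc}") from exc
    return PriorVector(nodes=net.nodes, values=solution)


def smooth_matrix(net: NormalizedNetwork, matrix: GeneMatrix, cfg: PropagationConfig | None = None) -> GeneMatrix:
    """Smooth every row of a binary sample x gene matrix over the network.

    Each row, restricted to the network's node set (genes outside V are
    dropped, genes in V but absent from the matrix contribute zero prior), is
    treated as a binary prior and propagated. Output columns are exactly the
    network nodes in node order; rows are preserved. Rows are iterated as one
    batched matrix recurrence; the contract is per-row equivalence with
    :func:`propagate` (up to the convergence tolerance).
    """
    cfg = cfg or PropagationConfig()
    if matrix.dtype_flag != BINARY:
        raise ValidationError("smooth_matrix expects a binary matrix")
    nodes = list(net.nodes)
    priors = matrix.data.reindex(columns=nodes, fill_value=0.0).to_numpy(dtype=float)
    if cfg.alpha == 0.0 or not np.any(priors):
        smoothed = priors
    else:
        base = (1.0 - cfg.alpha) * priors
        current = priors.copy()
        w_t = net.matrix.T  # symmetric, but keep the algebra explicit
        for iteration in range(1, cfg.max_iter + 1):
            nxt = cfg.alpha * (current @ w_t) + base
            # converged when every row satisfies the per-row criterion
            row_residual = float(np.max(np.linalg.norm(nxt - current, axis=1)))
            current = nxt
            if row_residual < cfg.epsilon:
                break
        else:
            raise ConvergenceError(
                "matrix smoothing did not converge", residual=row_residual, n_iter=cfg.max_iter
            )
        smoothed = current
    data = pd.DataFrame(smoothed, index=matrix.data.index, columns=nodes)
    return GeneMatrix(data, dtype_flag=CONTINUOUS)
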