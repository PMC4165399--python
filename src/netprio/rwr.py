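"""Random Walk with Restart (RWR) prioritization from seed node(s).

The walk iterates p_{t+1} = (1 - r) W p_t + r p_0, where r is the restart
probability, W the column-normalized adjacency matrix of the (undirected,
unweighted) network, and p_0 the uniform distribution over the seed nodes.
The stationary vector ranks every node by its proximity/affinity to the
seeds.  Only components containing at least one seed take part in the walk;
nodes elsewhere are excluded with score 0 — this keeps the total probability
over included nodes exactly 1 at every iteration.

A dense closed-form solver, p = r (I - (1-r) W)^{-1} p_0, is provided as an
exact oracle for small graphs, and stationary scores can be binned into the
layer scheme used for candidate triage: the seed is layer A, and a non-seed
node with floor(-log10 score) = b lands in the b-th letter bin (2 -> B,
3 -> C, 4 -> D, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .deg import DEGTable
from .errors import InvalidParameterError, UndefinedMetricError, UnknownGeneError
from .network import PPINetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RWRParams:
    """Restart probability and convergence control for the iterative walk."""

    restart_probability: float = 0.7
    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_probability <= 1.0):
            raise InvalidParameterError(
                f"restart probability must lie in (0, 1], got {self.restart_probability}"
            )
        if self.tolerance <= 0:
            raise InvalidParameterError("tolerance must be positive")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")


@dataclass(frozen=True)
class RWRResult:
    """Stationary probabilities per node plus run metadata."""

    scores: dict[str, float]
    seeds: frozenset[str]
    params: RWRParams
    iterations_used: int
    converged: bool
    excluded_nodes: frozenset[str] = field(default_factory=frozenset)

    def score_series(self) -> pd.Series:
        return pd.Series(self.scores, name="score")

    def write_tsv(self, path, restrict_to=None) -> None:
        frame = rank_table(self, restrict_to=restrict_to)
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def column_normalize(net: PPINetwork) -> tuple[list[str], sparse.csr_matrix, list[str]]:
    """Column-stochastic transition matrix over a fixed node order.

    Returns ``(nodes, W, zero_degree_nodes)`` with W[i, j] = A[i, j]/degree(j);
    columns of degree-0 nodes are all-zero and those nodes are flagged.
    """
    nodes = sorted(net.nodes)
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csc", dtype=float)
    degrees = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.divide(1.0, degrees, out=np.zeros_like(degrees), where=degrees > 0)
    w = (adj @ sparse.diags(inv)).tocsr()
    zero_degree = [n for n, d in zip(nodes, degrees) if d == 0]
    return nodes, w, zero_degree


def _included_component(net: PPINetwork, seeds: frozenset[str]) -> tuple[PPINetwork, set[str]]:
    """Restrict the walk to components containing at least one seed."""
    included: set[str] = set()
    for component in nx.connected_components(net):
        if component & seeds:
            included |= component
    excluded = set(net.nodes) - included
    return net.subgraph(included), excluded


def _check_seeds(net: PPINetwork, seeds) -> frozenset[str]:
    seeds = frozenset(seeds)
    if not seeds:
        raise InvalidParameterError("seed set is empty")
    missing = seeds - set(net.nodes)
    if missing:
        raise UnknownGeneError(f"seed(s) not in network: {sorted(missing)}")
    return seeds


def run_rwr(net: PPINetwork, seeds, params: RWRParams = RWRParams()) -> RWRResult:
    """Iterate the walk from the uniform seed distribution until the L1 change
    drops below the tolerance (geometric convergence with ratio <= 1 - r).
    """
    seeds = _check_seeds(net, seeds)
    walk_net, excluded = _included_component(net, seeds)
    if walk_net.number_of_nodes() == 0:
        raise UndefinedMetricError("no component contains a seed")
    nodes, w, _ = column_normalize(walk_net)
    index = {n: i for i, n in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in seeds]] = 1.0 / len(seeds)

    r = params.restart_probability
    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        p_next = (1.0 - r) * (w @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < params.tolerance:
            converged = True
            break
    if not converged:
        log.warning("RWR did not converge in %d iterations", params.max_iterations)

    scores = {n: float(s) for n, s in zip(nodes, p)}
    scores.update({n: 0.0 for n in excluded})
    return RWRResult(scores, seeds, params, iterations, converged, frozenset(excluded))


def rwr_closed_form(net: PPINetwork, seeds, r: float = 0.7) -> RWRResult:
    """Exact stationary solution p = r (I - (1-r) W)^{-1} p_0.

    Dense solve — intended as an oracle for graphs up to a few hundred nodes.
    Requires r > 0 (the matrix is then invertible because the spectral radius
    of (1-r) W is below 1).
    """
    if not (0.0 < r <= 1.0):
        raise InvalidParameterError(f"restart probability must lie in (0, 1], got {r}")
    seeds = _check_seeds(net, seeds)
    walk_net, excluded = _included_component(net, seeds)
    nodes, w, _ = column_normalize(walk_net)
    index = {n: i for i, n in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in seeds]] = 1.0 / len(seeds)
    system = np.eye(len(nodes)) - (1.0 - r) * w.toarray()
    p = r * np.linalg.solve(system, p0)
    scores = {n: float(s) for n, s in zip(nodes, p)}
    scores.update({n: 0.0 for n in excluded})
    return RWRResult(scores, seeds, RWRParams(restart_probability=r), 0, True,
                     frozenset(excluded))


def assign_layers(result: RWRResult, restrict_to=None) -> dict[str, str]:
    """Bin stationary scores into letter layers.

    Seeds are always layer "A".  A non-seed node with score p gets the layer
    at alphabet position floor(-log10 p): scores with log10 in [-2.99, -2]
    land in "B", [-3.99, -3] in "C", and so on.  Scores above 0.01 clamp to
    "B" with a warning; excluded zero-score nodes are labelled "unreached".
    """
    nodes = set(result.scores) if restrict_to is None else set(restrict_to) & set(result.scores)
    layers: dict[str, str] = {}
    n_clamped = 0
    for node in nodes:
        if node in result.seeds:
            layers[node] = "A"
            continue
        p = result.scores[node]
        if p <= 0.0:
            layers[node] = "unreached"
            continue
        b = math.floor(-math.log10(p))
        if b < 2:
            n_clamped += 1
            b = 2
        layers[node] = chr(ord("A") + min(b, 25) - 1)
    if n_clamped:
        log.warning("%d non-seed node(s) scored above 1e-2; clamped to layer B", n_clamped)
    return layers


def rank_table(result: RWRResult, restrict_to=None) -> pd.DataFrame:
    """Full score table (node, score, log10_score, layer, is_seed), sorted by
    score descending with ties broken by symbol."""
    layers = assign_layers(result, restrict_to=restrict_to)
    rows = []
    for node in sorted(layers):
        score = result.scores[node]
        rows.append((
            node, score,
            math.log10(score) if score > 0 else float("-inf"),
            layers[node], node in result.seeds,
        ))
    frame = pd.DataFrame(rows, columns=["node", "score", "log10_score", "layer", "is_seed"])
    return frame.sort_values(["score", "node"], ascending=[False, True]).reset_index(drop=True)


def rank_genes(result: RWRResult, degs: DEGTable) -> pd.DataFrame:
    """Restrict the ranking to DEG symbols present in the walked network.

    Returns (gene, score, layer, direction) sorted by score descending, ties
    by symbol.  The seed is excluded unless it is itself a DEG.
    """
    directions = degs.directions
    present = [g for g in degs.genes if g in result.scores]
    layers = assign_layers(result, restrict_to=present)
    rows = [(g, result.scores[g], layers[g], directions[g]) for g in present]
    frame = pd.DataFrame(rows, columns=["gene", "score", "layer", "direction"])
    return frame.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)
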