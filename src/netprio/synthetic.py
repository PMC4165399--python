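"""Synthetic data generators for every stage of the pipeline.

Three generators emulate the statistical structure the analysis assumes:

* scale-free undirected PPI networks via preferential attachment
  (Barabási–Albert), which yields connected simple graphs whose degree
  distribution is heavy-tailed — the property the topology stage tests for;
* paired case/control expression profiles with planted up/down-regulated
  genes at configurable fold changes, log-normal baseline intensities
  (mimicking RMA-normalized microarray output) and multiplicative noise
  (additive on the log2 scale, the standard microarray error model);
* random gene-set collections for enrichment testing.

Every generator takes an explicit RNG seed and is bit-reproducible; there is
no hidden global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .deg import ExpressionPair
from .enrichment import GeneSetCollection
from .errors import InvalidParameterError
from .network import PPINetwork, new_network

#: Log2-scale mean/sd of baseline (control) intensities; right-skewed positive
#: values in the range RMA-normalized arrays produce.
CONTROL_LOG2_MEAN = 7.0
CONTROL_LOG2_SD = 1.5


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated expression pair.

    ``planted_fc`` maps every gene to its true case/control ratio (1.0 for
    unperturbed genes, >= 1 for planted up, <= 1 for planted down).
    """

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    planted_fc: dict[str, float]
    network_seed_params: dict

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise InvalidParameterError("planted up and down sets overlap")
        for g in self.planted_up:
            if self.planted_fc[g] < 1:
                raise InvalidParameterError(f"planted-up gene {g} has fc < 1")
        for g in self.planted_down:
            if self.planted_fc[g] > 1:
                raise InvalidParameterError(f"planted-down gene {g} has fc > 1")

    def sensitivity(self, called_up: set[str], called_down: set[str]) -> float:
        """Fraction of planted DEGs recovered with the correct direction."""
        planted = len(self.planted_up) + len(self.planted_down)
        if planted == 0:
            return float("nan")
        hits = len(self.planted_up & called_up) + len(self.planted_down & called_down)
        return hits / planted

    def write_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_up"] = sorted(self.planted_up)
        payload["planted_down"] = sorted(self.planted_down)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _symbol(i: int) -> str:
    return f"G{i + 1:06d}"


def generate_scale_free_network(
    n_nodes: int, edges_per_new_node: int, rng_seed: int
) -> PPINetwork:
    """Preferential-attachment network with synthetic gene symbols.

    Returns a connected, undirected, simple graph on ``n_nodes`` nodes labelled
    ``G000001`` ... whose degree distribution is heavy-tailed.  Deterministic
    given ``rng_seed``.
    """
    if not (n_nodes > edges_per_new_node >= 1):
        raise InvalidParameterError(
            f"need n_nodes > edges_per_new_node >= 1, got {n_nodes}, {edges_per_new_node}"
        )
    ba = nx.barabasi_albert_graph(n_nodes, edges_per_new_node, seed=int(rng_seed))
    net = new_network(
        ((_symbol(a), _symbol(b)) for a, b in ba.edges),
        nodes=(_symbol(i) for i in range(n_nodes)),
        provenance=[f"synthetic-ba(n={n_nodes},m={edges_per_new_node},seed={rng_seed})"],
    )
    return net


def generate_expression_pair(
    network: PPINetwork,
    n_up: int,
    n_down: int,
    fc_low: float,
    fc_high: float,
    noise_sd: float,
    rng_seed: int,
    labels: tuple[str, str] = ("control", "case"),
) -> tuple[ExpressionPair, SyntheticTruth]:
    """Case/control profiles over the network's gene universe with planted DEGs.

    Control intensities are log-normal (log2 mean 7, sd 1.5).  Planted-up
    genes get a true fold change uniform in [fc_low, fc_high]; planted-down
    genes the reciprocal.  Case = control x fold change x 2**eps with
    eps ~ Normal(0, noise_sd), i.e. multiplicative noise on the linear scale.
    The gene universe equals the network node set, so every DEG is mappable.
    """
    genes = sorted(network.nodes)
    n = len(genes)
    if n_up < 0 or n_down < 0:
        raise InvalidParameterError("n_up and n_down must be non-negative")
    if n_up + n_down > n:
        raise InvalidParameterError(
            f"n_up + n_down = {n_up + n_down} exceeds the {n}-gene universe"
        )
    if not (fc_high >= fc_low > 1):
        raise InvalidParameterError("need fc_high >= fc_low > 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")

    rng = np.random.default_rng(int(rng_seed))
    control = 2.0 ** rng.normal(CONTROL_LOG2_MEAN, CONTROL_LOG2_SD, size=n)

    chosen = rng.choice(n, size=n_up + n_down, replace=False)
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]
    fc = np.ones(n)
    fc[up_idx] = rng.uniform(fc_low, fc_high, size=n_up)
    fc[down_idx] = 1.0 / rng.uniform(fc_low, fc_high, size=n_down)

    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    case = control * fc * 2.0 ** eps

    pair = ExpressionPair(tuple(genes), control, case, labels)
    truth = SyntheticTruth(
        planted_up=frozenset(genes[i] for i in up_idx),
        planted_down=frozenset(genes[i] for i in down_idx),
        planted_fc={g: float(f) for g, f in zip(genes, fc)},
        network_seed_params={
            "provenance": list(network.graph.get("provenance", [])),
            "rng_seed": int(rng_seed),
            "n_up": n_up,
            "n_down": n_down,
            "fc_low": fc_low,
            "fc_high": fc_high,
            "noise_sd": noise_sd,
        },
    )
    return pair, truth


def generate_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    size_low: int,
    size_high: int,
    rng_seed: int,
    category: str = "synthetic",
) -> GeneSetCollection:
    """Uniformly sampled gene subsets with sizes uniform in [size_low, size_high]."""
    universe = list(universe)
    if not universe:
        raise InvalidParameterError("gene universe is empty")
    if not (1 <= size_low <= size_high <= len(universe)):
        raise InvalidParameterError(
            f"need 1 <= size_low <= size_high <= |universe|, got "
            f"{size_low}, {size_high}, {len(universe)}"
        )
    if n_sets < 0:
        raise InvalidParameterError("n_sets must be >= 0")
    rng = np.random.default_rng(int(rng_seed))
    width = len(str(max(n_sets, 1)))
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_low, size_high + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{i + 1:0{width}d}"] = (
            category,
            frozenset(universe[j] for j in members),
        )
    return GeneSetCollection(sets=sets, background=frozenset(universe))
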