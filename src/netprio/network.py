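"""Reading, integrating and writing protein-protein interaction networks.

A PPI network is represented as an undirected simple :class:`networkx.Graph`
whose nodes are uppercase gene/protein symbols.  Source names are accumulated
in ``graph.graph["provenance"]`` (a list of strings).  Self-loops and duplicate
unordered pairs are removed when files are read, so every graph handled by the
rest of the package is simple by construction.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import InputFormatError

log = logging.getLogger(__name__)

#: Alias used throughout the package: an undirected simple graph over symbols.
PPINetwork = nx.Graph

_DIALECTS = ("generic-tsv", "biogrid-tab", "hprd-flat")

# Header names BioGRID uses for the two official gene symbol columns.
_BIOGRID_SYMBOL_HEADERS = (
    "official symbol interactor a",
    "official symbol interactor b",
)


def new_network(
    edges: Iterable[tuple[str, str]] = (),
    nodes: Iterable[str] = (),
    provenance: Sequence[str] = (),
) -> PPINetwork:
    """Build a simple undirected network from symbol pairs.

    Symbols are uppercased and stripped; self-loops and duplicate unordered
    pairs are dropped silently.
    """
    g = nx.Graph(provenance=list(provenance))
    for node in nodes:
        g.add_node(_clean(node))
    for a, b in edges:
        a, b = _clean(a), _clean(b)
        if a and b and a != b:
            g.add_edge(a, b)
    return g


def _clean(symbol: str) -> str:
    return symbol.strip().upper()


def _parse_generic(lines: list[list[str]], header: list[str] | None) -> list[tuple[str, str]]:
    pairs = []
    rows = lines if header is None else lines
    for row in rows:
        if len(row) < 2:
            raise InputFormatError(
                f"generic-tsv rows need at least 2 columns, got {len(row)}: {row!r}"
            )
        pairs.append((row[0], row[1]))
    return pairs


def read_edge_list(
    path: str | Path,
    dialect: str = "generic-tsv",
    symbol_columns: tuple[int, int] | tuple[str, str] | None = None,
) -> PPINetwork:
    """Read a PPI edge list in one of three dialects.

    Parameters
    ----------
    path
        Tab-separated file.  Lines starting with ``#`` are comments.
    dialect
        ``generic-tsv`` — first two columns are symbols, no header required;
        ``biogrid-tab`` — header row present, the two official-symbol columns
        are located by name (or by ``symbol_columns`` given as header names);
        ``hprd-flat`` — positional columns, defaulting to (0, 3) which matches
        the HPRD flat-file layout (symbol, id, id, symbol), overridable via
        ``symbol_columns`` as integer indices.

    Returns
    -------
    PPINetwork
        Uppercased, deduplicated simple graph.  Dropped-row counts are logged.
    """
    if dialect not in _DIALECTS:
        raise InputFormatError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    raw_rows: list[list[str]] = []
    with path.open() as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                # BioGRID conventionally prefixes its header row with '#'
                if not (dialect == "biogrid-tab" and i == 0):
                    continue
                line = line.lstrip().lstrip("#")
            raw_rows.append(line.split("\t") if "\t" in line else line.split())
    if not raw_rows:
        log.warning("empty edge-list file %s -> empty network", path)
        return new_network(provenance=[path.name])

    if dialect == "generic-tsv":
        idx_a, idx_b = 0, 1
        data_rows = raw_rows
    elif dialect == "biogrid-tab":
        header = [h.strip().lower().lstrip("#") for h in raw_rows[0]]
        wanted = (
            tuple(str(c).strip().lower() for c in symbol_columns)
            if symbol_columns is not None
            else _BIOGRID_SYMBOL_HEADERS
        )
        try:
            idx_a, idx_b = header.index(wanted[0]), header.index(wanted[1])
        except ValueError:
            raise InputFormatError(
                f"biogrid-tab file {path} lacks symbol columns {wanted!r}; header was {header!r}"
            ) from None
        data_rows = raw_rows[1:]
    else:  # hprd-flat
        if symbol_columns is None:
            idx_a, idx_b = 0, 3
        else:
            idx_a, idx_b = int(symbol_columns[0]), int(symbol_columns[1])
        data_rows = raw_rows

    pairs: list[tuple[str, str]] = []
    n_short = n_empty = 0
    for row in data_rows:
        if len(row) <= max(idx_a, idx_b):
            n_short += 1
            continue
        a, b = _clean(row[idx_a]), _clean(row[idx_b])
        if not a or not b:
            n_empty += 1
            continue
        pairs.append((a, b))

    g = new_network(pairs, provenance=[path.name])
    n_self = sum(1 for a, b in pairs if a == b)
    n_dup = len(pairs) - n_self - g.number_of_edges()
    log.info(
        "%s (%s): %d rows -> %d edges (%d short, %d empty-symbol, %d self-loop, %d duplicate)",
        path.name, dialect, len(data_rows), g.number_of_edges(),
        n_short, n_empty, n_self, n_dup,
    )
    return g


def integrate(networks: Sequence[PPINetwork]) -> PPINetwork:
    """Union several PPI networks, removing redundant interactions.

    The node set is the union of node sets and the edge set the union of
    unordered edge sets, so the operation is commutative, associative and
    idempotent.  Provenance lists are concatenated.
    """
    if not networks:
        raise InputFormatError("integrate requires at least one network")
    merged = nx.Graph(
        provenance=[p for n in networks for p in n.graph.get("provenance", [])]
    )
    for net in networks:
        merged.add_nodes_from(net.nodes)
        merged.add_edges_from(net.edges)
    return merged


def summarize(network: PPINetwork) -> dict[str, int]:
    """Exact counts of nodes, edges, connected components and isolated nodes."""
    return {
        "nodes": network.number_of_nodes(),
        "edges": network.number_of_edges(),
        "components": nx.number_connected_components(network) if network else 0,
        "isolated_nodes": sum(1 for n in network if network.degree(n) == 0),
    }


def apply_alias_map(network: PPINetwork, aliases: dict[str, str]) -> PPINetwork:
    """Relabel nodes through a symbol alias map (old -> new), re-simplifying."""
    cleaned = {_clean(k): _clean(v) for k, v in aliases.items()}
    return new_network(
        ((cleaned.get(a, a), cleaned.get(b, b)) for a, b in network.edges),
        nodes=(cleaned.get(n, n) for n in network.nodes),
        provenance=network.graph.get("provenance", []),
    )


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    """Write the canonical two-column TSV edge list (sorted, deterministic)."""
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{b}\n")


def write_sif(network: PPINetwork, path: str | Path, relation: str = "pp") -> None:
    """Write a Cytoscape SIF file; isolated nodes get a bare-node line."""
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(network.nodes):
            if network.degree(n) == 0:
                fh.write(f"{n}\n")


def write_graphml(network: PPINetwork, path: str | Path) -> None:
    g = network.copy()
    g.graph["provenance"] = ";".join(g.graph.get("provenance", []))
    nx.write_graphml(g, str(path))
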