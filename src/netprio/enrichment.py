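"""Functional-annotation-chart enrichment of a gene list against gene sets.

A gene list is tested against every set of a GMT collection with the
one-sided hypergeometric (Fisher exact) upper-tail test, or DAVID's more
conservative EASE variant (one overlap gene removed).  Significant terms can
be connected into an Enrichment-Map-style term graph whose edges carry the
overlap coefficient |A∩B| / min(|A|,|B|), and two charts can be compared into
shared/unique term partitions.

No multiple-testing correction is applied by default — the chart filter is a
raw P < alpha cut (strict inequality); Benjamini–Hochberg is available as an
option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputFormatError, InvalidInputError, UnknownGeneError

log = logging.getLogger(__name__)

CHART_COLUMNS = ["term", "category", "k", "n", "K", "N", "p_value", "fold_enrichment"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: term -> (category label, member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise InvalidInputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term: str) -> frozenset[str]:
        try:
            return self.sets[term][1]
        except KeyError:
            raise UnknownGeneError(f"unknown term {term!r}") from None

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term overlap counts and p-values for one gene list."""

    frame: pd.DataFrame  # CHART_COLUMNS
    method: str = "fisher"
    background: frozenset[str] = field(default_factory=frozenset)

    @property
    def terms(self) -> set[str]:
        return set(self.frame["term"])

    def __len__(self) -> int:
        return len(self.frame)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, term name, description/category, members."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, category = fields[0], fields[1]
            if name in sets:
                raise InputFormatError(f"{path}:{lineno}: duplicate term {name!r}")
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise InputFormatError(f"{path}:{lineno}: term {name!r} has no members")
            sets[name] = (category, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.sets):
            category, members = collection.sets[name]
            fh.write("\t".join([name, category, *sorted(members)]) + "\n")


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); exactly 1.0 when k <= 0."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def annotation_chart(
    genes: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    method: str = "fisher",
) -> EnrichmentResult:
    """Functional annotation chart of a gene list across all collection sets.

    For each term with overlap k > 0 reports the one-sided hypergeometric
    upper-tail p-value P(X >= k) (``fisher``) or P(X >= k-1) (``ease``,
    DAVID's conservative score), plus the fold enrichment (k/n)/(K/N).
    Gene lists and sets are intersected with the background first; genes
    outside the background are dropped with a log message.
    """
    if method not in ("fisher", "ease"):
        raise InvalidInputError(f"method must be 'fisher' or 'ease', got {method!r}")
    background = frozenset(background)
    if not background:
        raise InvalidInputError("background universe is empty")
    genes = frozenset(genes)
    dropped = genes - background
    if dropped:
        log.info("dropping %d query genes outside the background", len(dropped))
    genes &= background

    N, n = len(background), len(genes)
    rows = []
    for term in sorted(collection.sets):
        category, members = collection.sets[term]
        members = members & background
        K = len(members)
        k = len(genes & members)
        if k == 0 or K == 0:
            continue
        k_eff = k if method == "fisher" else max(k - 1, 0)
        p = hypergeom_tail(k_eff, n, K, N)
        fold = (k / n) / (K / N) if n else float("nan")
        rows.append((term, category, k, n, K, N, p, fold))
    frame = pd.DataFrame(rows, columns=CHART_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["p_value", "term"]).reset_index(drop=True)
    return EnrichmentResult(frame=frame, method=method, background=background)


def filter_significant(result: EnrichmentResult, alpha: float = 0.05,
                       correct: bool = False) -> EnrichmentResult:
    """Keep rows with p < alpha (strict).  ``correct`` applies BH first."""
    frame = result.frame.copy()
    if correct and len(frame):
        p = frame["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        frame["p_adjusted"] = adj
        keep = frame["p_adjusted"] < alpha
    else:
        keep = frame["p_value"] < alpha
    return EnrichmentResult(frame=frame[keep].reset_index(drop=True),
                            method=result.method, background=result.background)


def overlap_coefficient(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A ∩ B| / min(|A|, |B|); undefined (error) for an empty set."""
    a, b = frozenset(set_a), frozenset(set_b)
    if not a or not b:
        raise InvalidInputError("overlap coefficient undefined for an empty set")
    return len(a & b) / min(len(a), len(b))


def enrichment_map_edges(
    result: EnrichmentResult,
    collection: GeneSetCollection,
    cutoff: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrichment-Map term graph tables from a (pre-filtered) chart.

    Returns ``(edges, nodes)``: edges are all unordered term pairs whose
    overlap coefficient reaches ``cutoff``; nodes carry -log10 p as the size
    attribute (more significant terms draw larger).
    """
    terms = sorted(result.terms)
    for term in terms:
        if term not in collection.sets:
            raise UnknownGeneError(f"term {term!r} missing from the collection")
    members = {t: collection.sets[t][1] for t in terms}
    edge_rows = []
    for i, ta in enumerate(terms):
        for tb in terms[i + 1:]:
            coef = overlap_coefficient(members[ta], members[tb])
            if coef >= cutoff:
                edge_rows.append((ta, tb, coef))
    edges = pd.DataFrame(edge_rows, columns=["term_a", "term_b", "overlap_coefficient"])
    nodes = result.frame[["term", "category", "p_value"]].copy()
    nodes["neg_log10_p"] = -np.log10(nodes["p_value"])
    return edges, nodes


def compare_charts(
    chart_a: EnrichmentResult, chart_b: EnrichmentResult
) -> tuple[set[str], set[str], set[str]]:
    """Three-way partition of term names: (unique to a, unique to b, shared)."""
    a, b = chart_a.terms, chart_b.terms
    return a - b, b - a, a & b
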