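"""Protein–protein interaction graph handling.

Reads BioGRID-style tab-delimited edge lists into an undirected simple
graph restricted to its largest connected component, and builds the
normalized linear operators used by network propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: default column names for fixture edge lists
DEFAULT_COLUMNS = ("symbol_a", "symbol_b")
#: column names of a BioGRID TAB3 export
BIOGRID_COLUMNS = ("Official Symbol Interactor A", "Official Symbol Interactor B")


class Interactome:
    """Undirected simple graph over gene symbols.

    Node order is deterministic (lexicographic); the graph is expected to
    be connected when built through :func:`read_edge_list` or the synthetic
    generator.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise InputError("interactome graph is empty")
        self._graph = graph
        self._nodes: tuple[str, ...] = tuple(sorted(graph.nodes))
        self._index = {s: i for i, s in enumerate(self._nodes)}

    # -- basic accessors ---------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def node_index(self) -> dict[str, int]:
        return self._index

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted unordered pairs, lexicographically ordered."""
        return sorted(tuple(sorted(e)) for e in self._graph.edges)

    def degree(self, symbol: str) -> int:
        return self._graph.degree[symbol]

    def neighbors(self, symbol: str) -> list[str]:
        return sorted(self._graph.neighbors(symbol))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def has_edge(self, a: str, b: str) -> bool:
        return self._graph.has_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        """Add an undirected edge between two existing nodes (no self-loops)."""
        if a == b:
            raise ValidationError("self-loops are not allowed")
        if a not in self._index or b not in self._index:
            raise ValidationError(f"unknown node in edge ({a}, {b})")
        self._graph.add_edge(a, b)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Interactome":
        """Build from raw symbol pairs: uppercase, drop self-loops and
        duplicate/reversed-duplicate edges, restrict to the largest
        connected component."""
        g = nx.Graph()
        n_self = 0
        n_dup = 0
        for a, b in edges:
            a = str(a).strip().upper()
            b = str(b).strip().upper()
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
        if g.number_of_nodes() == 0:
            raise InputError("no usable edges: graph is empty")
        components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        removed_nodes = g.number_of_nodes() - len(components[0])
        g = g.subgraph(components[0]).copy()
        logger.info(
            "interactome: %d nodes, %d edges (dropped %d self-loops, %d duplicates, "
            "%d nodes outside the largest component)",
            g.number_of_nodes(), g.number_of_edges(), n_self, n_dup, removed_nodes,
        )
        return cls(g)


def read_edge_list(
    path: str | Path,
    column_map: Sequence[str] | None = None,
) -> Interactome:
    """Read a tab-delimited edge list into an :class:`Interactome`.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    column_map:
        Pair of column names holding the two interactor symbols. Defaults
        to the fixture dialect ``("symbol_a", "symbol_b")``; pass
        :data:`BIOGRID_COLUMNS` for BioGRID TAB3 exports.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge list not found: {path}")
    cols = tuple(column_map) if column_map is not None else DEFAULT_COLUMNS
    if len(cols) != 2:
        raise ValidationError("column_map must name exactly two columns")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"edge list {path} is missing columns: {missing}")
    return Interactome.from_edges(zip(df[cols[0]], df[cols[1]]))


@dataclass(frozen=True)
class PropagationOperator:
    """Normalized adjacency operator aligned with an interactome's node order.

    ``column-stochastic`` is A·D⁻¹ (every column sums to 1, so diffusion
    conserves mass); ``symmetric-degree`` is D^(−1/2)·A·D^(−1/2) (symmetric,
    spectral radius ≤ 1).
    """

    matrix: sparse.csr_matrix = field(repr=False)
    mode: str
    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)


OPERATOR_MODES = ("column-stochastic", "symmetric-degree")


def build_operator(net: Interactome, mode: str = "column-stochastic") -> PropagationOperator:
    """Build the propagation operator for a connected interactome."""
    if mode not in OPERATOR_MODES:
        raise ValidationError(f"unknown normalization mode: {mode!r}")
    adj = nx.adjacency_matrix(net.graph, nodelist=net.nodes).astype(float)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(deg == 0):
        raise ValidationError("operator undefined: graph has an isolated node")
    if mode == "column-stochastic":
        mat = adj @ sparse.diags(1.0 / deg)
    else:
        half = sparse.diags(1.0 / np.sqrt(deg))
        mat = half @ adj @ half
    return PropagationOperator(matrix=mat.tocsr(), mode=mode, nodes=net.nodes)
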