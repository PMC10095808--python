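"""Directed-network node importance and overlap enrichment.

A node's weight grows linearly with its outdegree, from 1 (no targets) to 2
(the maximal outdegree in the network).  Its impact combines the weights of
its first neighbours: the outgoing-neighbour sum is scaled by the node's
average shortest path length (ASPL) over the nodes it can reach, and the
incoming-neighbour sum by the network's end-node proportion R (the fraction
of nodes with no outgoing edge)::

    impact(i) = ASPL(i) * sum_{j in succ(i)} w(j) + R * sum_{j in pred(i)} w(j)

Genes with many cascading targets two or more edges away get a higher ASPL
and thus a higher scaled outgoing term; in a network rich in end-nodes the
incoming term contributes more.  Overlap of two gene sets against a common
background is tested with the upper-tail (exact) hypergeometric probability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, InvalidContingencyError

__all__ = [
    "GeneNetwork",
    "EnrichmentResult",
    "node_weights",
    "end_node_proportion",
    "average_shortest_path_length",
    "node_impact",
    "hypergeometric_enrichment",
]

EDGE_SIGNS = ("activation", "repression", "undetermined")

# Cytoscape edge "name" column convention: "source (interaction) target"
_CYTOSCAPE_EDGE_RE = re.compile(r"^\s*(?P<source>.+?)\s*\((?P<interaction>[^)]*)\)\s*(?P<target>.+?)\s*$")


class GeneNetwork:
    """Directed signed gene network backed by a :class:`networkx.DiGraph`.

    Edge signs (activation / repression / undetermined) are carried as edge
    attributes but do not enter the weight or impact statistics, which
    depend only on degrees and path lengths.  Nodes may carry an optional
    ``log2FC`` annotation.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "GeneNetwork":
        """Build from ``(source, sign, target)`` triples (plus isolated nodes)."""
        g = nx.DiGraph()
        if nodes is not None:
            for n in nodes:
                g.add_node(str(n))
        for source, sign, target in edges:
            if sign not in EDGE_SIGNS:
                raise ConfigurationError(
                    f"edge sign {sign!r} not in {EDGE_SIGNS}"
                )
            g.add_edge(str(source), str(target), sign=sign)
        return cls(g)

    @classmethod
    def from_cytoscape_tables(
        cls, node_table: pd.DataFrame, edge_table: pd.DataFrame
    ) -> "GeneNetwork":
        """Parse Cytoscape "Table to File" exports.

        The node table needs a ``name`` column (optional ``log2FC``); the
        edge table either explicit ``source, interaction, target`` columns or
        a ``name`` column in the ``source (interaction) target`` convention.
        """
        g = nx.DiGraph()
        if "name" not in node_table.columns:
            raise ConfigurationError("node table needs a 'name' column")
        has_fc = "log2FC" in node_table.columns
        for i in node_table.index:
            attrs = {}
            if has_fc and pd.notna(node_table.at[i, "log2FC"]):
                attrs["log2FC"] = float(node_table.at[i, "log2FC"])
            g.add_node(str(node_table.at[i, "name"]), **attrs)
        cols = set(edge_table.columns)
        if {"source", "target"}.issubset(cols):
            for row in edge_table.itertuples():
                sign = getattr(row, "interaction", "undetermined")
                g.add_edge(str(row.source), str(row.target), sign=_normalise_sign(sign))
        elif "name" in cols:
            for value in edge_table["name"]:
                m = _CYTOSCAPE_EDGE_RE.match(str(value))
                if not m:
                    raise ConfigurationError(
                        f"cannot parse Cytoscape edge name {value!r}"
                    )
                g.add_edge(
                    m.group("source"),
                    m.group("target"),
                    sign=_normalise_sign(m.group("interaction")),
                )
        else:
            raise ConfigurationError(
                "edge table needs 'source'/'target' columns or a 'name' column"
            )
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def _normalise_sign(sign) -> str:
    s = str(sign).strip().lower()
    if s in EDGE_SIGNS:
        return s
    return "undetermined"


def node_weights(g: GeneNetwork) -> dict[str, float]:
    """Outdegree-proportional node weights in [1, 2].

    ``w(i) = 1 + O(i) / max_j O(j)`` (all 1 when the network has no edges);
    the node(s) with maximal outdegree get weight 2, end-nodes weight 1.
    """
    out = dict(g.graph.out_degree())
    if not out:
        return {}
    o_max = max(out.values())
    if o_max == 0:
        return {n: 1.0 for n in out}
    return {n: 1.0 + o / o_max for n, o in out.items()}


def end_node_proportion(g: GeneNetwork) -> float:
    """Fraction R of nodes with no outgoing edge."""
    n = len(g)
    if n == 0:
        raise ConfigurationError("network has no nodes")
    ends = sum(1 for _, o in g.graph.out_degree() if o == 0)
    return ends / n


def average_shortest_path_length(g: GeneNetwork, node) -> float:
    """Mean directed shortest-path length from ``node`` to its reachable nodes.

    Unreachable nodes are excluded from the mean (keeping ASPL finite on
    DAG-like regulatory networks); a node reaching nothing has ASPL 0.
    """
    lengths = nx.single_source_shortest_path_length(g.graph, node)
    lengths.pop(node, None)
    if not lengths:
        return 0.0
    return sum(lengths.values()) / len(lengths)


def node_impact(g: GeneNetwork) -> pd.DataFrame:
    """Impact table of every node, ordered by impact descending.

    Columns ``node, weight, impact, outdegree, indegree``; ties are broken
    lexicographically by node id.
    """
    w = node_weights(g)
    if not w:
        return pd.DataFrame(columns=["node", "weight", "impact", "outdegree", "indegree"])
    r = end_node_proportion(g)
    rows = []
    for n in g.graph.nodes:
        aspl = average_shortest_path_length(g, n)
        out_sum = sum(w[j] for j in g.graph.successors(n))
        in_sum = sum(w[j] for j in g.graph.predecessors(n))
        rows.append(
            {
                "node": n,
                "weight": w[n],
                "impact": aspl * out_sum + r * in_sum,
                "outdegree": g.graph.out_degree(n),
                "indegree": g.graph.in_degree(n),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["impact", "node"], ascending=[False, True], ignore_index=True
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of two gene sets against a common background."""

    n_a: int
    n_b: int
    overlap: int
    background: int
    fold: float
    p_value: float


def hypergeometric_enrichment(
    n_a: int, n_b: int, overlap: int, background: int
) -> EnrichmentResult:
    """Fold enrichment and exact upper-tail hypergeometric probability.

    ``fold = k / (nA * nB / N)`` compares the observed overlap ``k`` with
    its expectation under independent draws; ``p = P[X >= k]`` for
    ``X ~ Hypergeometric(N, nA, nB)``.
    """
    n_a, n_b, overlap, background = map(int, (n_a, n_b, overlap, background))
    if min(n_a, n_b, overlap, background) < 0:
        raise InvalidContingencyError("counts must be >= 0")
    if overlap > min(n_a, n_b) or max(n_a, n_b) > background:
        raise InvalidContingencyError(
            f"inconsistent counts: k={overlap}, nA={n_a}, nB={n_b}, N={background}"
        )
    if n_a == 0 or n_b == 0:
        raise InvalidContingencyError("set sizes must be > 0 for an enrichment")
    expected = n_a * n_b / background
    fold = overlap / expected
    p = float(hypergeom.sf(overlap - 1, background, n_a, n_b))
    return EnrichmentResult(
        n_a=n_a, n_b=n_b, overlap=overlap, background=background, fold=fold, p_value=p
    )
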