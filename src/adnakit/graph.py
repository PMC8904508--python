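"""Admixture graphs: rooted DAGs with drift lengths and mixing weights.

Nodes are population labels. Ordinary nodes have a single parent reached by
a drift edge of length ``c >= 0`` (in f2 units once scaled by the root
heterozygosity). Admixture nodes have exactly two parents and a mixing
weight ``alpha`` giving the fraction inherited from the first parent; the
mixture itself is instantaneous, drift accrues only on drift edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["AdmixtureGraph", "GraphError"]


class GraphError(ValueError):
    """Raised for cyclic, multi-rooted, or otherwise malformed graphs."""


@dataclass
class AdmixtureGraph:
    """Directed acyclic admixture graph.

    Parameters
    ----------
    edges : list of (parent, child, c)
        Drift edges with drift length ``c >= 0``.
    admixtures : dict
        ``child -> (parentA, parentB, alpha)`` with ``0 <= alpha <= 1``;
        the child's frequency is ``alpha*pA + (1-alpha)*pB``.
    """

    edges: list[tuple[str, str, float]]
    admixtures: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.edges = [(str(p), str(c), float(d)) for p, c, d in self.edges]
        for p, c, d in self.edges:
            if d < 0:
                raise GraphError(f"negative drift on edge {p}->{c}")
        for child, (pa, pb, alpha) in self.admixtures.items():
            if not 0.0 <= alpha <= 1.0:
                raise GraphError(f"alpha outside [0,1] at {child}")
        g = self._digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("graph contains a cycle")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise GraphError(f"expected exactly one root, found {roots}")
        self._root = roots[0]
        for n in g.nodes:
            indeg = g.in_degree(n)
            if n == self._root:
                continue
            if n in self.admixtures:
                if indeg != 2:
                    raise GraphError(f"admixture node {n} must have 2 parents")
            elif indeg != 1:
                raise GraphError(f"node {n} has {indeg} parents")

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for p, c, d in self.edges:
            g.add_edge(p, c, c=d)
        for child, (pa, pb, alpha) in self.admixtures.items():
            g.add_edge(pa, child)
            g.add_edge(pb, child)
        return g

    @property
    def root(self) -> str:
        return self._root

    @property
    def nodes(self) -> list[str]:
        return list(nx.topological_sort(self._digraph()))

    @property
    def leaves(self) -> list[str]:
        g = self._digraph()
        return sorted(n for n in g.nodes if g.out_degree(n) == 0)

    def drift_parent(self, node: str) -> tuple[str, float] | None:
        for p, c, d in self.edges:
            if c == node:
                return p, d
        return None

    def topological_order(self) -> list[str]:
        return self.nodes

    # --- ancestry weights -------------------------------------------------

    def leaf_paths(self, leaf: str) -> list[tuple[float, list[tuple[str, str]]]]:
        """All root-to-leaf lineages as (probability, [drift edges]).

        Each admixture node on the way splits the lineage with weights
        (alpha, 1-alpha); the returned probabilities sum to 1.
        """
        out = []

        def walk(node, prob, edges_acc):
            if node == self._root:
                out.append((prob, list(edges_acc)))
                return
            if node in self.admixtures:
                pa, pb, alpha = self.admixtures[node]
                if alpha > 0:
                    walk(pa, prob * alpha, edges_acc)
                if alpha < 1:
                    walk(pb, prob * (1 - alpha), edges_acc)
            else:
                parent, _ = self.drift_parent(node)
                walk(parent, prob, edges_acc + [(parent, node)])

        walk(leaf, 1.0, [])
        return out

    def edge_usage(self, leaf: str) -> dict[tuple[str, str], float]:
        """Probability that the lineage of ``leaf`` traverses each drift edge."""
        usage: dict[tuple[str, str], float] = {}
        for prob, edges in self.leaf_paths(leaf):
            for e in edges:
                usage[e] = usage.get(e, 0.0) + prob
        return usage

    # --- text round trip --------------------------------------------------

    def to_text(self) -> str:
        """Edge-list text: ``edge parent child c`` / ``admix child pA pB alpha``."""
        lines = [f"edge\t{p}\t{c}\t{d:.10g}" for p, c, d in self.edges]
        lines += [
            f"admix\t{child}\t{pa}\t{pb}\t{alpha:.10g}"
            for child, (pa, pb, alpha) in sorted(self.admixtures.items())
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AdmixtureGraph":
        edges, admix = [], {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "edge":
                edges.append((parts[1], parts[2], float(parts[3])))
            elif parts[0] == "admix":
                admix[parts[1]] = (parts[2], parts[3], float(parts[4]))
            else:
                raise GraphError(f"unrecognized graph line: {line!r}")
        return cls(edges, admix)

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for p, c, d in self.edges:
            lines.append(f'  "{p}" -> "{c}" [label="{d:.4g}"];')
        for child, (pa, pb, alpha) in self.admixtures.items():
            lines.append(f'  "{pa}" -> "{child}" [style=dashed, label="{alpha:.2f}"];')
            lines.append(
                f'  "{pb}" -> "{child}" [style=dashed, label="{1 - alpha:.2f}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
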