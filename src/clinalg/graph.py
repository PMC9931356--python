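"""Display-condition dependency graph of an algorithm's nodes.

Vertices are node ids; an edge ``u -> v`` means node v's display
condition references node u (v can only become askable after u is
resolved).  The graph must be acyclic for the staged questioning order
to exist.
"""

from __future__ import annotations

import networkx as nx

from .model import ClinicalAlgorithm


class CycleError(ValueError):
    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("display-condition cycle: " + " -> ".join(cycle))


def dependency_graph(alg: ClinicalAlgorithm) -> nx.DiGraph:
    """Directed graph of display-condition references between nodes.

    Raises :class:`CycleError` (listing the cycle path) if the references
    are circular.
    """
    g = build_graph(alg)
    cycle = _cycle_path(g)
    if cycle:
        raise CycleError(cycle)
    return g


def build_graph(alg: ClinicalAlgorithm) -> nx.DiGraph:
    """The reference graph without the acyclicity check."""
    g = nx.DiGraph()
    g.add_nodes_from(alg.nodes)
    for node in alg.nodes.values():
        if node.display_condition is None:
            continue
        for dep in sorted(node.display_condition.node_ids()):
            if dep in alg.nodes:
                g.add_edge(dep, node.id)
    return g


def _cycle_path(g: nx.DiGraph) -> list[str] | None:
    try:
        edges = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        return None
    path = [e[0] for e in edges]
    path.append(edges[-1][1])
    return path


def find_cycle(alg: ClinicalAlgorithm) -> list[str] | None:
    """The first display-dependency cycle as a node-id path, or None."""
    return _cycle_path(build_graph(alg))


def topological_index(alg: ClinicalAlgorithm) -> dict[str, int]:
    """Stable topological position of every node.

    Ties are broken by authoring order, so the index is deterministic for
    a given document.  Raises :class:`CycleError` on circular references.
    """
    g = build_graph(alg)
    cycle = _cycle_path(g)
    if cycle:
        raise CycleError(cycle)
    authoring = {nid: i for i, nid in enumerate(alg.nodes)}
    order = nx.lexicographical_topological_sort(g, key=lambda n: authoring[n])
    return {nid: i for i, nid in enumerate(order)}
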