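"""Fragment-similarity networks over hit lists.

Nodes are domain-fragment clusters (``<domain_id>_<cluster>`` — the same
domain can appear as two nodes when different regions of its sequence carry
different shared fragments) and an edge joins two nodes whenever at least one
hit links them.  Parallel and reciprocal hits between the same node pair
collapse into a single unweighted edge whose multiplicity is recorded.
Connected components then group domains around one fragment type.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .hits import Hit

__all__ = [
    "SimilarityNetwork",
    "build_network",
    "components",
    "hubs",
    "summarize",
    "write_graphml",
    "write_dot",
]


@dataclass
class SimilarityNetwork:
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def multiplicity(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["multiplicity"]


def build_network(hits: list[Hit], collapse_clusters: bool = False) -> SimilarityNetwork:
    """Build the similarity network for a hit list.

    One node per distinct (domain, cluster) pair occurring on either side of
    any hit; one edge per connected node pair, with hit multiplicity stored
    as an edge attribute.  ``collapse_clusters=True`` merges all cluster tags
    of a domain into one bare-domain node (non-default; the cluster-tagged
    identity is what distinguishes two fragment occurrences in one domain).
    """
    g = nx.Graph()
    for h in hits:
        if collapse_clusters:
            u, v = h.query_id, h.subject_id
        else:
            u, v = h.node_id("query"), h.node_id("subject")
        if u == v:
            continue
        for node, scop in ((u, h.q_scop), (v, h.s_scop)):
            if node not in g:
                g.add_node(node, scop=scop, fold=".".join(scop.split(".")[:2]))
        if g.has_edge(u, v):
            g.edges[u, v]["multiplicity"] += 1
            g.edges[u, v]["hits"].append(h)
        else:
            g.add_edge(u, v, multiplicity=1, hits=[h])
    return SimilarityNetwork(g)


def components(net: SimilarityNetwork) -> list[set[str]]:
    """Connected components, largest first, ties broken by smallest node id."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def hubs(net: SimilarityNetwork, k: int) -> list[str]:
    """The ``k`` most connected nodes (degree on collapsed edges), degree
    ties broken by node id.  Asks for more nodes than exist → returns all."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(net.graph.nodes, key=lambda n: (-net.graph.degree[n], n))
    if k > len(ranked):
        import warnings

        warnings.warn(f"k={k} exceeds node count {len(ranked)}; returning all",
                      stacklevel=2)
    return ranked[:k]


def summarize(net: SimilarityNetwork) -> dict:
    """Shape summary: node/edge/component counts, component sizes and
    per-fold node counts."""
    comps = components(net)
    per_fold: dict[str, int] = {}
    for _, data in net.graph.nodes(data=True):
        fold = data.get("fold", "?")
        per_fold[fold] = per_fold.get(fold, 0) + 1
    return {
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "n_components": len(comps),
        "component_sizes": [len(c) for c in comps],
        "per_fold": dict(sorted(per_fold.items())),
    }


def write_graphml(net: SimilarityNetwork, path) -> None:
    g = nx.Graph()
    g.add_nodes_from((n, dict(d)) for n, d in net.graph.nodes(data=True))
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, multiplicity=d["multiplicity"])
    nx.write_graphml(g, str(path))


def write_dot(net: SimilarityNetwork, path) -> None:
    lines = ["graph similarity {"]
    for n, d in sorted(net.graph.nodes(data=True)):
        lines.append(f'  "{n}" [scop="{d.get("scop", "")}"];')
    for u, v in sorted(map(sorted, net.graph.edges)):
        m = net.graph.edges[u, v]["multiplicity"]
        lines.append(f'  "{u}" -- "{v}" [multiplicity={m}];')
    lines.append("}")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")
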