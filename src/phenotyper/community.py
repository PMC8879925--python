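"""Confusion-matrix similarity graphs and Louvain community detection.

The confusion matrix becomes an undirected weighted graph: nodes are class
labels, the edge weight between distinct classes i and j is the arithmetic
mean of the two directed confusion fractions, and the diagonal
(self-confusion) is discarded. Rectangular matrices are first embedded on
the union of row and column labels with absent cells treated as zero.

Louvain here is the standard two-phase greedy modularity optimizer: local
node moves to the neighboring community with the largest positive gain
(ties broken by smallest community id for determinism), then aggregation,
repeated until the partition stabilizes. Node visiting order is randomized
per seed and the best of several restarts by modularity is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .classify import ConfusionMatrix


@dataclass
class Partition:
    communities: dict           # node -> community id (0-based, contiguous)
    modularity: float
    flags: list[str] = field(default_factory=list)

    def groups(self) -> list[set]:
        out: dict[int, set] = {}
        for node, cid in self.communities.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


def build_similarity_graph(cm: ConfusionMatrix) -> nx.Graph:
    """Symmetrize a (possibly rectangular) confusion matrix into a graph."""
    nodes = sorted(set(cm.row_labels) | set(cm.col_labels))
    ridx = {l: i for i, l in enumerate(cm.row_labels)}
    cidx = {l: j for j, l in enumerate(cm.col_labels)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a_i, a in enumerate(nodes):
        for b in nodes[a_i + 1:]:
            ab = cm.values[ridx[a], cidx[b]] if a in ridx and b in cidx else 0.0
            ba = cm.values[ridx[b], cidx[a]] if b in ridx and a in cidx else 0.0
            w = (ab + ba) / 2.0
            if w > 0:
                g.add_edge(a, b, weight=float(w))
    return g


def modularity(graph: nx.Graph, partition: dict, resolution: float = 1.0) -> float:
    """Q = sum_c [ W_c/W - resolution * (S_c / 2W)^2 ].

    W is the total edge weight, W_c the intra-community weight and S_c the
    community degree sum (self-loops contribute twice to their node degree).
    """
    uncovered = set(graph.nodes) - set(partition)
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {sorted(map(str, uncovered))}")
    W = graph.size(weight="weight")
    if W == 0:
        return 0.0
    intra: dict = {}
    degsum: dict = {}
    for u, v, w in graph.edges(data="weight", default=1.0):
        cu, cv = partition[u], partition[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    for u in graph.nodes:
        degsum[partition[u]] = degsum.get(partition[u], 0.0) + graph.degree(u, weight="weight")
    q = 0.0
    for c in degsum:
        q += intra.get(c, 0.0) / W - resolution * (degsum[c] / (2.0 * W)) ** 2
    return q


# --------------------------------------------------------------------------
# Louvain internals operate on an adjacency-dict view of the graph
# --------------------------------------------------------------------------
def _one_level(adj, loops, node2com, resolution, rng):
    """One pass of local moves; returns True if any node moved."""
    m2 = sum(sum(nb.values()) for nb in adj.values()) + 2.0 * sum(loops.values())
    # m2 = 2W including self-loops counted twice
    if m2 == 0:
        return False
    degrees = {u: sum(adj[u].values()) + 2.0 * loops.get(u, 0.0) for u in adj}
    com_tot = {}
    for u, c in node2com.items():
        com_tot[c] = com_tot.get(c, 0.0) + degrees[u]
    moved_any = False
    improved = True
    while improved:
        improved = False
        nodes = list(adj)
        rng.shuffle(nodes)
        for u in nodes:
            cu = node2com[u]
            ku = degrees[u]
            # weight from u to each neighboring community
            links = {}
            for v, w in adj[u].items():
                links[node2com[v]] = links.get(node2com[v], 0.0) + w
            com_tot[cu] -= ku
            base = links.get(cu, 0.0) - resolution * com_tot[cu] * ku / m2
            best_c, best_rel = cu, 0.0
            # sorted iteration + strict improvement => smallest community wins ties
            for c in sorted(links):
                if c == cu:
                    continue
                rel = (links[c] - resolution * com_tot.get(c, 0.0) * ku / m2) - base
                if rel > best_rel + 1e-12:
                    best_c, best_rel = c, rel
            com_tot[best_c] = com_tot.get(best_c, 0.0) + ku
            if best_c != cu:
                node2com[u] = best_c
                improved = True
                moved_any = True
    return moved_any


def _aggregate(adj, loops, node2com):
    """Collapse communities into super-nodes."""
    new_adj: dict = {}
    new_loops: dict = {}
    for u, nbrs in adj.items():
        cu = node2com[u]
        new_adj.setdefault(cu, {})
        new_loops[cu] = new_loops.get(cu, 0.0) + loops.get(u, 0.0)
        for v, w in nbrs.items():
            cv = node2com[v]
            if cu == cv:
                # each intra edge visited from both endpoints -> w/2 each
                new_loops[cu] = new_loops.get(cu, 0.0) + w / 2.0
            else:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
    return new_adj, new_loops


def louvain(graph: nx.Graph, resolution: float = 1.0, seed: int = 0,
            restarts: int = 10) -> Partition:
    """Two-phase Louvain on a weighted undirected graph; best of restarts."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes, key=lambda n: (isinstance(n, tuple), n))
    total_w = graph.size(weight="weight")
    if total_w == 0:
        part = {n: i for i, n in enumerate(nodes)}
        return Partition(part, 0.0, flags=["all-zero-weight graph: singleton communities"])

    best: Partition | None = None
    master = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        rng = np.random.default_rng(master.integers(2**63))
        adj = {u: {} for u in nodes}
        loops = {}
        for u, v, w in graph.edges(data="weight", default=1.0):
            if u == v:
                loops[u] = loops.get(u, 0.0) + w
            else:
                adj[u][v] = adj[u].get(v, 0.0) + w
                adj[v][u] = adj[v].get(u, 0.0) + w
        node2com = {u: u for u in nodes}          # community ids = representative nodes
        membership = {u: u for u in nodes}        # original node -> current super-node
        while True:
            moved = _one_level(adj, loops, node2com, resolution, rng)
            if not moved:
                break
            membership = {orig: node2com[sup] for orig, sup in membership.items()}
            adj, loops = _aggregate(adj, loops, node2com)
            node2com = {c: c for c in adj}
        final = {}
        ids = {}
        for n in nodes:
            rep = membership[n]
            if rep not in ids:
                ids[rep] = len(ids)
            final[n] = ids[rep]
        q = modularity(graph, final, resolution=resolution)
        if best is None or q > best.modularity + 1e-15:
            best = Partition(final, q)
    return best


def partition_to_json(partition: Partition) -> dict:
    fmt = lambda n: f"{n[0]}:{n[1]}" if isinstance(n, tuple) else str(n)
    return {
        "communities": {fmt(n): int(c) for n, c in partition.communities.items()},
        "modularity": partition.modularity,
        "flags": partition.flags,
    }


def export_graph(graph: nx.Graph, edge_csv=None, graphml=None) -> None:
    if edge_csv is not None:
        import csv

        with open(edge_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "weight"])
            fmt = lambda n: f"{n[0]}:{n[1]}" if isinstance(n, tuple) else str(n)
            for u, v, d in graph.edges(data=True):
                w.writerow([fmt(u), fmt(v), d.get("weight", 1.0)])
    if graphml is not None:
        g2 = nx.relabel_nodes(
            graph, {n: (f"{n[0]}:{n[1]}" if isinstance(n, tuple) else str(n)) for n in graph.nodes}
        )
        nx.write_graphml(g2, graphml)
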