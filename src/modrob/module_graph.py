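"""Coarse-grained module network: weighted arcs, filtering, centralities.

Collapsing each module of a partition to one node yields a directed module
graph.  An arc i→j exists when at least one network arc runs from module i
to module j (i ≠ j; intra-module arcs are not represented).  Its absolute
weight w counts those arcs; its relative weight w/(n_i·n_j) normalizes by
the maximal possible number of interactions between the two modules.

The appearance-ratio filter keeps only the ⌈ratio·E⌉ heaviest module arcs,
which exposes strongly interacting or isolated modules.  Five centralities
describe how centrally a module sits among the others: degree (in+out),
harmonic closeness on outgoing shortest paths, betweenness (fraction of
shortest paths through the module), stress (count of shortest paths through
it), and eigenvector centrality of the symmetrized adjacency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import Partition, SignedDigraph

MODES = ("absolute", "relative")

CENTRALITY_COLUMNS = ("degree", "closeness", "betweenness", "stress", "eigenvector")


@dataclass(frozen=True)
class ModuleGraph:
    """Module-level digraph; nodes are module indices 0..M-1."""

    graph: nx.DiGraph
    mode: str

    @property
    def n_modules(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, i: int, j: int) -> float:
        key = "absolute_weight" if self.mode == "absolute" else "relative_weight"
        return self.graph.edges[i, j][key]


def build_module_graph(
    net: SignedDigraph, part: Partition, mode: str = "absolute"
) -> ModuleGraph:
    """Count inter-module arcs and build the weighted module digraph."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    part.validate_against(net)
    mod_of = part.module_of
    counts: dict[tuple[int, int], int] = {}
    for src, tgt, _ in net.arcs:
        a, b = mod_of[src], mod_of[tgt]
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    g = nx.DiGraph(mode=mode)
    for i, mod in enumerate(part.modules):
        g.add_node(i, size=len(mod), members=",".join(sorted(mod)))
    for (a, b), w in sorted(counts.items()):
        rel = w / (len(part.modules[a]) * len(part.modules[b]))
        dist = 1.0 / (w if mode == "absolute" else rel)
        g.add_edge(a, b, absolute_weight=w, relative_weight=rel, distance=dist)
    return ModuleGraph(graph=g, mode=mode)


def filter_by_appearance_ratio(mg: ModuleGraph, ratio: float) -> ModuleGraph:
    """Keep the ⌈ratio·E⌉ heaviest module arcs (E = current arc count).

    Ties at the cutoff are broken by ascending (source, target) module
    index, which makes the filter idempotent and monotone in ``ratio``.
    All module nodes are retained.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    edges = list(mg.graph.edges)
    keep_n = math.ceil(ratio * len(edges))
    ranked = sorted(edges, key=lambda e: (-mg.weight(*e), e[0], e[1]))
    keep = set(ranked[:keep_n])
    g = nx.DiGraph(mode=mg.mode)
    g.add_nodes_from(mg.graph.nodes(data=True))
    for u, v in sorted(keep):
        g.add_edge(u, v, **mg.graph.edges[u, v])
    return ModuleGraph(graph=g, mode=mg.mode)


def _stress_centrality(g: nx.DiGraph, weight: str | None) -> dict[int, float]:
    """Count shortest paths through each node, over all ordered pairs."""
    stress = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        for t in g.nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            for path in nx.all_shortest_paths(g, s, t, weight=weight):
                for v in path[1:-1]:
                    stress[v] += 1.0
    return stress


def _eigenvector_centrality(g: nx.DiGraph) -> dict[int, float]:
    """Principal eigenvector of the symmetrized adjacency.

    Computed on the largest connected component of the undirected skeleton
    (Perron-Frobenius guarantees a unique nonnegative vector there);
    modules outside it get 0.  L2-normalized with nonnegative entries.
    """
    und = g.to_undirected()
    nodes = list(g.nodes)
    values = {v: 0.0 for v in nodes}
    if not nodes:
        return values
    comps = sorted(nx.connected_components(und), key=lambda c: (-len(c), min(c)))
    comp = sorted(comps[0])
    adj = nx.to_numpy_array(und, nodelist=comp)
    eigvals, eigvecs = np.linalg.eigh(adj)
    vec = eigvecs[:, int(np.argmax(eigvals))]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)  # Perron vector is nonnegative; clean rounding noise
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    for v, x in zip(comp, vec):
        values[v] = float(x)
    return values


def module_centralities(mg: ModuleGraph, weighted: bool = False) -> pd.DataFrame:
    """Five centralities per module, as a DataFrame indexed by module id.

    By default path-based measures use the unweighted directed module graph;
    ``weighted=True`` switches shortest paths to distance = 1/weight.
    """
    g = mg.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty module graph")
    weight = "distance" if weighted else None
    degree = {v: g.in_degree(v) + g.out_degree(v) for v in g.nodes}
    # harmonic closeness on outgoing paths: networkx sums over incoming,
    # so evaluate on the reversed graph
    closeness = nx.harmonic_centrality(g.reverse(), distance=weight)
    betweenness = nx.betweenness_centrality(g, normalized=False, weight=weight)
    stress = _stress_centrality(g, weight)
    eigen = _eigenvector_centrality(g)
    nodes = sorted(g.nodes)
    df = pd.DataFrame(
        {
            "degree": [float(degree[v]) for v in nodes],
            "closeness": [float(closeness[v]) for v in nodes],
            "betweenness": [float(betweenness[v]) for v in nodes],
            "stress": [float(stress[v]) for v in nodes],
            "eigenvector": [eigen[v] for v in nodes],
        },
        index=pd.Index(nodes, name="module"),
    )
    return df


def write_module_graph(mg: ModuleGraph, prefix: str | Path) -> tuple[Path, Path]:
    """Export GraphML and a TSV edge list; returns the two paths."""
    prefix = Path(prefix)
    graphml = prefix.with_suffix(".graphml")
    tsv = prefix.with_suffix(".edges.tsv")
    nx.write_graphml(mg.graph, graphml)
    with open(tsv, "w") as fh:
        fh.write("source\ttarget\tabsolute_weight\trelative_weight\n")
        for u, v, data in sorted(mg.graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data['absolute_weight']}\t{data['relative_weight']:.10g}\n"
            )
    return graphml, tsv


def export_detailed_view(
    net: SignedDigraph, part: Partition, path: str | Path
) -> Path:
    """Detailed mode: the original network plus a node→module attribute table."""
    path = Path(path)
    mod_of = part.module_of
    with open(path, "w") as fh:
        fh.write("node\tmodule\n")
        for v in net.nodes:
            fh.write(f"{v}\t{mod_of[v]}\n")
    return path
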