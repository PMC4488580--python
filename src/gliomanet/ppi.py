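"""Interactome modularization: signature subsetting, percolation-score
hubs, first-neighbour expansion and community detection.

The procedure mirrors the stage-transition analysis of a protein-protein
interaction network: restrict the interactome to differentially expressed
genes, call hubs whose removal disrupts the largest connected component
(percolation score more than two standard deviations above the mean),
expand to the hubs' first neighbours, and partition the result into
communities by modularity maximization.

Graphs are plain :class:`networkx.Graph` objects; they must be simple and
undirected (``validate_graph`` enforces this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity

from gliomanet._util import InputError

__all__ = [
    "validate_graph",
    "subset_by_signature",
    "percolation_scores",
    "HubReport",
    "expand_to_neighbours",
    "detect_communities",
    "ModuleSet",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
]


def validate_graph(graph: nx.Graph) -> nx.Graph:
    """Check the simple-undirected-graph invariants."""
    if graph.is_directed() or graph.is_multigraph():
        raise InputError("graph must be simple and undirected")
    if any(u == v for u, v in graph.edges):
        raise InputError("self-loops are not allowed")
    return graph


@dataclass
class HubReport:
    """Per-node percolation scores and the mean + 2 SD hub call."""

    scores: pd.Series  # node -> percolation score in [0, 1]
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean + 2.0 * self.sd

    @property
    def is_hub(self) -> pd.Series:
        return self.scores > self.threshold

    @property
    def hubs(self) -> set:
        return set(self.scores.index[self.is_hub])


@dataclass
class ModuleSet:
    """Disjoint communities of a graph plus the partition's modularity."""

    communities: list[set]
    modularity: float

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.communities:
            if seen & c:
                raise InputError("communities must be disjoint")
            seen |= c


def subset_by_signature(graph: nx.Graph, signature) -> nx.Graph:
    """Induced subgraph on the signature's selected genes.

    Isolated selected nodes are retained (they can still contribute
    neighbours in a later expansion).  An empty intersection yields an
    empty graph with a warning, not an exception.
    """
    validate_graph(graph)
    selected = signature.selected_genes if hasattr(signature, "selected_genes") else set(signature)
    keep = set(graph.nodes) & set(selected)
    if not keep:
        warnings.warn("signature selects no node of the graph; returning an empty graph")
    return graph.subgraph(keep).copy()


def percolation_scores(graph: nx.Graph) -> HubReport:
    """Largest-component disruption score per node.

    ``score(v) = (S - 1 - S_minus_v) / (S - 1)`` where ``S`` is the size of
    the graph's largest connected component and ``S_minus_v`` the size of
    the largest component after deleting ``v``.  A node whose removal
    shatters the giant component scores near 1; removal of a peripheral
    node scores 0.  Hubs are nodes scoring above mean + 2 sample standard
    deviations.
    """
    validate_graph(graph)
    if graph.number_of_nodes() == 0:
        raise InputError("graph is empty")
    components = list(nx.connected_components(graph))
    s_big = max(len(c) for c in components)
    nodes = list(graph.nodes)
    scores = np.zeros(len(nodes))
    if s_big > 1:
        for i, v in enumerate(nodes):
            h = graph.copy()
            h.remove_node(v)
            s_minus = max((len(c) for c in nx.connected_components(h)), default=0)
            scores[i] = (s_big - 1 - s_minus) / (s_big - 1)
    scores = np.clip(scores, 0.0, 1.0)
    series = pd.Series(scores, index=nodes, name="percolation_score")
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return HubReport(series, float(series.mean()), sd)


def expand_to_neighbours(graph: nx.Graph, hubs: set) -> nx.Graph:
    """Induced subgraph on the hubs and their first neighbours."""
    validate_graph(graph)
    hubs = set(hubs)
    if not hubs <= set(graph.nodes):
        raise InputError("hubs must be nodes of the graph")
    keep = set(hubs)
    for h in hubs:
        keep |= set(graph.neighbors(h))
    return graph.subgraph(keep).copy()


def detect_communities(graph: nx.Graph, min_size: int = 5, seed: int = 0) -> ModuleSet:
    """Partition a graph into communities by greedy modularity maximization.

    Communities smaller than ``min_size`` are dropped from the report.
    Isolated nodes do not contribute to the modularity computation.  The
    greedy agglomeration is deterministic; ``seed`` is accepted for
    interface stability and to fix tie-breaking in future refinements.
    """
    validate_graph(graph)
    if graph.number_of_edges() == 0:
        raise InputError("graph has no edges; subset/expand the interactome first")
    core = graph.subgraph([n for n, d in graph.degree if d > 0])
    communities = [set(c) for c in greedy_modularity_communities(core)]
    q = modularity(core, communities)
    kept = [c for c in communities if len(c) >= min_size]
    return ModuleSet(kept, float(q))


def read_edgelist_tsv(path) -> nx.Graph:
    """Read a 2-column (optionally 3-column with confidence) edge-list TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        u, v = row[0], row[1]
        if u == v:
            continue
        attrs = {"confidence": float(row[2])} if len(row) > 2 and pd.notna(row[2]) else {}
        g.add_edge(u, v, **attrs)
    return validate_graph(g)


def write_edgelist_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            conf = data.get("confidence")
            if conf is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{conf}\n")
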