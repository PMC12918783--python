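"""Thresholded co-essentiality graphs and reciprocal-top-list modules.

The graph view connects gene pairs whose correlation clears the
permutation-calibrated thresholds. A stricter construction looks for
reciprocity: gene b must sit in gene a's top-N correlation list AND a in
b's. Connected components of that mutual-hit graph are high-confidence
functional modules — a useful lens for genes with no annotated function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .coessentiality import CorrelationResult, ThresholdEstimate, correlation_matrix
from .containers import DependencyMatrix
from .literature import novelty_flag

logger = logging.getLogger(__name__)

GRAPH_FORMATS = ("graphml", "edge_list")
EDGE_ATTRS = ("r", "n_obs", "copub_index", "novel")


@dataclass
class ReciprocalModule:
    """Connected component of the mutual top-N correlation graph."""

    members: list[str]
    top_n: int
    internal_edges: int


def build_graph(
    results: list[CorrelationResult],
    thresholds: ThresholdEstimate,
    copub=None,
    index_cutoff: float = 5.0,
) -> nx.Graph:
    """Undirected graph of threshold-passing correlations.

    Every gene named in ``results`` becomes a node; an edge appears for
    each pair with r above ``r_pos`` or below ``r_neg``, annotated with r,
    n_obs, the co-publication index and the novelty flag. Input order does
    not affect the result.
    """
    graph = nx.Graph()
    for res in results:
        graph.add_node(res.gene_a)
        graph.add_node(res.gene_b)
        if res.gene_a == res.gene_b or not thresholds.passes(res.r):
            continue
        idx = copub.index(res.gene_a, res.gene_b) if copub is not None else 0.0
        graph.add_edge(
            res.gene_a,
            res.gene_b,
            r=res.r,
            n_obs=res.n_obs,
            copub_index=idx,
            novel=novelty_flag(abs(res.r), idx, index_cutoff=index_cutoff),
        )
    return graph


class ReciprocalModuleFinder(BaseEstimator):
    """Extract modules of mutually top-ranked co-essential genes.

    Ranks every gene's partners by r descending (positive correlations
    only, unless ``use_abs``), keeps an edge a–b iff each gene lies in the
    other's top ``top_n``, and reports connected components with at least
    two members. Components are sorted by size descending, then by the
    lexicographically smallest member; member lists are sorted.
    """

    def __init__(self, top_n: int = 3, use_abs: bool = False):
        self.top_n = top_n
        self.use_abs = use_abs

    def fit(self, X: DependencyMatrix, y=None):
        if self.top_n < 1:
            raise ValueError("top_n must be at least 1")
        r, _ = correlation_matrix(X)
        genes = list(r.index)
        rv = r.to_numpy(copy=True)
        np.fill_diagonal(rv, np.nan)
        rank_on = np.abs(rv) if self.use_abs else rv
        top_lists: dict[str, set[str]] = {}
        for i, g in enumerate(genes):
            row = rank_on[i]
            ok = ~np.isnan(row)
            if not self.use_abs:
                ok &= row > 0  # only positive r count as co-functional hits
            idx = np.nonzero(ok)[0]
            order = idx[np.argsort(-row[idx], kind="stable")]
            top_lists[g] = {genes[j] for j in order[: self.top_n]}
        graph = nx.Graph()
        graph.add_nodes_from(genes)
        for i, a in enumerate(genes):
            for b in top_lists[a]:
                if a in top_lists[b]:
                    graph.add_edge(a, b)
        modules = []
        for comp in nx.connected_components(graph):
            if len(comp) < 2:
                continue
            members = sorted(comp)
            modules.append(
                ReciprocalModule(
                    members=members,
                    top_n=self.top_n,
                    internal_edges=graph.subgraph(comp).number_of_edges(),
                )
            )
        modules.sort(key=lambda m: (-len(m.members), m.members[0]))
        self.modules_ = modules
        self.reciprocal_graph_ = graph
        return self

    def fit_predict(self, X: DependencyMatrix) -> list[ReciprocalModule]:
        return self.fit(X).modules_


def reciprocal_modules(
    dep: DependencyMatrix, top_n: int = 3, use_abs: bool = False
) -> list[ReciprocalModule]:
    """Functional wrapper over :class:`ReciprocalModuleFinder`."""
    return ReciprocalModuleFinder(top_n=top_n, use_abs=use_abs).fit_predict(dep)


def export_graph(graph: nx.Graph, path: str, format: str = "graphml") -> None:
    """Write a co-essentiality graph as GraphML or a TSV edge list."""
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge_list":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\t" + "\t".join(EDGE_ATTRS) + "\n")
            for a, b, attrs in sorted(graph.edges(data=True)):
                fh.write(
                    f"{a}\t{b}\t{attrs['r']!r}\t{attrs['n_obs']}\t"
                    f"{attrs['copub_index']!r}\t{attrs['novel']}\n"
                )
    else:
        raise ValueError(
            f"unknown graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}"
        )


def import_graph(path: str, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_list":
        graph = nx.Graph()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            assert header[:2] == ["gene_a", "gene_b"]
            for line in fh:
                a, b, r, n_obs, copub, novel = line.rstrip("\n").split("\t")
                graph.add_edge(
                    a,
                    b,
                    r=float(r),
                    n_obs=int(n_obs),
                    copub_index=float(copub),
                    novel=novel == "True",
                )
        return graph
    raise ValueError(
        f"unknown graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}"
    )
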