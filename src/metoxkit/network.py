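"""GO-similarity protein networks and Newman assortativity.

Two proteins are related when their GO-term sets have Jaccard similarity
of at least 0.5 (the threshold is inclusive).  Over the resulting
undirected graph, whose nodes are labeled by oxidation group (red =
ex vivo, blue = in vitro), assortative mixing is quantified with Newman's
coefficient.  With a symmetric mixing matrix e_ij (the fraction of edge
ends joining type i to type j; each undirected edge contributes both
orientations) and marginals a_i = sum_j e_ij, the coefficient for two
numeric labels {0, 1} is

    r = sum_ij i*j*(e_ij - a_i a_j) / (sigma_a * sigma_b),

the Pearson correlation of endpoint labels over the edge-end list; r = 1
for perfect assortativity, r = -1 for perfect disassortativity.

Two null models are provided: label permutation on fixed topology
(``relabel_null``) and induced-subgraph sampling from a larger proteome
graph with random labels (``subsample_null``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

from .composition import NullDistribution
from .io import ProteinRecord


class UndefinedAssortativity(ValueError):
    """All edge ends carry one label: the coefficient is undefined."""


def jaccard(set_i: Iterable, set_j: Iterable) -> float:
    """Jaccard similarity |i ∩ j| / |i ∪ j|; two empty sets give 0."""
    si, sj = set(set_i), set(set_j)
    union = len(si | sj)
    if union == 0:
        return 0.0
    return len(si & sj) / union


def build_graph(
    proteins: Sequence[ProteinRecord],
    threshold: float = 0.5,
    label_from_group: bool = True,
) -> nx.Graph:
    """Build the GO-similarity graph: edge iff Jaccard >= threshold, i != j.

    Every protein becomes a node (isolated nodes are retained); node
    attribute ``label`` holds the oxidation group.  Proteins with empty GO
    sets have similarity 0 with everything and stay isolated.
    """
    g = nx.Graph()
    for p in proteins:
        g.add_node(p.id, label=p.group if label_from_group else None)
    # sparse indicator algebra: pairwise intersections via B @ B.T
    terms: dict[str, int] = {}
    rows, cols = [], []
    sizes = np.zeros(len(proteins), dtype=np.int64)
    for i, p in enumerate(proteins):
        sizes[i] = len(p.go_terms)
        for t in p.go_terms:
            rows.append(i)
            cols.append(terms.setdefault(t, len(terms)))
    if not terms:
        return g
    b = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(proteins), len(terms)),
    )
    inter = sparse.triu(b @ b.T, k=1).tocoo()
    union = sizes[inter.row] + sizes[inter.col] - inter.data
    keep = inter.data >= threshold * union  # inter/union >= threshold, union > 0
    for i, j in zip(inter.row[keep], inter.col[keep]):
        g.add_edge(proteins[i].id, proteins[j].id)
    return g


def _r_from_end_counts(n_rr: float, n_bb: float, n_rb: float) -> float:
    """Newman r for two types from undirected edge counts by end labels."""
    m = n_rr + n_bb + n_rb
    if m == 0:
        raise UndefinedAssortativity("graph has no edges")
    e11 = n_rr / m           # labels: blue=0, red=1
    e10 = n_rb / (2 * m)     # each mixed edge gives one (1,0) and one (0,1) end
    a1 = e11 + e10           # = b1 on an undirected graph
    var = a1 - a1 * a1
    if var <= 0:
        raise UndefinedAssortativity("all edge ends carry a single label")
    return (e11 - a1 * a1) / var


def assortativity(graph: nx.Graph, label_attr: str = "label") -> float:
    """Newman assortativity of a binary-labeled graph (two label values).

    Raises :class:`UndefinedAssortativity` when the graph has no edges or
    all edge endpoints share one label.
    """
    labels = nx.get_node_attributes(graph, label_attr)
    values = sorted({labels[n] for n in graph.nodes})
    if len(values) > 2:
        raise ValueError(f"expected at most two label values, got {values}")
    n_rr = n_bb = n_rb = 0
    red = values[-1]
    for u, v in graph.edges:
        lu, lv = labels[u] == red, labels[v] == red
        if lu and lv:
            n_rr += 1
        elif not lu and not lv:
            n_bb += 1
        else:
            n_rb += 1
    return _r_from_end_counts(n_rr, n_bb, n_rb)


def _edge_index_arrays(graph: nx.Graph) -> tuple[np.ndarray, np.ndarray, list]:
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    if graph.number_of_edges():
        uv = np.array([(index[u], index[v]) for u, v in graph.edges], dtype=np.int64)
        return uv[:, 0], uv[:, 1], nodes
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), nodes


def _r_from_labels(u: np.ndarray, v: np.ndarray, red: np.ndarray) -> float:
    lu, lv = red[u], red[v]
    n_rr = int(np.count_nonzero(lu & lv))
    n_bb = int(np.count_nonzero(~lu & ~lv))
    n_rb = len(u) - n_rr - n_bb
    return _r_from_end_counts(n_rr, n_bb, n_rb)


def relabel_null(
    graph: nx.Graph,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
    mode: str = "permute",
    label_attr: str = "label",
) -> NullDistribution:
    """Label-permutation null for assortativity on a fixed topology.

    ``mode='permute'`` (default) shuffles the existing labels, preserving
    the red/blue counts; ``mode='bernoulli'`` relabels each node
    independently with the observed red fraction.  Iterations where r is
    undefined are skipped and counted in ``n_skipped``.
    """
    labels = nx.get_node_attributes(graph, label_attr)
    values = sorted({labels[n] for n in graph.nodes})
    red_value = values[-1]
    u, v, nodes = _edge_index_arrays(graph)
    red = np.array([labels[n] == red_value for n in nodes])
    observed = _r_from_labels(u, v, red)
    rng = np.random.default_rng(seed)
    out, skipped = [], 0
    for _ in range(n_iter):
        if mode == "permute":
            perm = rng.permutation(red)
        elif mode == "bernoulli":
            perm = rng.random(len(red)) < red.mean()
        else:
            raise ValueError("mode must be 'permute' or 'bernoulli'")
        try:
            out.append(_r_from_labels(u, v, perm))
        except UndefinedAssortativity:
            skipped += 1
    return NullDistribution.from_values(
        "assortativity", len(nodes), np.array(out), observed, n_skipped=skipped
    )


def subsample_null(
    proteome_graph: nx.Graph,
    n_red: int = 1113,
    n_blue: int = 503,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
    observed: float | None = None,
) -> NullDistribution:
    """Subsampling null: random induced subgraphs of a larger proteome graph.

    Each iteration samples ``n_red + n_blue`` nodes uniformly without
    replacement, takes the induced subgraph, labels ``n_red`` of them red
    at random, and records r.  Undefined iterations (e.g. an edgeless
    subgraph) are skipped and counted.  ``observed`` is the assortativity
    of the actual labeled network to be compared against this null.
    """
    u, v, nodes = _edge_index_arrays(proteome_graph)
    n_nodes = len(nodes)
    k = n_red + n_blue
    if k > n_nodes:
        raise ValueError("proteome graph smaller than requested subsample")
    rng = np.random.default_rng(seed)
    out, skipped = [], 0
    for _ in range(n_iter):
        chosen = rng.permutation(n_nodes)[:k]
        in_sub = np.zeros(n_nodes, dtype=bool)
        in_sub[chosen] = True
        red = np.zeros(n_nodes, dtype=bool)
        red[chosen[:n_red]] = True  # the selection order is already random
        keep = in_sub[u] & in_sub[v]
        try:
            out.append(_r_from_labels(u[keep], v[keep], red))
        except UndefinedAssortativity:
            skipped += 1
    if not out:
        raise UndefinedAssortativity(
            f"all {n_iter} subsample iterations were undefined"
        )
    return NullDistribution.from_values(
        "assortativity",
        k,
        np.array(out),
        observed if observed is not None else float("nan"),
        n_skipped=skipped,
    )


def write_edge_list(graph: nx.Graph, path) -> None:
    """Two-column TSV edge list."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in graph.edges:
            fh.write(f"{a}\t{b}\n")
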