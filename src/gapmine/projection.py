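"""Unipartite projections of the bipartite network and community detection.

The projection on the row set V has adjacency A @ A.T (A.T @ A for the
column set W): the edge weight between two nodes is the summed product of
their weights to shared partners.  Missing cells contribute zero to every
product — the projection measures shared *observed* partners, since missing
cells are unknown interactions rather than true zeros.  Self-similarities
(the diagonal of the product) are stored separately; zero-weight pairs carry
no edge.

Community detection delegates to python-igraph (walktrap, multilevel,
infomap, label propagation, leading eigenvector, spinglass, fast greedy);
the added value here is seeding, per-component handling, and the internal
(average silhouette width) and external (Jaccard / Rand) validation around
the detected partitions.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import numpy as np
from sklearn.metrics import silhouette_samples

from ._pairs import pair_counts_from_labels
from .incidence import IncidenceMatrix
from .structure import modularity

CLUSTER_METHODS = (
    "walktrap",
    "multilevel",
    "infomap",
    "label_propagation",
    "leading_eigenvector",
    "spinglass",
    "fast_greedy",
)

#: deterministic igraph methods (identical membership across runs at any seed)
DETERMINISTIC_METHODS = ("fast_greedy", "leading_eigenvector", "walktrap")


@dataclass
class ProjectionGraph:
    part: str  # "V" (rows) or "W" (columns)
    names: list[str]
    graph: ig.Graph
    self_similarity: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.graph.vcount()

    @property
    def edge_weights(self) -> np.ndarray:
        if self.graph.ecount() == 0:
            return np.zeros(0)
        return np.asarray(self.graph.es["weight"], dtype=float)

    def to_edge_list_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for e in self.graph.es:
                fh.write(
                    f"{self.names[e.source]}\t{self.names[e.target]}\t{e['weight']}\n"
                )

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        g.vs["name"] = self.names
        g.write_graphml(str(path))


@dataclass
class ClusteringResult:
    method: str
    membership: dict[str, int]
    Q: float
    asw: float
    seed: int
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_clusters = len(set(self.membership.values()))


def _normalize_part(part: str) -> str:
    key = str(part).lower()
    if key in ("v", "rows", "row"):
        return "V"
    if key in ("w", "cols", "col", "columns"):
        return "W"
    raise ValueError(f"unknown part {part!r}; use 'V'/'rows' or 'W'/'cols'")


def project(M: IncidenceMatrix, part: str = "V") -> ProjectionGraph:
    """Project the bipartite network onto one node set (missing -> 0)."""
    part = _normalize_part(part)
    A = M.values_filled(0.0)
    if part == "V":
        S = A @ A.T
        names = list(M.row_names)
    else:
        S = A.T @ A
        names = list(M.col_names)
    self_sim = np.diag(S).copy()
    W = S.copy()
    np.fill_diagonal(W, 0.0)
    src, tgt = np.nonzero(np.triu(W, k=1))
    g = ig.Graph(n=W.shape[0], edges=list(zip(src.tolist(), tgt.tolist())))
    g.es["weight"] = [float(W[i, j]) for i, j in zip(src, tgt)]
    return ProjectionGraph(part=part, names=names, graph=g, self_similarity=self_sim)


def prune_weak_edges(
    G: ProjectionGraph,
    threshold: Optional[float] = None,
    quantile: Optional[float] = None,
) -> ProjectionGraph:
    """Remove edges with weight <= threshold (or <= the q-quantile of weights).

    The node set is unchanged.  Pruning every edge emits a warning and
    returns an edgeless graph.
    """
    if (threshold is None) == (quantile is None):
        raise ValueError("give exactly one of threshold or quantile")
    if quantile is not None:
        if G.graph.ecount() == 0:
            raise ValueError("quantile pruning needs at least one edge")
        threshold = float(np.quantile(G.edge_weights, quantile))
    g = G.graph.copy()
    drop = [e.index for e in g.es if e["weight"] <= threshold]
    g.delete_edges(drop)
    if g.ecount() == 0 and G.graph.ecount() > 0:
        warnings.warn("pruning removed every edge", stacklevel=2)
    return ProjectionGraph(
        part=G.part,
        names=list(G.names),
        graph=g,
        self_similarity=G.self_similarity.copy(),
    )


def _seed_igraph(seed: int) -> None:
    ig.set_random_number_generator(random.Random(seed))


def _run_method(g: ig.Graph, method: str, seed: int) -> list[int]:
    weights = g.es["weight"] if g.ecount() > 0 else None
    if g.ecount() == 0:
        return list(range(g.vcount()))  # every isolated node its own cluster
    _seed_igraph(seed)
    if method == "walktrap":
        return g.community_walktrap(weights=weights).as_clustering().membership
    if method == "multilevel":
        return g.community_multilevel(weights=weights).membership
    if method == "infomap":
        return g.community_infomap(edge_weights=weights).membership
    if method == "label_propagation":
        return g.community_label_propagation(weights=weights).membership
    if method == "leading_eigenvector":
        return g.community_leading_eigenvector(weights=weights).membership
    if method == "fast_greedy":
        return g.community_fastgreedy(weights=weights).as_clustering().membership
    if method == "spinglass":
        # spinglass requires a connected graph: run per component, offset ids
        comps = g.connected_components()
        membership = [0] * g.vcount()
        offset = 0
        for comp in comps:
            if len(comp) == 1:
                membership[comp[0]] = offset
                offset += 1
                continue
            sub = g.subgraph(comp)
            _seed_igraph(seed)
            sub_mem = sub.community_spinglass(
                weights=sub.es["weight"] if sub.ecount() else None
            ).membership
            for v, c in zip(comp, sub_mem):
                membership[v] = offset + c
            offset += max(sub_mem) + 1
        return membership
    raise ValueError(f"unknown clustering method {method!r}")


def find_clusters(
    G: ProjectionGraph,
    methods: Sequence[str] | str = "all",
    seed: int = 0,
) -> list[ClusteringResult]:
    """Run the requested community-detection algorithms with validation.

    Each result carries the modularity Q of the partition and the average
    silhouette width (asw) computed on the same graph the method ran on.
    """
    if methods == "all":
        methods = CLUSTER_METHODS
    elif isinstance(methods, str):
        methods = [methods]
    for name in methods:
        if name not in CLUSTER_METHODS:
            raise ValueError(f"unknown clustering method {name!r}")
    if G.n_nodes == 0:
        raise ValueError("empty graph")
    results = []
    for name in methods:
        mem = _run_method(G.graph, name, seed)
        q = modularity(G.graph, mem) if G.graph.ecount() > 0 else float("nan")
        asw = silhouette_score(G, mem)
        results.append(
            ClusteringResult(
                method=name,
                membership={G.names[i]: int(c) for i, c in enumerate(mem)},
                Q=q,
                asw=asw,
                seed=seed,
            )
        )
    return results


def graph_distances(G: ProjectionGraph) -> np.ndarray:
    """Pairwise node distances: shortest paths with edge length 1/weight.

    Unreachable pairs are assigned twice the largest finite distance (the
    graph's finite diameter); an edgeless graph has no defined distances and
    returns an all-NaN matrix (silhouette is then undefined).
    """
    n = G.n_nodes
    if G.graph.ecount() == 0:
        return np.full((n, n), np.nan)
    lengths = [1.0 / w for w in G.graph.es["weight"]]
    D = np.asarray(G.graph.distances(weights=lengths), dtype=float)
    finite = D[np.isfinite(D)]
    diam = float(finite.max())
    D[~np.isfinite(D)] = 2.0 * diam
    return D


def silhouette_score(G: ProjectionGraph, membership: Sequence[int] | dict) -> float:
    """Average silhouette width of a partition under the path-length metric.

    Returns NaN (undefined) for a single-cluster partition or an edgeless
    graph; all-singleton partitions score 0 by the usual convention.
    """
    if isinstance(membership, dict):
        mem = np.asarray([membership[name] for name in G.names])
    else:
        mem = np.asarray(list(membership))
    labels = np.unique(mem)
    if labels.size < 2:
        return float("nan")
    if labels.size == mem.size:
        return 0.0
    D = graph_distances(G)
    if np.isnan(D).any():
        return float("nan")
    vals = silhouette_samples(D, mem, metric="precomputed")
    return float(vals.mean())


def external_validation(
    membership: dict[str, int], truth_labels: dict[str, object]
) -> dict[str, float]:
    """Pair-counting agreement between a clustering and prior labels.

    Rand = (a+d)/(a+b+c+d), Jaccard = a/(a+b+c), where a counts node pairs
    co-clustered in both partitions, b in the truth only, c in the candidate
    only, and d in neither.
    """
    if set(membership) != set(truth_labels):
        raise ValueError("membership and truth labels must cover the same nodes")
    nodes = sorted(membership)
    cand = [membership[v] for v in nodes]
    truth = [truth_labels[v] for v in nodes]
    pc = pair_counts_from_labels(truth, cand)
    total = pc.a + pc.b + pc.c + pc.d
    denom = pc.a + pc.b + pc.c
    return {
        "rand": (pc.a + pc.d) / total if total else float("nan"),
        "jaccard": pc.a / denom if denom else 0.0,
    }
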