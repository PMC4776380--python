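"""Similarity-graph construction, Markov clustering, core and pioneer calls.

The whole-repertoire comparison builds an undirected graph over all
protein sequences from all datasets, with edges kept at a stringent
e-value threshold (default 1e-35) and weighted by -log10(e-value); the
graph is partitioned with an in-package implementation of the Markov
Cluster algorithm (MCL) at high inflation (default I = 6, favouring
many tight clusters).  Clusters are then labelled:

* *effector-containing* if any member is a candidate effector (from the
  expression/secretion pipeline or supplied published candidate lists);
* *core* if effector-containing and represented by at least
  ``min_datasets`` of the aphid datasets (default 5 of 8);
* *pioneer* if effector-containing, every member lacks both a database
  hit (at 1e-5) and a Pfam-A domain, and the members' datasets are
  confined to a single species or genus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io_formats import AnnotationRecord, SimilarityEdge

__all__ = [
    "SimilarityGraph",
    "Cluster",
    "MCLParams",
    "build_graph",
    "mcl_cluster",
    "label_clusters",
    "label_and_find_core",
    "find_pioneers",
]

EVALUE_ZERO_WEIGHT = 200.0  # -log10 weight assigned to an e-value of exactly 0


@dataclass
class SimilarityGraph:
    """Undirected weighted similarity graph over sequence ids."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class Cluster:
    """One MCL cluster with dataset-membership metadata."""

    id: int
    members: frozenset[str]
    datasets: frozenset[str] = frozenset()
    contains_effector: bool = False

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MCLParams:
    """MCL tuning knobs; the stated defaults are the pipeline's defaults."""

    inflation: float = 6.0
    evalue_threshold: float = 1e-35
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


def evalue_weight(evalue: float) -> float:
    """-log10(e-value), with e-value 0 mapped to the fixed cap."""
    if evalue < 0:
        raise ValueError("negative e-value")
    if evalue == 0.0:
        return EVALUE_ZERO_WEIGHT
    return min(-math.log10(evalue), EVALUE_ZERO_WEIGHT)


def build_graph(
    edges: Iterable[SimilarityEdge],
    node_universe: Iterable[str] | None = None,
    evalue_threshold: float = 1e-35,
) -> SimilarityGraph:
    """Thresholded, weighted similarity graph.

    Edges with e-value above the threshold or joining a node to itself
    are dropped; reciprocal hits are merged keeping the larger weight.
    ``node_universe`` lets hit-less sequences enter as singletons.
    """
    g = nx.Graph()
    if node_universe is not None:
        g.add_nodes_from(node_universe)
    for e in edges:
        if e.query == e.subject or e.evalue > evalue_threshold:
            continue
        w = evalue_weight(e.evalue)
        if g.has_edge(e.query, e.subject):
            g[e.query][e.subject]["weight"] = max(g[e.query][e.subject]["weight"], w)
        else:
            g.add_edge(e.query, e.subject, weight=w)
    return SimilarityGraph(graph=g)


def mcl_cluster(graph: SimilarityGraph | nx.Graph, params: MCLParams | None = None) -> list[Cluster]:
    """Markov clustering by alternating expansion and inflation.

    The column-stochastic matrix (self-loops weighted by each node's
    maximum incident edge weight, 1 for isolated nodes) is iterated:
    expansion (matrix squaring), inflation (entrywise power, then column
    renormalisation) and pruning of entries below the prune threshold,
    until the largest entry change drops below the tolerance.  Clusters
    are read off the attractor structure of the limit matrix: rows with
    a nonzero diagonal are attractors, attractors reachable from one
    another form cluster cores, and every node joins the component of
    the attractors its column mass flows to (ties broken toward the
    component containing the lexicographically smallest attractor id).
    """
    if params is None:
        params = MCLParams()
    g = graph.graph if isinstance(graph, SimilarityGraph) else graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = max(m[idx[u], idx[v]], w)
        m[idx[v], idx[u]] = max(m[idx[v], idx[u]], w)
    # self-loops: the node's maximum incident weight, or 1 if isolated
    col_max = m.max(axis=0)
    np.fill_diagonal(m, np.where(col_max > 0, col_max, 1.0))

    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(params.max_iterations):
        prev = m
        m = m @ m
        m = np.power(m, params.inflation)
        m = m / m.sum(axis=0, keepdims=True)
        m[m < params.prune_threshold] = 0.0
        s = m.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        m = m / s
        if np.max(np.abs(m - prev)) < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iterations; interpreting current matrix")

    return _interpret(m, nodes)


def _interpret(m: np.ndarray, nodes: list[str]) -> list[Cluster]:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    # components among attractors: attractors sharing any column support
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(attractors)
    att_set = set(attractors)
    for j in range(n):
        rows = [i for i in np.nonzero(m[:, j])[0] if i in att_set]
        for a, b in zip(rows, rows[1:]):
            comp_graph.add_edge(a, b)
    components = list(nx.connected_components(comp_graph))
    comp_of_attractor: dict[int, int] = {}
    # deterministic component ids, ordered by their smallest attractor label
    components.sort(key=lambda c: nodes[min(c, key=lambda i: nodes[i])])
    for ci, comp in enumerate(components):
        for a in comp:
            comp_of_attractor[a] = ci

    member_sets: dict[int, set[str]] = {ci: set() for ci in range(len(components))}
    stray: list[str] = []
    for j in range(n):
        rows = [i for i in np.nonzero(m[:, j])[0] if i in att_set]
        if not rows:
            stray.append(nodes[j])
            continue
        comps = {comp_of_attractor[i] for i in rows}
        if len(comps) == 1:
            member_sets[comps.pop()].add(nodes[j])
        else:
            # overlap: join the component holding the smallest attractor id
            best = min(rows, key=lambda i: nodes[i])
            member_sets[comp_of_attractor[best]].add(nodes[j])
    clusters = [frozenset(s) for s in member_sets.values() if s]
    clusters.extend(frozenset([v]) for v in stray)
    clusters.sort(key=lambda c: min(c))
    return [Cluster(id=i, members=c) for i, c in enumerate(clusters)]


def label_clusters(
    clusters: Sequence[Cluster],
    effector_ids: set[str],
    dataset_of: Mapping[str, str],
) -> list[Cluster]:
    """Fill dataset membership and the contains_effector flag."""
    out = []
    for c in clusters:
        missing = [m for m in c.members if m not in dataset_of]
        if missing:
            raise KeyError(f"members with no dataset mapping: {sorted(missing)[:5]}")
        out.append(
            Cluster(
                id=c.id,
                members=c.members,
                datasets=frozenset(dataset_of[m] for m in c.members),
                contains_effector=bool(c.members & effector_ids),
            )
        )
    return out


def label_and_find_core(
    clusters: Sequence[Cluster],
    effector_ids: set[str],
    dataset_of: Mapping[str, str],
    min_datasets: int = 5,
    aphid_datasets: Iterable[str] | None = None,
) -> tuple[list[Cluster], list[Cluster]]:
    """Label clusters and select the core effector clusters.

    A cluster is core when it contains a candidate effector and is
    represented by at least ``min_datasets`` of the aphid datasets
    (outgroup datasets, i.e. those not in ``aphid_datasets``, do not
    count toward representation).  Returns (labelled clusters, core).
    """
    labelled = label_clusters(clusters, effector_ids, dataset_of)
    aphid = set(aphid_datasets) if aphid_datasets is not None else None
    core = []
    for c in labelled:
        counted = c.datasets if aphid is None else (c.datasets & aphid)
        if c.contains_effector and len(counted) >= min_datasets:
            core.append(c)
    return labelled, core


def find_pioneers(
    clusters: Sequence[Cluster],
    annotations: Mapping[str, AnnotationRecord],
    effector_ids: set[str],
    dataset_of: Mapping[str, str],
    genus_of: Mapping[str, str],
    db_evalue_threshold: float = 1e-5,
) -> list[Cluster]:
    """Effector clusters that look novel: hit-less, Pfam-less, one genus.

    A member counts as hit-less when its best database hit e-value is
    absent or above ``db_evalue_threshold``.  Clusters whose members'
    datasets span more than one genus are excluded (a single species
    trivially satisfies the single-genus rule).
    """
    labelled = label_clusters(clusters, effector_ids, dataset_of)
    pioneers = []
    for c in labelled:
        if not c.contains_effector:
            continue
        genera = set()
        for d in c.datasets:
            if d not in genus_of:
                raise KeyError(f"no genus mapping for dataset {d!r}")
            genera.add(genus_of[d])
        if len(genera) != 1:
            continue
        def _hitless(m: str) -> bool:
            a = annotations[m]
            no_hit = a.best_db_hit_evalue is None or a.best_db_hit_evalue > db_evalue_threshold
            return no_hit and not a.has_pfamA
        if all(_hitless(m) for m in c.members):
            pioneers.append(c)
    return pioneers
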