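"""Reciprocal best BLAST hit (RBBH) 1:1 orthologues and RBBH groups.

For each ordered dataset pair, a query's best hit is the highest
bitscore among hits passing the identity and query-coverage thresholds
(defaults 70% identity, 50% coverage).  Queries whose top bitscore is
tied between two or more subjects yield no best hit at all -- the tie
rejection that guards against recent gene duplicates masquerading as
orthologues.  A pair (a, b) is emitted only when each is the other's
unique best.  Pairs from all dataset combinations are then written as
abc edges (query, hit, e-value) and grouped with the same MCL engine
used for whole-repertoire clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cluster import MCLParams, evalue_weight, mcl_cluster
from .io_formats import SimilarityEdge

__all__ = ["RBBHPair", "RBBHGroup", "best_hits", "rbbh_pairs", "rbbh_groups"]


@dataclass
class RBBHPair:
    """A mutual-best 1:1 orthologue pair between two datasets."""

    id_a: str
    id_b: str
    dataset_a: str
    dataset_b: str
    identity: float
    coverage: float
    bitscore: float
    evalue: float  # min of the two directional e-values

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))  # type: ignore[return-value]


@dataclass
class RBBHGroup:
    """A connected set of RBBH pairs (expected <=1 member per dataset)."""

    id: int
    members: frozenset[str]
    contains_effector: bool = False


def best_hits(
    edges: Iterable[SimilarityEdge],
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
    *,
    bitscore_decimals: int = 1,
) -> dict[str, SimilarityEdge]:
    """Unique best hit per query, with tie rejection.

    Hits failing the identity or query-coverage filters are ignored;
    bitscores are compared after rounding to ``bitscore_decimals``
    (matching common BLAST reporting granularity), and a query whose
    rounded top score is shared by two or more subjects is dropped.
    """
    by_query: dict[str, list[SimilarityEdge]] = {}
    for e in edges:
        if e.identity >= min_identity and e.query_coverage >= min_coverage:
            by_query.setdefault(e.query, []).append(e)
    best: dict[str, SimilarityEdge] = {}
    for q, hits in by_query.items():
        top = max(round(h.bitscore, bitscore_decimals) for h in hits)
        top_hits = [h for h in hits if round(h.bitscore, bitscore_decimals) == top]
        if len({h.subject for h in top_hits}) == 1:
            best[q] = top_hits[0]
    return best


def rbbh_pairs(
    edges_ab: Iterable[SimilarityEdge],
    edges_ba: Iterable[SimilarityEdge],
    dataset_a: str,
    dataset_b: str,
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
    *,
    known_ids_a: set[str] | None = None,
    known_ids_b: set[str] | None = None,
    both_way_coverage: bool = False,
) -> list[RBBHPair]:
    """Reciprocal best-hit pairs between two datasets.

    ``edges_ab`` are hits with dataset-A queries, ``edges_ba`` the
    reverse direction.  Coverage is assessed on the query side of each
    direction (set ``both_way_coverage`` to additionally require the
    A->B alignment to cover half of B, i.e. treat coverage
    symmetrically).  Supplying ``known_ids_*`` turns unknown ids into
    errors instead of silent pass-through.
    """
    edges_ab = list(edges_ab)
    edges_ba = list(edges_ba)
    if known_ids_a is not None or known_ids_b is not None:
        for e in edges_ab:
            if known_ids_a is not None and e.query not in known_ids_a:
                raise KeyError(f"unknown query id {e.query!r} for dataset {dataset_a}")
            if known_ids_b is not None and e.subject not in known_ids_b:
                raise KeyError(f"unknown subject id {e.subject!r} for dataset {dataset_b}")
        for e in edges_ba:
            if known_ids_b is not None and e.query not in known_ids_b:
                raise KeyError(f"unknown query id {e.query!r} for dataset {dataset_b}")
            if known_ids_a is not None and e.subject not in known_ids_a:
                raise KeyError(f"unknown subject id {e.subject!r} for dataset {dataset_a}")
    if both_way_coverage:
        subj_len_b = {e.query: e.query_length for e in edges_ba}
        edges_ab = [
            e for e in edges_ab
            if e.query not in subj_len_b or e.subject not in subj_len_b
            or 100.0 * e.aln_length / subj_len_b[e.subject] >= min_coverage
        ]
    best_ab = best_hits(edges_ab, min_identity, min_coverage)
    best_ba = best_hits(edges_ba, min_identity, min_coverage)
    pairs: list[RBBHPair] = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject
        back = best_ba.get(b)
        if back is None or back.subject != a:
            continue
        pairs.append(
            RBBHPair(
                id_a=a,
                id_b=b,
                dataset_a=dataset_a,
                dataset_b=dataset_b,
                identity=hit.identity,
                coverage=hit.query_coverage,
                bitscore=hit.bitscore,
                evalue=min(hit.evalue, back.evalue),
            )
        )
    return pairs


def rbbh_groups(
    all_pairs: Sequence[RBBHPair],
    effector_ids: set[str] | None = None,
    inflation: float = 6.0,
) -> list[RBBHGroup]:
    """Group RBBH pairs into orthologue groups with the MCL engine.

    Pairs become abc-style edges weighted by -log10 of the smaller of
    the two directional e-values (capped as in the similarity graph);
    the resulting graph is clustered at the given inflation.
    """
    g = nx.Graph()
    for p in all_pairs:
        w = evalue_weight(p.evalue)
        if g.has_edge(p.id_a, p.id_b):
            g[p.id_a][p.id_b]["weight"] = max(g[p.id_a][p.id_b]["weight"], w)
        else:
            g.add_edge(p.id_a, p.id_b, weight=w)
    clusters = mcl_cluster(g, MCLParams(inflation=inflation))
    eff = effector_ids or set()
    return [
        RBBHGroup(id=c.id, members=c.members, contains_effector=bool(c.members & eff))
        for c in clusters
    ]


def abc_rows(all_pairs: Sequence[RBBHPair]) -> list[tuple[str, str, float]]:
    """abc file rows (query, hit, e-value) for the RBBH network."""
    return [(p.id_a, p.id_b, p.evalue) for p in all_pairs]
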