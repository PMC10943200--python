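"""Annotation-overlap redundancy reduction.

Proteins with near-identical GO annotation sets describe near-identical
functions, so keeping them all would leak between training and test splits.
Redundancy is measured directly on the annotation sets: the overlap of two
proteins is the intersection size divided by the *smaller* set's size (the
"larger value" of the two possible fractions). Proteins are clustered at a
90% overlap threshold and one representative is drawn per cluster.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import IO, Literal, Sequence

import networkx as nx
import numpy as np

from .go_corpus import AnnotationSet


def go_overlap(a: AnnotationSet, b: AnnotationSet) -> float:
    """Annotation overlap: |A ∩ B| / min(|A|, |B|).

    Equivalently the larger of the two fractions with either set as the
    denominator (a containment coefficient). Symmetric; 1.0 iff the smaller
    set is contained in the larger.
    """
    if not a.go_ids or not b.go_ids:
        raise ValueError("go_overlap requires non-empty annotation sets")
    inter = len(a.go_ids & b.go_ids)
    return inter / min(len(a.go_ids), len(b.go_ids))


@dataclass
class ClusterSet:
    """A partition of proteins into overlap clusters, with optional representatives."""

    clusters: list[frozenset[str]]
    threshold: float
    representatives: list[str] | None = None
    seed: int | None = None

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def __len__(self) -> int:
        return len(self.clusters)


def _overlap_edges(anns: Sequence[AnnotationSet], threshold: float):
    """Yield index pairs with overlap >= threshold, pruned via an inverted index."""
    by_go: dict[str, list[int]] = defaultdict(list)
    for i, a in enumerate(anns):
        for g in a.go_ids:
            by_go[g].append(i)
    seen: set[tuple[int, int]] = set()
    for members in by_go.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                pair = (members[ai], members[bi])
                if pair in seen:
                    continue
                seen.add(pair)
                if go_overlap(anns[pair[0]], anns[pair[1]]) >= threshold:
                    yield pair


def cluster_by_overlap(
    anns: Sequence[AnnotationSet],
    threshold: float = 0.90,
    method: Literal["components", "leader"] = "components",
) -> ClusterSet:
    """Cluster proteins whose annotation overlap is >= ``threshold``.

    The default rule takes connected components of the graph with an edge
    between every pair at or above threshold (single linkage), which
    guarantees every between-cluster pair falls below threshold. A greedy
    leader alternative (first unassigned protein becomes a leader; proteins
    join the first leader they overlap with) is available for comparison.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for a in anns:
        if not a.go_ids:
            raise ValueError(f"{a.accession}: empty annotation set")
    accs = [a.accession for a in anns]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in input")
    if not anns:
        return ClusterSet([], threshold)

    if method == "components":
        g = nx.Graph()
        g.add_nodes_from(range(len(anns)))
        g.add_edges_from(_overlap_edges(anns, threshold))
        comps = nx.connected_components(g)
        clusters = [frozenset(accs[i] for i in comp) for comp in comps]
    elif method == "leader":
        leaders: list[int] = []
        membership: dict[int, list[int]] = {}
        for i, a in enumerate(anns):
            for lead in leaders:
                if go_overlap(a, anns[lead]) >= threshold:
                    membership[lead].append(i)
                    break
            else:
                leaders.append(i)
                membership[i] = [i]
        clusters = [frozenset(accs[i] for i in members) for members in membership.values()]
    else:
        raise ValueError(f"unknown method: {method!r}")

    clusters.sort(key=lambda c: min(c))
    return ClusterSet(clusters, threshold)


def select_representatives(cs: ClusterSet, seed: int) -> ClusterSet:
    """Draw one member uniformly at random from each cluster (seeded)."""
    rng = np.random.default_rng(seed)
    reps = [sorted(c)[rng.integers(len(c))] for c in cs.clusters]
    return ClusterSet(cs.clusters, cs.threshold, representatives=reps, seed=seed)


def write_cluster_tsv(cs: ClusterSet, stream: IO[str]) -> None:
    """Report: accession<TAB>cluster_id<TAB>is_representative."""
    reps = set(cs.representatives or [])
    for cid, cluster in enumerate(cs.clusters):
        for acc in sorted(cluster):
            stream.write(f"{acc}\t{cid}\t{int(acc in reps)}\n")
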