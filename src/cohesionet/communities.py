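"""Modularity communities, hubs, and centrality seed rankings.

Community structure is detected by Louvain-style greedy modularity
maximization.  The largest communities ("principal communities") are the
ones that together cover a requested share of nodes; within a community,
hubs are its members whose whole-graph degree strictly exceeds a
threshold.  Five centrality metrics (degree, betweenness, closeness,
k-core number, PageRank) produce seed-node rankings whose top-n overlap
is summarized as a Jaccard matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

CENTRALITY_METRICS = ("degree", "betweenness", "closeness", "kcore", "pagerank")


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float
    resolution: float
    seed: int

    def communities(self) -> dict[int, list]:
        """label -> sorted member list."""
        out: dict[int, list] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, []).append(node)
        return {label: sorted(members) for label, members in out.items()}

    def sizes(self) -> dict[int, int]:
        return {label: len(m) for label, m in self.communities().items()}

    def to_dict(self) -> dict:
        sizes = self.sizes()
        return {
            "n_communities": len(sizes),
            "sizes": dict(sorted(sizes.items())),
            "modularity": self.modularity,
            "resolution": self.resolution,
            "seed": self.seed,
        }


@dataclass
class CentralityRanking:
    metric: str
    top: list[tuple[str, float]]  # (node, score), score descending

    def top_nodes(self) -> list[str]:
        return [node for node, _ in self.top]


@dataclass
class CentralityRankingSet:
    rankings: dict[str, CentralityRanking]
    overlap: dict[str, dict[str, float]] = field(default_factory=dict)
    top_n: int = 10

    def to_dict(self) -> dict:
        return {
            "top_n": self.top_n,
            "top": {m: r.top for m, r in self.rankings.items()},
            "overlap": self.overlap,
        }


def detect_communities(g: nx.Graph, resolution: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Louvain greedy modularity maximization, reproducible given seed.

    Community labels are assigned in decreasing size order (ties broken
    by smallest member id) so that label 0 is always the largest
    community.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    if g.number_of_edges() == 0:
        comms = [{n} for n in g.nodes]
        mod = 0.0
    else:
        comms = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
        mod = float(nx.community.modularity(g, comms, resolution=resolution))
    ordered = sorted(comms, key=lambda c: (-len(c), min(str(n) for n in c)))
    assignment = {node: label for label, comm in enumerate(ordered) for node in comm}
    return CommunityPartition(assignment=assignment, modularity=mod,
                              resolution=resolution, seed=seed)


def principal_communities(p: CommunityPartition, coverage: float = 0.83) -> list[int]:
    """Smallest prefix of size-sorted communities covering >= ``coverage``.

    Returns community labels, largest first.  The boundary is inclusive:
    a prefix reaching exactly the coverage share suffices.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    sizes = p.sizes()
    total = sum(sizes.values())
    ordered = sorted(sizes, key=lambda label: (-sizes[label], label))
    out, acc = [], 0
    for label in ordered:
        out.append(label)
        acc += sizes[label]
        if acc / total >= coverage:
            break
    return out


def community_hubs(g: nx.Graph, p: CommunityPartition, community: int,
                   degree_threshold: int = 300) -> list[str]:
    """Members of ``community`` whose whole-graph degree strictly exceeds
    ``degree_threshold``, sorted by degree descending (id ascending on ties)."""
    members = p.communities().get(community)
    if members is None:
        raise KeyError(f"no community labelled {community!r}")
    hubs = [n for n in members if g.degree(n) > degree_threshold]
    return sorted(hubs, key=lambda n: (-g.degree(n), str(n)))


def _scores(g: nx.Graph, metric: str) -> dict:
    if metric == "degree":
        return dict(g.degree)
    if metric == "betweenness":
        return nx.betweenness_centrality(g, normalized=True)
    if metric == "closeness":
        # classic geodesic closeness within each node's component
        return nx.closeness_centrality(g, wf_improved=False)
    if metric == "kcore":
        h = nx.Graph(g)
        h.remove_edges_from(nx.selfloop_edges(h))
        return nx.core_number(h)
    if metric == "pagerank":
        return nx.pagerank(g, alpha=0.85, tol=1e-9, max_iter=1000)
    raise ValueError(f"unknown centrality metric {metric!r}")


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def centrality_rankings(g: nx.Graph, top_n: int = 10) -> CentralityRankingSet:
    """Top-n seed rankings under five centrality metrics plus their
    pairwise Jaccard overlap.  Ties break by node id for determinism."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty graph")
    rankings = {}
    for metric in CENTRALITY_METRICS:
        scores = _scores(g, metric)
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
        rankings[metric] = CentralityRanking(
            metric=metric, top=[(n, float(s)) for n, s in ordered[:top_n]]
        )
    overlap = {
        m1: {
            m2: _jaccard(set(rankings[m1].top_nodes()), set(rankings[m2].top_nodes()))
            for m2 in CENTRALITY_METRICS
        }
        for m1 in CENTRALITY_METRICS
    }
    return CentralityRankingSet(rankings=rankings, overlap=overlap, top_n=top_n)
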