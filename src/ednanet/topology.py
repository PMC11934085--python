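"""Topological characterization of co-occurrence networks and food webs.

Conventions (they matter for directed graphs):

* average neighbours counts DISTINCT adjacent nodes ignoring edge
  direction, so a reciprocal consumer pair contributes one neighbour to
  each endpoint, not two;
* shortest paths on directed graphs follow edge direction; eccentricity
  is taken over the nodes actually reachable from a node, and the radius
  is the minimum POSITIVE eccentricity (nodes that reach nothing are
  excluded) — the convention under which a top predator whose prey are
  all basal attains radius 1;
* the characteristic path length averages distances over all ordered
  reachable pairs;
* the clustering coefficient is the mean local clustering on the
  undirected projection over nodes with at least two neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TopologyReport",
    "topology_report",
    "centralities",
    "keystones",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching conventional report formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    avg_neighbours: float
    diameter: int | None
    radius: int | None
    char_path_length: float | None
    clustering_coefficient: float | None
    density: float
    directed: bool

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self) -> dict:
        """Display-precision view (2 dp, 3 dp for avg. neighbours)."""
        d = self.to_dict()
        d["avg_neighbours"] = round_half_up(self.avg_neighbours, 3)
        for key in ("char_path_length", "clustering_coefficient", "density"):
            if d[key] is not None:
                d[key] = round_half_up(d[key], 2)
        return d


def _distances(g: nx.Graph | nx.DiGraph) -> dict:
    return dict(nx.all_pairs_shortest_path_length(g))


def topology_report(g: nx.Graph | nx.DiGraph) -> TopologyReport:
    """Compute the standard topology statistics under the module conventions."""
    directed = g.is_directed()
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("graph must have at least one node")
    e = g.number_of_edges()
    u = g.to_undirected() if directed else g
    avg_neighbours = float(np.mean([len(set(u.neighbors(v))) for v in u.nodes]))
    if n > 1:
        density = e / (n * (n - 1)) if directed else 2 * e / (n * (n - 1))
    else:
        density = 0.0
    if e == 0:
        return TopologyReport(n, 0, 0.0, None, None, None, None, 0.0, directed)
    dist = _distances(g)
    eccs: list[int] = []
    all_d: list[int] = []
    for v, dd in dist.items():
        ds = [d for t, d in dd.items() if t != v]
        all_d.extend(ds)
        if ds:
            eccs.append(max(ds))
    diameter = max(eccs) if eccs else None
    radius = min(eccs) if eccs else None
    cpl = float(np.mean(all_d)) if all_d else None
    local = nx.clustering(u)
    eligible = [local[v] for v in u.nodes if len(set(u.neighbors(v))) >= 2]
    clustering = float(np.mean(eligible)) if eligible else None
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        avg_neighbours=avg_neighbours,
        diameter=diameter,
        radius=radius,
        char_path_length=cpl,
        clustering_coefficient=clustering,
        density=float(density),
        directed=directed,
    )


def centralities(g: nx.Graph | nx.DiGraph) -> pd.DataFrame:
    """Degree, closeness and betweenness per node.

    Degree is taken on the undirected projection (number of distinct
    neighbours).  Closeness uses outgoing distances with the
    Wasserman-Faust reachable-set normalization, so isolated nodes get 0.
    Betweenness is shortest-path betweenness with pair normalization.
    """
    u = g.to_undirected() if g.is_directed() else g
    degree = {v: len(set(u.neighbors(v))) for v in u.nodes}
    # networkx measures closeness over INCOMING paths on digraphs; reverse
    # to follow outgoing (consumer->resource) distances instead.
    h = g.reverse() if g.is_directed() else g
    closeness = nx.closeness_centrality(h, wf_improved=True)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    rows = [
        {
            "otu_id": v,
            "degree": degree[v],
            "closeness": closeness[v],
            "betweenness": betweenness[v],
        }
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows).set_index("otu_id", drop=False)


def keystones(
    centrality: pd.DataFrame, k: int = 10, by: str = "degree"
) -> list[str]:
    """Top-``k`` candidate keystone OTUs by a centrality column.

    Ties break by higher closeness, then lexicographic id.  If the graph
    has fewer than ``k`` nodes, all are returned (still ranked).
    """
    if by not in {"degree", "closeness", "betweenness"}:
        raise ValueError(f"unknown centrality {by!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        centrality.itertuples(),
        key=lambda r: (-getattr(r, by), -r.closeness, r.otu_id),
    )
    return [r.otu_id for r in ranked[:k]]
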