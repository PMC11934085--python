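"""Cross-network comparison statistics.

Edge identity across subsets is the unordered OTU pair; the sign is
ignored for matching (a pair positive in one subset and negative in
another still counts as shared) but sign agreement is reported
separately.  Percentages are displayed as integer percents, half-up.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index import IndexTable
from .inference import CoocNetwork
from .topology import round_half_up

__all__ = [
    "sign_fractions",
    "edge_overlap",
    "abundance_degree_correlation",
    "keystone_overlap",
]

Pair = tuple[str, str]


def _edge_signs(network) -> dict[Pair, str]:
    if isinstance(network, CoocNetwork):
        return {e.pair: e.sign for e in network.edges}
    # plain networkx graph with optional 'sign' attributes
    out = {}
    for a, b, data in network.edges(data=True):
        key = tuple(sorted((a, b)))
        out[key] = data.get("sign", "copresence")
    return out


def sign_fractions(network) -> dict[str, float] | None:
    """Fractions of co-presence and mutual-exclusion edges; None if empty."""
    signs = _edge_signs(network)
    if not signs:
        return None
    n = len(signs)
    n_pos = sum(1 for s in signs.values() if s == "copresence")
    return {
        "fraction_copresence": n_pos / n,
        "fraction_exclusion": (n - n_pos) / n,
        "n_edges": n,
    }


def edge_overlap(networks: Mapping[str, object]) -> pd.DataFrame:
    """Pairwise shared-edge statistics over named networks.

    For each network pair: shared count, per-network unique counts, union
    size, percent shared of the union (integer percent, half-up) and the
    number of shared edges whose signs agree.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks to overlap")
    signs = {name: _edge_signs(net) for name, net in networks.items()}
    names = list(networks)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            ea, eb = set(signs[na]), set(signs[nb])
            shared = ea & eb
            union = ea | eb
            agree = sum(1 for p in shared if signs[na][p] == signs[nb][p])
            pct = round_half_up(100.0 * len(shared) / len(union), 0) if union else 0.0
            rows.append(
                {
                    "network_a": na,
                    "network_b": nb,
                    "shared": len(shared),
                    "unique_a": len(ea - eb),
                    "unique_b": len(eb - ea),
                    "union": len(union),
                    "percent_shared": pct,
                    "sign_agreement": agree,
                }
            )
    return pd.DataFrame(rows)


def pooled_edge_overlap(
    group_a: Mapping[str, object], group_b: Mapping[str, object]
) -> dict:
    """Overlap between two POOLED groups of networks (duplicates removed
    within each group) — e.g. all temporal subsets vs all spatial subsets."""
    ea: set[Pair] = set()
    for net in group_a.values():
        ea |= set(_edge_signs(net))
    eb: set[Pair] = set()
    for net in group_b.values():
        eb |= set(_edge_signs(net))
    shared, union = ea & eb, ea | eb
    return {
        "shared": len(shared),
        "unique_a": len(ea - eb),
        "unique_b": len(eb - ea),
        "union": len(union),
        "percent_shared": round_half_up(100.0 * len(shared) / len(union), 0)
        if union
        else 0.0,
    }


def abundance_degree_correlation(
    index: IndexTable, network
) -> tuple[float, float] | None:
    """Pearson correlation between mean eDNA index and node degree.

    Abundance is the per-OTU mean index over the subset's samples — the
    analysis-facing relative-abundance measure, not raw reads.  Returns
    (r, two-sided p) or None when degenerate (constant degree or
    abundance, or fewer than 3 nodes).
    """
    g = network.graph() if isinstance(network, CoocNetwork) else network
    nodes = sorted(g.nodes)
    missing = [v for v in nodes if v not in set(index.otu_ids)]
    if missing:
        raise ValueError(f"network nodes absent from index table: {missing}")
    if len(nodes) < 3:
        return None
    abundance = index.values.loc[nodes].mean(axis=1).to_numpy()
    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    if np.ptp(abundance) == 0 or np.ptp(degree) == 0:
        return None
    r, p = stats.pearsonr(abundance, degree)
    return float(r), float(p)


def keystone_overlap(lists: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Membership of each keystone OTU across named networks.

    Returns one row per OTU appearing in any list, with boolean columns
    per network and a multiplicity count.
    """
    if len(lists) < 2:
        raise ValueError("need at least two keystone lists")
    names = list(lists)
    otus = sorted({o for lst in lists.values() for o in lst})
    rows = []
    for otu in otus:
        row: dict = {"otu_id": otu}
        for name in names:
            row[name] = otu in set(lists[name])
        row["multiplicity"] = sum(row[name] for name in names)
        rows.append(row)
    return pd.DataFrame(rows, columns=["otu_id", *names, "multiplicity"])
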