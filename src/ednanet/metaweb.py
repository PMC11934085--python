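"""Meta-web food-web construction and trophic matching.

A meta-web is the cumulative set of all potential consumer-resource links
for a species pool, assembled from diet records (databases plus
literature).  Restricting the meta-web to the OTUs actually detected (and
surviving the prevalence filter) yields the local food web.  Edges are
stored consumer -> resource (predator points to prey); the convention is
recorded on the graph so path-based statistics stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .otu_io import OtuTable, OtuTableError

__all__ = [
    "DietRecord",
    "read_diet_records",
    "write_diet_records",
    "build_metaweb",
    "assign_trophic_levels",
    "trophic_match",
    "DIRECTION_CONVENTION",
]

DIRECTION_CONVENTION = "consumer->resource"


@dataclass(frozen=True)
class DietRecord:
    """One documented consumer-resource interaction."""

    consumer_otu: str
    resource_otu: str
    source: str = ""


def read_diet_records(path: str | Path) -> list[DietRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"consumer_otu", "resource_otu"}
    missing = required - set(df.columns)
    if missing:
        raise OtuTableError(f"diet records missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    return [
        DietRecord(str(r.consumer_otu), str(r.resource_otu), str(r.source))
        for r in df.itertuples()
    ]


def write_diet_records(records: Sequence[DietRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("consumer_otu\tresource_otu\tsource\n")
        for r in records:
            fh.write(f"{r.consumer_otu}\t{r.resource_otu}\t{r.source}\n")


def build_metaweb(
    records: Iterable[DietRecord],
    community: OtuTable,
    synonyms: Mapping[str, str] | None = None,
    allow_cannibalism: bool = False,
) -> nx.DiGraph:
    """Local food web: diet records restricted to the detected community.

    ``community`` must already be subset- and prevalence-filtered.  Nodes
    are ALL community OTUs, including isolated ones (detected species
    with no documented interactions still belong to the web).  Records
    naming a finer taxon than an OTU label are resolved through the
    explicit ``synonyms`` table (record name -> OTU id); no fuzzy
    matching.  Duplicate records collapse to one edge; records with an
    endpoint outside the community are skipped and counted.
    """
    synonyms = dict(synonyms or {})
    otu_ids = community.otu_ids if isinstance(community, OtuTable) else list(community)
    members = set(otu_ids)
    web = nx.DiGraph(direction=DIRECTION_CONVENTION)
    web.add_nodes_from(otu_ids)
    n_skipped = 0
    n_self = 0
    for rec in records:
        c = synonyms.get(rec.consumer_otu, rec.consumer_otu)
        r = synonyms.get(rec.resource_otu, rec.resource_otu)
        if c not in members or r not in members:
            n_skipped += 1
            continue
        if c == r and not allow_cannibalism:
            n_self += 1
            continue
        web.add_edge(c, r)
    web.graph["n_records_skipped"] = n_skipped
    web.graph["n_self_loops_skipped"] = n_self
    return web


def assign_trophic_levels(web: nx.DiGraph, otu_meta: pd.DataFrame) -> nx.DiGraph:
    """Attach a trophic level to every node.

    Rules: algae and fungi (primary producers and decomposers) are level
    1; invertebrates are level 2; vertebrates take their database-derived
    value from the metadata.  An explicit ``trophic_level`` in the
    metadata always wins over the group rule.  Nodes that cannot be
    classified raise an error listing them.
    """
    web = web.copy()
    unresolved: list[str] = []
    for node in web.nodes:
        level: float | None = None
        if node in otu_meta.index:
            row = otu_meta.loc[node]
            tl = row.get("trophic_level")
            if tl is not None and pd.notna(tl):
                level = float(tl)
            else:
                group = row.get("group")
                if group in {"algae", "fungi"}:
                    level = 1.0
                elif group == "invertebrate":
                    level = 2.0
        if level is None:
            unresolved.append(node)
        else:
            web.nodes[node]["trophic_level"] = level
    if unresolved:
        raise OtuTableError(
            f"no trophic level assignable for nodes: {sorted(unresolved)}"
        )
    return web


def trophic_match(network, web: nx.DiGraph) -> tuple[pd.DataFrame, int, float]:
    """Label co-occurrence edges that coincide with a trophic link.

    A network edge A-B counts as trophic iff A->B or B->A is in the food
    web (direction-blind match).  Returns the labelled edge table, the
    count of trophic edges and their fraction of all network edges.
    ``network`` may be a :class:`~ednanet.inference.CoocNetwork` or any
    undirected :class:`networkx.Graph`.
    """
    g = network.graph() if hasattr(network, "graph") and callable(network.graph) else network
    rows = []
    n_trophic = 0
    for a, b in sorted(map(tuple, map(sorted, g.edges()))):
        is_trophic = web.has_edge(a, b) or web.has_edge(b, a)
        n_trophic += bool(is_trophic)
        rows.append({"otu_a": a, "otu_b": b, "trophic": bool(is_trophic)})
    table = pd.DataFrame(rows, columns=["otu_a", "otu_b", "trophic"])
    n_edges = len(rows)
    fraction = n_trophic / n_edges if n_edges else 0.0
    return table, n_trophic, fraction
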