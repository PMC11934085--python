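"""End-to-end orchestration: subsets -> index -> network -> food web -> reports.

Per analysis subset the stages run in the order the analysis assumes:
sample subsetting first, then the prevalence filter (occupancy is
relative to the subset), then the eDNA index (the row maximum is taken
within the subset by default), then ensemble merging across markers,
network inference, food-web restriction and topology.  A final
comparison step pools the per-subset networks.  Reruns with the same
config file and seed are byte-identical; every output embeds the config
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import networkx as nx
import yaml

from . import compare as cmp
from .index import IndexTable, ensemble_index, index_from_table, write_index_table
from .inference import CoocNetwork, InferenceConfig, infer_network
from .metaweb import assign_trophic_levels, build_metaweb, read_diet_records, trophic_match
from .otu_io import (
    OtuTable,
    OtuTableError,
    SubsetSpec,
    prevalence_filter,
    read_otu_metadata,
    read_otu_table,
    read_sample_metadata,
    subset_samples,
)
from .topology import centralities, keystones, topology_report

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("ednanet")


@dataclass(frozen=True)
class RunConfig:
    otu_tables: dict[str, str]  # marker label -> TSV path
    sample_metadata: str
    otu_metadata: str
    outdir: str
    diet_records: str | None = None
    subsets: tuple[SubsetSpec, ...] = ()
    min_prevalence: float = 0.25
    index_scope: str = "subset"  # or "global"
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    keystone_k: int = 10

    def validate_paths(self) -> None:
        paths = [self.sample_metadata, self.otu_metadata, *self.otu_tables.values()]
        if self.diet_records:
            paths.append(self.diet_records)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise OtuTableError(f"missing input files: {missing}")

    def config_hash(self) -> str:
        payload = {
            "otu_tables": dict(sorted(self.otu_tables.items())),
            "sample_metadata": self.sample_metadata,
            "otu_metadata": self.otu_metadata,
            "diet_records": self.diet_records,
            "subsets": [vars(s) | {"months": sorted(s.months) if s.months else None,
                                    "sample_ids": list(s.sample_ids) if s.sample_ids else None}
                        for s in self.subsets],
            "min_prevalence": self.min_prevalence,
            "index_scope": self.index_scope,
            "inference": self.inference.to_dict(),
            "keystone_k": self.keystone_k,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subset_from_dict(d: Mapping) -> SubsetSpec:
    d = dict(d)
    if "months" in d and d["months"] is not None:
        d["months"] = frozenset(d["months"])
    if "sample_ids" in d and d["sample_ids"] is not None:
        d["sample_ids"] = tuple(d["sample_ids"])
    return SubsetSpec(**d)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    inference = InferenceConfig(**{**raw.get("inference", {}),
                                   "metrics": tuple(raw.get("inference", {}).get(
                                       "metrics", InferenceConfig().metrics))})
    subsets = tuple(_subset_from_dict(s) for s in raw.get("subsets", []))
    return RunConfig(
        otu_tables=dict(raw["otu_tables"]),
        sample_metadata=raw["sample_metadata"],
        otu_metadata=raw["otu_metadata"],
        diet_records=raw.get("diet_records"),
        outdir=raw["outdir"],
        subsets=subsets,
        min_prevalence=float(raw.get("min_prevalence", 0.25)),
        index_scope=raw.get("index_scope", "subset"),
        inference=inference,
        keystone_k=int(raw.get("keystone_k", 10)),
    )


def _subset_index(
    table: OtuTable,
    meta: pd.DataFrame,
    spec: SubsetSpec | None,
    min_prevalence: float,
    scope: str,
) -> IndexTable:
    """Subset, prevalence-filter and index one marker table."""
    sub = subset_samples(table, meta, spec) if spec is not None else table
    filt = prevalence_filter(sub, min_prevalence)
    if scope == "subset" or spec is None:
        return index_from_table(filt)
    # global scope: the row maximum is taken over ALL samples, then the
    # subset's columns are extracted for the filtered OTUs
    full = index_from_table(table)
    values = full.values.loc[filt.otu_ids, filt.sample_ids]
    prov = {o: full.provenance[o] for o in filt.otu_ids}
    abund = (
        full.abundances.loc[filt.otu_ids, filt.sample_ids]
        if full.abundances is not None
        else None
    )
    return IndexTable(values=values, provenance=prov, abundances=abund)


def _build_subset_network(
    tables: Mapping[str, OtuTable],
    meta: pd.DataFrame,
    spec: SubsetSpec | None,
    config: RunConfig,
) -> tuple[IndexTable, CoocNetwork]:
    indices = [
        _subset_index(t, meta, spec, config.min_prevalence, config.index_scope)
        for t in tables.values()
    ]
    merged = reduce(ensemble_index, indices)
    network = infer_network(merged, config.inference)
    return merged, network


def _write_tsv_with_hash(df: pd.DataFrame, path: Path, cfg_hash: str, **kw) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report bundle; returns the report dict."""
    config.validate_paths()
    cfg_hash = config.config_hash()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start (config hash %s)", cfg_hash)

    tables = {
        marker: read_otu_table(path, marker=marker)
        for marker, path in sorted(config.otu_tables.items())
    }
    sample_meta = read_sample_metadata(config.sample_metadata)
    otu_meta = read_otu_metadata(config.otu_metadata)
    diet = read_diet_records(config.diet_records) if config.diet_records else []

    subsets: Sequence[SubsetSpec | None] = config.subsets or (None,)
    report: dict = {"config_hash": cfg_hash, "subsets": {}}
    networks: dict[str, CoocNetwork] = {}
    indices: dict[str, IndexTable] = {}
    keystone_lists: dict[str, list[str]] = {}

    for spec in subsets:
        name = spec.name if spec is not None else "all"
        log.info("subset %s", name)
        index, network = _build_subset_network(tables, sample_meta, spec, config)
        networks[name] = network
        indices[name] = index
        write_index_table(index, outdir / f"{name}.index.tsv")
        network.write_edge_table(outdir / f"{name}.edges.tsv")
        g = network.graph()
        g.graph["config_hash"] = cfg_hash
        nx.write_graphml(g, outdir / f"{name}.cooc.graphml")

        entry: dict = {
            "n_samples": index.n_samples,
            "cooc_topology": topology_report(g).rounded(),
            "sign_fractions": cmp.sign_fractions(network),
            "provenance": network.provenance,
        }
        cent = centralities(g)
        keystone_lists[name] = keystones(cent, k=config.keystone_k, by="degree")
        entry["keystones_degree"] = keystone_lists[name]
        _write_tsv_with_hash(
            cent.reset_index(drop=True), outdir / f"{name}.centrality.tsv", cfg_hash
        )
        ad = cmp.abundance_degree_correlation(index, network)
        entry["abundance_degree"] = (
            {"r": ad[0], "p": ad[1]} if ad is not None else None
        )

        if diet:
            web = build_metaweb(diet, index.otu_ids)
            web = assign_trophic_levels(web, otu_meta)
            web.graph["config_hash"] = cfg_hash
            nx.write_graphml(web, outdir / f"{name}.foodweb.graphml")
            entry["foodweb_topology"] = topology_report(web).rounded()
            match_table, n_trophic, frac = trophic_match(network, web)
            _write_tsv_with_hash(
                match_table, outdir / f"{name}.trophic_match.tsv", cfg_hash
            )
            entry["trophic_match"] = {
                "n_trophic_edges": n_trophic,
                "fraction_trophic": frac,
            }
            web_cent = centralities(web)
            entry["foodweb_keystones_degree"] = keystones(
                web_cent, k=config.keystone_k, by="degree"
            )
        report["subsets"][name] = entry

    if len(networks) >= 2:
        overlap = cmp.edge_overlap(networks)
        _write_tsv_with_hash(overlap, outdir / "edge_overlap.tsv", cfg_hash)
        report["edge_overlap"] = overlap.to_dict(orient="records")
        report["keystone_overlap"] = cmp.keystone_overlap(keystone_lists).to_dict(
            orient="records"
        )
        temporal = {n: networks[n] for n, s in zip(networks, subsets)
                    if s is not None and s.kind == "temporal"}
        spatial = {n: networks[n] for n, s in zip(networks, subsets)
                   if s is not None and s.kind == "spatial"}
        if temporal and spatial:
            report["pooled_temporal_vs_spatial"] = cmp.pooled_edge_overlap(
                temporal, spatial
            )

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline done: %s", outdir / "report.json")
    return report
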