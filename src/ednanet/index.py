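"""The eDNA index: scaled relative abundance per OTU.

Read counts are compositional — each sample sums to its sequencing depth —
so raw counts are not comparable across samples.  The index used here
first closes each sample to proportions, then rescales each OTU row by its
maximum proportion, yielding a within-OTU relative abundance in [0, 1]
that is comparable across samples under the assumption of constant
per-taxon amplification efficiency.  Indices from two primer sets covering
the same OTU are averaged per sample into an ensemble index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .otu_io import OtuTable, OtuTableError

__all__ = [
    "IndexTable",
    "to_proportions",
    "edna_index",
    "ensemble_index",
    "concat_index_tables",
    "write_index_table",
    "read_index_table",
]


@dataclass(frozen=True)
class IndexTable:
    """Per-OTU scaled relative abundances in [0, 1].

    ``provenance`` maps each OTU id to the tuple of markers whose reads
    contributed to its row.  ``abundances`` optionally retains the
    underlying relative-abundance (proportion-scale) matrix the index was
    derived from; the permutation null uses it to recompute each sample's
    compositional normalization, which an index-scale matrix cannot
    support (every row carries its own scaling constant).
    """

    values: pd.DataFrame
    provenance: dict[str, tuple[str, ...]]
    abundances: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and ((v < 0) | (v > 1 + 1e-12)).any():
            raise OtuTableError("index values must lie in [0, 1]")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise OtuTableError("duplicate OTU or sample ids in index table")
        if self.abundances is not None:
            if self.abundances.shape != self.values.shape:
                raise OtuTableError("abundances must mirror the index layout")
            if (self.abundances.to_numpy() < 0).any():
                raise OtuTableError("abundances must be non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_otus(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def to_proportions(table: OtuTable) -> pd.DataFrame:
    """Close each sample column to proportions (columns sum to 1).

    A sample with zero total reads carries no compositional information
    and is rejected; the caller should drop it upstream.
    """
    counts = table.counts
    sums = counts.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise OtuTableError(f"zero-read sample(s): {zero}")
    return counts / sums


def edna_index(proportions: pd.DataFrame, marker: str = "") -> IndexTable:
    """Scale each OTU row of a proportion matrix by its row maximum.

    ``index[i, j] = p[i, j] / max_j p[i, j]``; an all-zero row stays all
    zero (0/0 is defined as 0 so the transform is total — such OTUs are
    removed by the prevalence filter in any real analysis).
    """
    p = proportions.to_numpy(dtype=float)
    if p.size and ((p < 0) | (p > 1 + 1e-12)).any():
        raise OtuTableError("proportions must lie in [0, 1]")
    row_max = p.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(row_max > 0, p / np.where(row_max > 0, row_max, 1.0), 0.0)
    out = pd.DataFrame(values, index=proportions.index, columns=proportions.columns)
    prov = {otu: (marker,) if marker else () for otu in out.index}
    return IndexTable(values=out, provenance=prov, abundances=proportions.astype(float))


def index_from_table(table: OtuTable) -> IndexTable:
    """Convenience: proportions then index, tagged with the table's marker."""
    return edna_index(to_proportions(table), marker=table.marker)


def ensemble_index(a: IndexTable, b: IndexTable) -> IndexTable:
    """Merge two marker-specific index tables over the same samples.

    OTUs detected by both markers get the per-sample arithmetic mean of
    the two indices; OTUs detected by only one marker pass through
    unchanged.  Symmetric in its arguments.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        raise OtuTableError("ensemble_index requires identical sample sets")
    cols = a.sample_ids
    shared = [o for o in a.otu_ids if o in set(b.otu_ids)]
    only_a = [o for o in a.otu_ids if o not in set(b.otu_ids)]
    only_b = [o for o in b.otu_ids if o not in set(a.otu_ids)]
    order = a.otu_ids + only_b
    prov: dict[str, tuple[str, ...]] = {}
    for o in shared:
        prov[o] = tuple(a.provenance.get(o, ())) + tuple(b.provenance.get(o, ()))
    for o in only_a:
        prov[o] = tuple(a.provenance.get(o, ()))
    for o in only_b:
        prov[o] = tuple(b.provenance.get(o, ()))

    def merge(da: pd.DataFrame, db: pd.DataFrame) -> pd.DataFrame:
        parts = []
        if shared:
            parts.append((da.loc[shared, cols] + db.loc[shared, cols]) / 2.0)
        if only_a:
            parts.append(da.loc[only_a, cols])
        if only_b:
            parts.append(db.loc[only_b, cols])
        merged = pd.concat(parts) if parts else da.iloc[:0]
        return merged.loc[order]

    values = merge(a.values, b.values)
    abund = None
    if a.abundances is not None and b.abundances is not None:
        abund = merge(a.abundances, b.abundances)
    return IndexTable(values=values, provenance=prov, abundances=abund)


def concat_index_tables(tables: Sequence[IndexTable]) -> IndexTable:
    """Row-concatenate index tables with disjoint OTU ids over shared samples."""
    if not tables:
        raise OtuTableError("no index tables to concatenate")
    first = tables[0]
    if len(tables) == 1:
        return first
    cols = first.sample_ids
    seen: set[str] = set()
    parts = []
    abund_parts: list[pd.DataFrame] | None = []
    prov: dict[str, tuple[str, ...]] = {}
    for t in tables:
        if set(t.sample_ids) != set(cols):
            raise OtuTableError("concat_index_tables requires identical sample sets")
        overlap = seen & set(t.otu_ids)
        if overlap:
            raise OtuTableError(f"duplicate otu_id across tables: {sorted(overlap)}")
        seen |= set(t.otu_ids)
        parts.append(t.values[cols])
        if abund_parts is not None and t.abundances is not None:
            abund_parts.append(t.abundances[cols])
        else:
            abund_parts = None
        prov.update(t.provenance)
    abund = pd.concat(abund_parts) if abund_parts else None
    return IndexTable(values=pd.concat(parts), provenance=prov, abundances=abund)


def write_index_table(index: IndexTable, path: str | Path) -> None:
    """Write index values as TSV plus ``.provenance.tsv`` and (when the
    table carries them) ``.abundances.tsv`` side-cars."""
    path = Path(path)
    out = index.values.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")
    side = path.with_suffix(path.suffix + ".provenance.tsv")
    with open(side, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tmarkers\n")
        for otu in index.otu_ids:
            fh.write(f"{otu}\t{','.join(index.provenance.get(otu, ()))}\n")
    if index.abundances is not None:
        ab = index.abundances.copy()
        ab.index.name = "otu_id"
        ab.to_csv(path.with_suffix(path.suffix + ".abundances.tsv"), sep="\t")


def read_index_table(path: str | Path) -> IndexTable:
    """Inverse of :func:`write_index_table`; side-cars are optional."""
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    prov: dict[str, tuple[str, ...]] = {str(o): () for o in values.index}
    side = path.with_suffix(path.suffix + ".provenance.tsv")
    if side.exists():
        df = pd.read_csv(side, sep="\t", dtype=str).fillna("")
        for row in df.itertuples():
            prov[str(row.otu_id)] = tuple(m for m in str(row.markers).split(",") if m)
    ab_path = path.with_suffix(path.suffix + ".abundances.tsv")
    abundances = (
        pd.read_csv(ab_path, sep="\t", index_col=0) if ab_path.exists() else None
    )
    return IndexTable(values=values, provenance=prov, abundances=abundances)
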