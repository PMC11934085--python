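"""Reading, validation, filtering and subsetting of OTU read-count tables.

The observation unit throughout is a wide table of non-negative integer
read counts with OTUs as rows and water samples as columns, one table per
primer set (marker).  Sample metadata carries the calendar month and the
distance from shore used to define the temporal and spatial analysis
subsets; OTU metadata carries taxon name, coarse taxonomic group and
(for vertebrates) a database-derived trophic level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "OtuTableError",
    "SubsetSpec",
    "NEARSHORE_PRESETS",
    "GROUP_VOCABULARY",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "read_otu_metadata",
    "prevalence_filter",
    "subset_samples",
]

#: Closed vocabulary for the coarse taxonomic group of an OTU.
GROUP_VOCABULARY = frozenset(
    {"fish", "mammal", "bird", "invertebrate", "algae", "fungi", "other"}
)

#: Named nearshore/offshore boundary presets (metres from shore).  The two
#: values correspond to the two boundary definitions in common use for the
#: Moray Firth surveys; neither is a silent default — the caller must pick.
NEARSHORE_PRESETS = {
    "nearshore_1200m": 1200.0,
    "nearshore_1000m": 1000.0,
}


class OtuTableError(ValueError):
    """Raised for malformed OTU tables or metadata."""


@dataclass(frozen=True)
class OtuTable:
    """A samples-by-OTUs read-count table for one primer set.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows indexed by OTU id,
        columns by sample id.
    marker
        Label of the primer set / barcode the reads came from.
    removed_otus
        Provenance: OTU ids dropped by upstream filtering steps.
    """

    counts: pd.DataFrame
    marker: str = ""
    removed_otus: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise OtuTableError("OTU table needs at least one OTU and one sample")
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise OtuTableError(f"duplicate OTU ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise OtuTableError(f"duplicate sample ids: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise OtuTableError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise OtuTableError(
                f"negative count at OTU {c.index[i]!r}, sample {c.columns[j]!r}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class SubsetSpec:
    """Rule selecting an analysis subset of samples.

    ``kind`` is one of ``temporal`` (a set of calendar months), ``spatial``
    (a shore-distance threshold in metres with a side) or ``custom`` (an
    explicit sample-id list).  The rule is total: every sample with
    metadata is unambiguously in or out.
    """

    name: str
    kind: str
    months: frozenset[str] | None = None
    shore_threshold_m: float | None = None
    side: str | None = None  # "nearshore" (< threshold) or "offshore" (>= threshold)
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"temporal", "spatial", "custom"}:
            raise OtuTableError(f"unknown subset kind {self.kind!r}")
        if self.kind == "temporal" and not self.months:
            raise OtuTableError("temporal subset needs a month set")
        if self.kind == "spatial":
            if self.shore_threshold_m is None or self.side not in {"nearshore", "offshore"}:
                raise OtuTableError(
                    "spatial subset needs shore_threshold_m and side in "
                    "{'nearshore','offshore'}"
                )
        if self.kind == "custom" and not self.sample_ids:
            raise OtuTableError("custom subset needs explicit sample ids")

    def matches(self, meta_row: pd.Series) -> bool:
        if self.kind == "temporal":
            return str(meta_row["month"]) in self.months  # type: ignore[operator]
        if self.kind == "spatial":
            d = float(meta_row["shore_distance_m"])
            if self.side == "nearshore":
                return d < float(self.shore_threshold_m)  # type: ignore[arg-type]
            return d >= float(self.shore_threshold_m)  # type: ignore[arg-type]
        return str(meta_row["sample_id"]) in self.sample_ids  # type: ignore[operator]


def read_otu_table(path: str | Path, marker: str = "") -> OtuTable:
    """Parse a tab-delimited OTU table (first column OTU id, header samples).

    Rejects ragged rows, duplicate identifiers and negative or non-numeric
    cells with an error naming the offending row/column.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise OtuTableError(f"{path}: no data rows")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(sample_ids) == 0:
        raise OtuTableError(f"{path}: malformed header (no sample columns)")
    if len(set(sample_ids)) != len(sample_ids):
        raise OtuTableError(f"{path}: duplicate sample ids in header")
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise OtuTableError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        otu_id, cells = parts[0], parts[1:]
        for sample_id, cell in zip(sample_ids, cells):
            try:
                value = int(cell)
            except ValueError:
                raise OtuTableError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(OTU {otu_id!r}, sample {sample_id!r})"
                ) from None
            if value < 0:
                raise OtuTableError(
                    f"{path}:{lineno}: negative count {value} "
                    f"(OTU {otu_id!r}, sample {sample_id!r})"
                )
        otu_ids.append(otu_id)
        rows.append([int(c) for c in cells])
    counts = pd.DataFrame(rows, index=otu_ids, columns=sample_ids, dtype=np.int64)
    counts.index.name = "otu_id"
    return OtuTable(counts=counts, marker=marker)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the table as TSV; inverse of :func:`read_otu_table`."""
    out = table.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Load sample metadata (sample_id, month, shore_distance_m)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "month": str})
    required = {"sample_id", "month", "shore_distance_m"}
    missing = required - set(meta.columns)
    if missing:
        raise OtuTableError(f"sample metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise OtuTableError("duplicate sample_id in sample metadata")
    if (meta["shore_distance_m"].astype(float) < 0).any():
        raise OtuTableError("negative shore_distance_m in sample metadata")
    return meta.set_index("sample_id", drop=False)


def read_otu_metadata(path: str | Path) -> pd.DataFrame:
    """Load OTU metadata (otu_id, taxon_name, group [, trophic_level])."""
    meta = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "taxon_name": str, "group": str})
    required = {"otu_id", "taxon_name", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise OtuTableError(f"OTU metadata missing columns: {sorted(missing)}")
    if meta["otu_id"].duplicated().any():
        raise OtuTableError("duplicate otu_id in OTU metadata")
    bad = set(meta["group"]) - GROUP_VOCABULARY
    if bad:
        raise OtuTableError(f"unknown group labels: {sorted(bad)}")
    if "trophic_level" in meta.columns:
        tl = pd.to_numeric(meta["trophic_level"], errors="coerce")
        if (tl.dropna() < 1).any():
            raise OtuTableError("trophic_level below 1 in OTU metadata")
        meta["trophic_level"] = tl
    else:
        meta["trophic_level"] = np.nan
    return meta.set_index("otu_id", drop=False)


def prevalence_filter(table: OtuTable, min_prevalence: float = 0.25) -> OtuTable:
    """Drop OTUs present (count > 0) in fewer than ``min_prevalence`` of samples.

    Presence is strictly positive read count; no minimum-read cutoff is
    applied.  Idempotent: re-filtering a filtered table is a no-op.
    """
    if not (0 < min_prevalence <= 1):
        raise OtuTableError("min_prevalence must be in (0, 1]")
    presence = (table.counts.to_numpy() > 0).sum(axis=1)
    keep = presence / table.n_samples >= min_prevalence
    if not keep.any():
        raise OtuTableError("empty community after prevalence filter")
    removed = tuple(np.asarray(table.otu_ids)[~keep])
    return replace(
        table,
        counts=table.counts.loc[keep],
        removed_otus=table.removed_otus + removed,
    )


def subset_samples(table: OtuTable, meta: pd.DataFrame, spec: SubsetSpec) -> OtuTable:
    """Restrict a table to the samples matched by ``spec``.

    Prevalence filtering belongs AFTER subsetting (per subset), never
    before: occupancy fractions are relative to the subset's sample count.
    """
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise OtuTableError(f"samples without metadata: {missing}")
    selected = [s for s in table.sample_ids if spec.matches(meta.loc[s])]
    if not selected:
        raise OtuTableError(f"subset {spec.name!r} matches no samples")
    return replace(table, counts=table.counts[selected])
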