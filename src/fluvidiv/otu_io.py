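"""OTU count tables: data model, TSV/BIOM-JSON readers, filters, rarefaction.

Tables are held as a pandas DataFrame of non-negative integers with samples
in rows and OTUs in columns (the canonical internal orientation).  Filtering
follows amplicon practice: removal of unwanted lineages (plastid,
mitochondrial, archaeal) first, rarefaction to a fixed read depth next, and a
minimum-total-read OTU drop afterwards for dissimilarity analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "TaxonomyMap",
    "LineageRemovalReport",
    "RarefactionReport",
    "read_table",
    "read_biom_json",
    "write_table",
    "read_metadata_tsv",
    "validate_metadata",
    "read_taxonomy_tsv",
    "drop_rare_otus",
    "drop_lineages",
    "rarefy",
    "occupancy",
    "FRACTIONS",
]

FRACTIONS = ("FL", "PA")  # free-living 0.2-3.0 um | particle-associated > 3.0 um
METADATA_COLUMNS = ["sample_id", "site_id", "fraction", "system"]
_OTU_INDEX_NAMES = {"#otu id", "otu_id", "otu id", "otu"}


@dataclass(frozen=True)
class OTUTable:
    """Samples x OTUs count matrix (non-negative integers, unique ids)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError(f"duplicate sample ids: {df.index[df.index.duplicated()].tolist()}")
        if df.columns.has_duplicates:
            raise ValueError(
                f"duplicate OTU ids: {df.columns[df.columns.duplicated()].tolist()}"
            )
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                raise ValueError(
                    f"non-integer count at sample {df.index[i]!r}, OTU {df.columns[j]!r}: "
                    f"{df.iat[i, j]}"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.counts.index:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.counts.loc[sample_id]

    def select_samples(self, sample_ids: Sequence[str]) -> "OTUTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return OTUTable(self.counts.loc[list(sample_ids)].copy())

    def drop_empty_otus(self) -> "OTUTable":
        return OTUTable(self.counts.loc[:, self.otu_totals() > 0].copy())

    def __eq__(self, other) -> bool:  # round-trip identity support
        return isinstance(other, OTUTable) and self.counts.equals(other.counts)


@dataclass(frozen=True)
class TaxonomyMap:
    """Per-OTU lineage strings plus freshwater-database annotation level.

    ``freshwater_level`` records at which level an OTU matched a curated
    freshwater 16S reference: ``tribe`` (finest), ``clade_lineage``, or
    ``none`` (non-typical freshwater taxa).  ``tribe`` labels (e.g. acI-B1,
    LD12) are only present for tribe-level matches.
    """

    lineage: Mapping[str, str]
    freshwater_level: Mapping[str, str] = field(default_factory=dict)
    tribe: Mapping[str, str] = field(default_factory=dict)

    VALID_LEVELS = ("tribe", "clade_lineage", "none")

    def __post_init__(self) -> None:
        bad = {v for v in self.freshwater_level.values()} - set(self.VALID_LEVELS)
        if bad:
            raise ValueError(f"invalid freshwater levels: {sorted(bad)}")

    def level_of(self, otu_id: str) -> str:
        return self.freshwater_level.get(otu_id, "none")

    def lineage_of(self, otu_id: str) -> str:
        return self.lineage.get(otu_id, "unassigned")


@dataclass(frozen=True)
class LineageRemovalReport:
    n_otus_removed: int
    n_reads_removed: int
    removed_otu_ids: tuple[str, ...]


@dataclass(frozen=True)
class RarefactionReport:
    depth: int
    seed: int
    dropped_samples: tuple[str, ...]


# -- readers / writers ------------------------------------------------------


def read_table(path, orientation: str = "auto") -> OTUTable:
    """Read a tab-delimited count table.

    ``orientation`` is ``"samples"`` (samples in rows), ``"otus"`` (OTUs in
    rows, the classic QIIME export) or ``"auto"``: the table is transposed when
    the header's first cell is an OTU-style label (``#OTU ID``/``otu_id``).
    """
    if orientation not in ("auto", "samples", "otus"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"malformed table {path}: missing value in row {row!r}")
    name = (df.index.name or "").strip().lower()
    if orientation == "otus" or (orientation == "auto" and name in _OTU_INDEX_NAMES):
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "sample_id"
    try:
        return OTUTable(df)
    except ValueError as exc:
        raise ValueError(f"invalid counts in {path}: {exc}") from exc


def write_table(table: OTUTable, path) -> None:
    """Write samples-in-rows TSV; ``read_table(write_table(t)) == t``."""
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_biom_json(path) -> OTUTable:
    """Read a BIOM v1 (JSON) table; rows are observations (OTUs), columns samples."""
    with open(path) as fh:
        doc = json.load(fh)
    otus = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros((len(otus), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat.T, index=samples, columns=otus)
    df.index.name = "sample_id"
    return OTUTable(df)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read sample metadata (``sample_id site_id fraction system``), indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata TSV {path}: missing columns {missing}")
    df = df.set_index("sample_id")
    bad = sorted(set(df["fraction"]) - set(FRACTIONS))
    if bad:
        raise ValueError(f"metadata TSV {path}: unknown fractions {bad}; expected {FRACTIONS}")
    bad = sorted(set(df["system"]) - {"mainstem", "tributary"})
    if bad:
        raise ValueError(f"metadata TSV {path}: unknown systems {bad}")
    return df


def validate_metadata(table: OTUTable, meta: pd.DataFrame) -> None:
    """Every table sample must have exactly one metadata row."""
    if meta.index.has_duplicates:
        raise ValueError(
            f"duplicate metadata rows for samples: "
            f"{meta.index[meta.index.duplicated()].tolist()}"
        )
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")


def read_taxonomy_tsv(path) -> TaxonomyMap:
    """Read taxonomy TSV (``otu_id lineage freshwater_level tribe``; tribe optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("otu_id", "lineage"):
        if col not in df.columns:
            raise ValueError(f"taxonomy TSV {path}: missing column {col!r}")
    lineage = dict(zip(df["otu_id"], df["lineage"]))
    level = {}
    if "freshwater_level" in df.columns:
        level = {o: (l or "none") for o, l in zip(df["otu_id"], df["freshwater_level"])}
    tribe = {}
    if "tribe" in df.columns:
        tribe = {o: t for o, t in zip(df["otu_id"], df["tribe"]) if t}
    return TaxonomyMap(lineage=lineage, freshwater_level=level, tribe=tribe)


def write_taxonomy_tsv(taxonomy: TaxonomyMap, path) -> None:
    otus = sorted(taxonomy.lineage)
    df = pd.DataFrame(
        {
            "otu_id": otus,
            "lineage": [taxonomy.lineage[o] for o in otus],
            "freshwater_level": [taxonomy.level_of(o) for o in otus],
            "tribe": [taxonomy.tribe.get(o, "") for o in otus],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- filters ----------------------------------------------------------------


def drop_rare_otus(table: OTUTable, min_reads: int = 2) -> OTUTable:
    """Remove OTUs whose total read count across all samples is below ``min_reads``.

    The default of 2 discards global singletons, the usual guard against
    spurious OTUs from sequencing error.  Idempotent; samples are never
    removed.
    """
    if min_reads < 0:
        raise ValueError(f"min_reads must be >= 0, got {min_reads}")
    keep = table.otu_totals() >= min_reads
    out = OTUTable(table.counts.loc[:, keep].copy())
    if out.n_otus == 0:
        warnings.warn("drop_rare_otus removed every OTU", stacklevel=2)
    return out


def drop_lineages(
    table: OTUTable, taxonomy: TaxonomyMap, labels: Sequence[str]
) -> tuple[OTUTable, LineageRemovalReport]:
    """Remove OTUs whose lineage contains any label (case-insensitive substring).

    Matching is literal on the rank-delimited lineage string: no synonym
    expansion, so e.g. chloroplast-assigned OTUs are only removed if
    "Chloroplast" itself is in ``labels``.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    low = [l.lower() for l in labels]
    removed = [
        o for o in table.otu_ids if any(l in taxonomy.lineage_of(o).lower() for l in low)
    ]
    n_reads = int(table.counts[removed].to_numpy().sum()) if removed else 0
    out = OTUTable(table.counts.drop(columns=removed))
    return out, LineageRemovalReport(len(removed), n_reads, tuple(removed))


def rarefy(
    table: OTUTable, depth: int, seed: int
) -> tuple[OTUTable, RarefactionReport]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped and reported.  The
    draw is multivariate hypergeometric per sample (the behaviour of vegan's
    ``rrarefy``) and deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = tuple(s for s in table.sample_ids if totals[s] < depth)
    rows = []
    for s in kept:
        row = table.counts.loc[s].to_numpy()
        if totals[s] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(kept), table.n_otus),
        index=kept,
        columns=table.otu_ids,
    )
    out.index.name = "sample_id"
    return OTUTable(out), RarefactionReport(depth=depth, seed=seed, dropped_samples=dropped)


def occupancy(table: OTUTable, presence_min: int = 1) -> pd.Series:
    """Number of samples in which each OTU has at least ``presence_min`` reads."""
    if presence_min < 1:
        raise ValueError(f"presence_min must be >= 1, got {presence_min}")
    return (table.counts >= presence_min).sum(axis=0)
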