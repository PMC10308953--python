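"""Abundance, taxonomy and metadata tables plus table-preparation steps.

This module holds the in-memory containers used throughout the package —
taxa-by-sample count tables with ranked taxonomy, and per-microcosm sample
metadata for serial-propagation experiments — together with the standard
preparation steps applied before any community statistics are computed:
rarefaction to a common read depth, aggregation to a taxonomic rank,
prevalence filtering, and conversion to relative abundances.

Tables are read and written as UTF-8 tab-separated files.  Abundance files
have a literal ``taxon_id`` header cell, one column per sample, and taxonomy
either embedded as a final ``taxonomy`` column of semicolon-separated rank
labels or supplied as a two-column sidecar file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks, shallowest to deepest.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

TAXONOMY_COLUMN = "taxonomy"
ID_COLUMN = "taxon_id"


class TableValidationError(ValueError):
    """A table violates a structural invariant (ids, signs, references)."""


class TableParseError(ValueError):
    """A file cell could not be parsed; the message names the offending cell."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise TableValidationError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Taxa × samples non-negative integer counts with ranked taxonomy.

    Parameters
    ----------
    taxon_ids : list of str
        Unique taxon (e.g. ASV or family) identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer read counts.
    taxonomy : dict
        ``taxon_id -> tuple of rank labels`` ordered kingdom…species;
        missing ranks are ``None``.  Every taxon has an entry (possibly
        all-missing).
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, tuple[Optional[str], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.allclose(self.counts, np.round(self.counts)):
                    raise TableValidationError("counts must be integral")
                self.counts = self.counts.astype(np.int64)
            if (self.counts < 0).any():
                t, s = np.argwhere(self.counts < 0)[0]
                raise TableValidationError(
                    f"negative count at taxon {self.taxon_ids[t]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
        self.counts = self.counts.astype(np.int64, copy=False)
        full = (None,) * len(RANKS)
        for t in self.taxon_ids:
            entry = self.taxonomy.get(t)
            if entry is None:
                self.taxonomy[t] = full
            else:
                entry = tuple(entry) + (None,) * (len(RANKS) - len(entry))
                self.taxonomy[t] = tuple(
                    (x if x not in ("", "NA", None) else None) for x in entry
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a taxa × samples DataFrame."""
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def subset_samples(self, keep: Iterable[str]) -> "AbundanceTable":
        """Restrict to the given sample ids, preserving their given order."""
        keep = list(keep)
        missing = set(keep) - set(self.sample_ids)
        if missing:
            raise TableValidationError(f"unknown sample ids: {sorted(missing)}")
        idx = [self.sample_ids.index(s) for s in keep]
        return AbundanceTable(
            list(self.taxon_ids), keep, self.counts[:, idx], dict(self.taxonomy)
        )

    def drop_empty_taxa(self) -> "AbundanceTable":
        """Drop taxa with zero total count across all samples."""
        mask = self.counts.sum(axis=1) > 0
        ids = [t for t, m in zip(self.taxon_ids, mask) if m]
        return AbundanceTable(
            ids, list(self.sample_ids), self.counts[mask], dict(self.taxonomy)
        )


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """Per-microcosm metadata for one sample of a propagation experiment.

    ``DOC`` is dissolved organic carbon in mg C per g litter at the 28-day
    endpoint, ``CO2`` the total 28-day CO₂ accumulation (mg per g litter),
    ``TN`` total nitrogen (mg per g litter).  ``parent_sample_id`` links a
    generation-``n`` microcosm to the generation-``n−1`` microcosm whose
    slurry inoculated it; it is ``None`` exactly for generation 0.
    """

    sample_id: str
    origin_id: str
    generation: int
    lineage_id: str
    parent_sample_id: Optional[str]
    replicate: str
    DOC: float
    CO2: float
    TN: float


METADATA_COLUMNS = [
    "sample_id",
    "origin_id",
    "generation",
    "lineage_id",
    "parent_sample_id",
    "replicate",
    "DOC",
    "CO2",
    "TN",
]


@dataclass
class MetadataTable:
    """Validated collection of :class:`SampleRecord`, keyed by sample id."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        _check_unique([r.sample_id for r in self.records], "sample")
        by_id = {r.sample_id: r for r in self.records}
        for r in self.records:
            if r.generation < 0:
                raise TableValidationError(
                    f"negative generation for sample {r.sample_id!r}"
                )
            if r.generation == 0:
                if r.parent_sample_id is not None:
                    raise TableValidationError(
                        f"generation-0 sample {r.sample_id!r} has a parent"
                    )
            else:
                if r.parent_sample_id is None:
                    raise TableValidationError(
                        f"sample {r.sample_id!r} (generation {r.generation}) "
                        "has no parent"
                    )
                parent = by_id.get(r.parent_sample_id)
                if parent is None:
                    raise TableValidationError(
                        f"dangling parent reference: sample {r.sample_id!r} "
                        f"names missing parent {r.parent_sample_id!r}"
                    )
                if parent.generation != r.generation - 1:
                    raise TableValidationError(
                        f"sample {r.sample_id!r} at generation {r.generation} "
                        f"has parent {parent.sample_id!r} at generation "
                        f"{parent.generation} (expected {r.generation - 1})"
                    )
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records])
        return df[METADATA_COLUMNS].set_index("sample_id", drop=False)

    def lineage_depth(self) -> int:
        """Length (in generations) of the longest parent→child chain."""
        if not self.records:
            return 0
        return max(r.generation for r in self.records) + 1


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_taxonomy_string(s: str) -> tuple[Optional[str], ...]:
    parts = [p.strip() for p in str(s).split(";")]
    parts = [(p if p not in ("", "NA", "nan", "None") else None) for p in parts]
    parts = parts[: len(RANKS)]
    return tuple(parts) + (None,) * (len(RANKS) - len(parts))


def read_abundance_table(
    path: str | Path,
    format: str = "tsv",
    taxonomy_path: str | Path | None = None,
) -> AbundanceTable:
    """Read a taxa × samples count table from a tab-separated file.

    The header row holds sample ids (first cell ``taxon_id``); the first
    column holds taxon ids.  Taxonomy may be embedded as a final
    ``taxonomy`` column of semicolon-separated rank labels, or supplied as a
    separate two-column sidecar via *taxonomy_path*.
    """
    if format != "tsv":
        raise ValueError(f"unsupported abundance table format: {format!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != ID_COLUMN:
        raise TableParseError(
            f"{path}: first header cell must be {ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    taxonomy: dict[str, tuple[Optional[str], ...]] = {}
    if TAXONOMY_COLUMN in df.columns:
        for tid, tax in zip(df[ID_COLUMN], df[TAXONOMY_COLUMN]):
            taxonomy[tid] = _parse_taxonomy_string(tax)
        df = df.drop(columns=[TAXONOMY_COLUMN])
    taxon_ids = df[ID_COLUMN].tolist()
    sample_ids = [c for c in df.columns if c != ID_COLUMN]
    counts = np.empty((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(sample_ids):
        for i, cell in enumerate(df[col]):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise TableParseError(
                    f"{path}: malformed count {cell!r} at taxon "
                    f"{taxon_ids[i]!r}, sample {col!r}"
                ) from None
            if v < 0:
                raise TableParseError(
                    f"{path}: negative count {v} at taxon {taxon_ids[i]!r}, "
                    f"sample {col!r}"
                )
            counts[i, j] = v
    if taxonomy_path is not None:
        side = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
        for tid, tax in zip(side.iloc[:, 0], side.iloc[:, 1]):
            taxonomy[tid] = _parse_taxonomy_string(tax)
    return AbundanceTable(taxon_ids, sample_ids, counts, taxonomy)


def write_table(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance table as TSV with an embedded taxonomy column."""
    df = table.to_dataframe().copy()
    df.insert(0, ID_COLUMN, table.taxon_ids)
    df[TAXONOMY_COLUMN] = [
        ";".join(x if x is not None else "" for x in table.taxonomy[t])
        for t in table.taxon_ids
    ]
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> MetadataTable:
    """Read and validate per-microcosm metadata from a tab-separated file."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise TableParseError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            gen = int(row["generation"])
        except ValueError:
            raise TableParseError(
                f"{path}: malformed generation {row['generation']!r} for "
                f"sample {row['sample_id']!r}"
            ) from None
        parent = row["parent_sample_id"] or None
        try:
            doc, co2, tn = (float(row[c]) for c in ("DOC", "CO2", "TN"))
        except ValueError:
            raise TableParseError(
                f"{path}: malformed numeric field for sample {row['sample_id']!r}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                origin_id=row["origin_id"],
                generation=gen,
                lineage_id=row["lineage_id"],
                parent_sample_id=parent,
                replicate=row["replicate"],
                DOC=doc,
                CO2=co2,
                TN=tn,
            )
        )
    return MetadataTable(records)


def write_metadata(metadata: MetadataTable, path: str | Path) -> None:
    df = metadata.to_dataframe().copy()
    df["parent_sample_id"] = df["parent_sample_id"].fillna("")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preparation steps
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (with a logged
    warning listing them); retained columns sum exactly to ``depth``.
    Subsampling draws a multivariate hypergeometric sample per column, i.e.
    reads are drawn without replacement, and is deterministic given *seed*.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep, dropped = [], []
    for s, tot in zip(table.sample_ids, totals):
        (keep if tot >= depth else dropped).append(s)
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    sub = table.subset_samples(keep)
    out = np.empty_like(sub.counts)
    for j in range(sub.n_samples):
        col = sub.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return AbundanceTable(list(sub.taxon_ids), list(sub.sample_ids), out,
                          dict(sub.taxonomy))


def aggregate_by_rank(
    table: AbundanceTable, rank: str, drop_unclassified: bool = False
) -> AbundanceTable:
    """Sum counts of taxa sharing the same label at ``rank``.

    Taxa lacking a label at ``rank`` are pooled under
    ``"Unclassified_<deepest assigned rank label>"`` (or dropped when
    *drop_unclassified* is set).  Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"invalid rank {rank!r}; choose from {RANKS}")
    level = RANKS.index(rank)
    groups: dict[str, np.ndarray] = {}
    group_tax: dict[str, tuple[Optional[str], ...]] = {}
    order: list[str] = []
    for i, tid in enumerate(table.taxon_ids):
        ranks = table.taxonomy[tid]
        label = ranks[level]
        if label is None:
            if drop_unclassified:
                continue
            assigned = [x for x in ranks[:level] if x is not None]
            deepest = assigned[-1] if assigned else "unknown"
            label = f"Unclassified_{deepest}"
            tax = tuple(ranks[:level]) + (None,) * (len(RANKS) - level)
        else:
            tax = tuple(ranks[: level + 1]) + (None,) * (len(RANKS) - level - 1)
        if label not in groups:
            groups[label] = table.counts[i].copy()
            group_tax[label] = tax
            order.append(label)
        else:
            groups[label] = groups[label] + table.counts[i]
    counts = np.vstack([groups[g] for g in order]) if order else np.empty(
        (0, table.n_samples), dtype=np.int64
    )
    return AbundanceTable(order, list(table.sample_ids), counts,
                          {g: group_tax[g] for g in order})


def prevalence_filter(
    table: AbundanceTable, min_prevalence: float, strict: bool = True
) -> AbundanceTable:
    """Retain taxa present (count > 0) in more than (``strict``) or at
    least (``not strict``) a fraction ``min_prevalence`` of samples."""
    if table.n_samples == 0:
        raise TableValidationError("cannot prevalence-filter an empty table")
    prev = (table.counts > 0).mean(axis=1)
    mask = prev > min_prevalence if strict else prev >= min_prevalence
    ids = [t for t, m in zip(table.taxon_ids, mask) if m]
    return AbundanceTable(ids, list(table.sample_ids), table.counts[mask],
                          dict(table.taxonomy))


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample fractions (columns sum to 1); errors on all-zero samples."""
    sums = table.sample_sums()
    if (sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise TableValidationError(f"all-zero sample(s): {bad}")
    frac = table.counts / sums[np.newaxis, :]
    return pd.DataFrame(frac, index=table.taxon_ids, columns=table.sample_ids)
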