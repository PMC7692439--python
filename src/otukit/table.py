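"""OTU count tables and their companion sample-metadata and taxonomy tables.

The central container is :class:`OtuTable`, a validated wrapper around a
pandas DataFrame of non-negative integer read counts with OTUs as rows and
samples as columns.  Companion tables are :class:`SampleMetadata` (per-sample
site / plant / compartment factors) and :class:`TaxonomyMap` (OTU -> lineage
labels).  All three round-trip through plain tab-separated text.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: The two plant compartments compared throughout the analysis.
COMPARTMENTS = ("rhizosphere", "phyllosphere")

_TSV_KWARGS = dict(sep="\t", quoting=csv.QUOTE_NONE, encoding="utf-8")


class ValidationError(ValueError):
    """An input table violates its structural contract."""


class OtuTable:
    """An OTU x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by OTU identifier, columns by sample identifier.
        Values must be non-negative integers (floats that are whole
        numbers are coerced).

    Notes
    -----
    The table is treated as immutable: filtering operations return new
    instances and depth/total vectors are cached on first access.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr.astype(float))):
                raise ValidationError("counts contain non-finite values")
            if np.any(arr.astype(float) != np.floor(arr.astype(float))):
                raise ValidationError("counts must be whole numbers")
        counts = counts.astype(np.int64, copy=True)
        if counts.size and (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        self._counts = counts
        self._depths: pd.Series | None = None
        self._totals: pd.Series | None = None

    # -- basic accessors --------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        """The underlying OTU x sample count matrix (do not mutate)."""
        return self._counts

    @property
    def otu_ids(self) -> list[str]:
        return self._counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._counts.columns.tolist()

    @property
    def n_otus(self) -> int:
        return self._counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self._counts.shape[1]

    @property
    def sample_depths(self) -> pd.Series:
        """Reads per sample (column sums)."""
        if self._depths is None:
            self._depths = self._counts.sum(axis=0)
        return self._depths

    @property
    def otu_totals(self) -> pd.Series:
        """Reads per OTU over the whole dataset (row sums)."""
        if self._totals is None:
            self._totals = self._counts.sum(axis=1)
        return self._totals

    @property
    def grand_total(self) -> int:
        return int(self.sample_depths.sum())

    def presence(self) -> pd.DataFrame:
        """Boolean OTU x sample presence/absence matrix."""
        return self._counts > 0

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str], drop_empty_otus: bool = False) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self._counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        sub = self._counts.loc[:, list(sample_ids)]
        if drop_empty_otus:
            sub = sub.loc[sub.sum(axis=1) > 0]
        return OtuTable(sub)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self._counts.index]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(self._counts.loc[list(otu_ids)])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1; all-zero samples stay 0)."""
        depths = self.sample_depths.replace(0, 1)
        return self._counts / depths

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self._counts.to_csv(path, sep="\t", index_label="otu_id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples, {self.grand_total} reads)"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OtuTable) and self._counts.equals(other._counts)


def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU table from TSV (first row sample ids, first column OTU ids).

    Raises
    ------
    ValidationError
        If the table has no OTU rows, a cell fails to parse as a
        non-negative integer (the error names the offending OTU and
        sample), or ids are duplicated.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, header=0, **_TSV_KWARGS)
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no OTU rows")
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    parsed = {}
    for col in raw.columns:
        try:
            parsed[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            numeric = pd.to_numeric(raw[col], errors="coerce")
            bad = numeric.index[numeric.isna()][0]
            raise ValidationError(
                f"{path}: malformed count at OTU {bad!r}, sample {col!r}: {raw.at[bad, col]!r}"
            ) from None
    frame = pd.DataFrame(parsed, index=raw.index)
    arr = frame.to_numpy(dtype=float)
    bad_cells = np.argwhere((arr < 0) | (arr != np.floor(arr)))
    if bad_cells.size:
        i, j = bad_cells[0]
        raise ValidationError(
            f"{path}: invalid count {arr[i, j]!r} at OTU {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r} (must be a non-negative integer)"
        )
    return OtuTable(frame)


class SampleMetadata:
    """Per-sample grouping factors: site, plant, compartment, and short code.

    Wraps a DataFrame indexed by sample id with the columns
    ``site``, ``plant``, ``compartment`` and ``code``.  ``compartment``
    must be ``rhizosphere`` or ``phyllosphere``.
    """

    REQUIRED = ("site", "plant", "compartment", "code")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "sample_id" and "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dup}")
        bad = sorted(set(frame["compartment"]) - set(COMPARTMENTS))
        if bad:
            raise ValidationError(
                f"compartment must be one of {COMPARTMENTS}, got {bad}"
            )
        frame.index = frame.index.astype(str)
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.index.tolist()

    def for_table(self, table: OtuTable) -> pd.DataFrame:
        """Metadata rows aligned to a table's samples; errors name any sample lacking metadata."""
        missing = [s for s in table.sample_ids if s not in self._frame.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        return self._frame.loc[table.sample_ids]

    def group_labels(self, factors: Sequence[str], samples: Sequence[str] | None = None,
                     sep: str = ":") -> pd.Series:
        """Combined group label per sample, e.g. ``plant:compartment``."""
        frame = self._frame if samples is None else self._frame.loc[list(samples)]
        unknown = [f for f in factors if f not in frame.columns]
        if unknown:
            raise KeyError(f"unknown metadata factors: {unknown}")
        labels = frame[list(factors)].astype(str).agg(sep.join, axis=1)
        labels.name = sep.join(factors)
        return labels

    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, dtype=str, **_TSV_KWARGS)
    return SampleMetadata(frame)


class TaxonomyMap(Mapping):
    """OTU id -> lineage (ordered rank labels, e.g. from a SILVA-style string).

    OTUs absent from the map are treated as ``unclassified`` and are never
    removed by taxonomy-based filters.
    """

    UNCLASSIFIED = ("unclassified",)

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {
            str(k): tuple(str(r).strip() for r in v) for k, v in lineages.items()
        }

    def __getitem__(self, otu_id: str) -> tuple[str, ...]:
        return self._lineages[otu_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lineages)

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        """Lineage for an OTU, or ``("unclassified",)`` if unknown."""
        return self._lineages.get(otu_id, self.UNCLASSIFIED)

    def contains_label(self, otu_id: str, label: str) -> bool:
        """True if `label` is a case-insensitive substring of any rank of the OTU's lineage."""
        needle = label.lower()
        return any(needle in rank.lower() for rank in self.lineage(otu_id))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("otu_id\tlineage\n")
            for otu, ranks in self._lineages.items():
                fh.write(f"{otu}\t{';'.join(ranks)}\n")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    frame = pd.read_csv(path, dtype=str, **_TSV_KWARGS)
    for col in ("otu_id", "lineage"):
        if col not in frame.columns:
            raise ValidationError(f"taxonomy table missing column {col!r}")
    lineages = {
        row.otu_id: tuple(part for part in str(row.lineage).split(";") if part)
        for row in frame.itertuples()
    }
    return TaxonomyMap(lineages)
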