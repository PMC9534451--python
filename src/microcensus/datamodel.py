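"""Abundance tables, taxonomy maps, normalization and rarefaction.

The universal exchange object is :class:`OtuTable`, a thin wrapper around a
pandas DataFrame in canonical samples-by-taxa orientation.  All downstream
modules (reference fitting, mixture simulation, census estimation, sewage
preprocessing, SAD comparison) consume and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "to_relative",
    "rarefy",
    "UNKNOWN_FAMILY",
]

#: Sentinel family name for taxa missing from a taxonomy map.
UNKNOWN_FAMILY = "unassigned"

_REL_TOL = 1e-6


class OtuTableError(ValueError):
    """Raised for malformed abundance tables or contract violations."""


@dataclass
class OtuTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns.  Values must be finite and non-negative.
    is_relative
        True when every row is a composition summing to 1.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise OtuTableError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise OtuTableError(f"duplicate taxon ids: {dups}")
        if values.size and not np.all(np.isfinite(values)):
            raise OtuTableError("non-finite abundance values")
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise OtuTableError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if self.is_relative and values.size:
            sums = values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            if bad.size:
                raise OtuTableError(
                    f"relative table rows must sum to 1; sample "
                    f"{self.data.index[bad[0]]!r} sums to {sums[bad[0]]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)].copy(), self.is_relative)

    def subset_taxa(self, taxon_ids: Iterable) -> "OtuTable":
        # Subsetting taxa breaks the unit-sum invariant of a relative table.
        return OtuTable(self.data.loc[:, list(taxon_ids)].copy(), is_relative=False)


@dataclass
class TaxonomyMap:
    """Mapping from taxon id to family name.

    Taxa absent from the mapping are reported as :data:`UNKNOWN_FAMILY`.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, family in self.mapping.items():
            if not str(family):
                raise OtuTableError(f"empty family name for taxon {taxon!r}")

    def family_of(self, taxon_id) -> str:
        return self.mapping.get(taxon_id, UNKNOWN_FAMILY)

    def __len__(self) -> int:
        return len(self.mapping)


def read_otu_table(
    path: str | Path,
    orientation: Literal["samples_by_taxa", "taxa_by_samples"] = "samples_by_taxa",
) -> OtuTable:
    """Read a tab-separated abundance table.

    The file must have one header row of identifiers and one identifier
    column.  Tables stored taxa-by-samples are transposed to the canonical
    samples-by-taxa orientation.  ``is_relative`` is inferred: True only when
    every row sum lies within 1e-6 of 1.
    """
    if orientation not in ("samples_by_taxa", "taxa_by_samples"):
        raise OtuTableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.isna().any() or df.columns.isna().any():
        raise OtuTableError(f"malformed header in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise OtuTableError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    neg = numeric.to_numpy(dtype=float) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise OtuTableError(
            f"negative cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "taxa_by_samples":
        numeric = numeric.T
    sums = numeric.to_numpy(dtype=float).sum(axis=1)
    is_relative = bool(numeric.size) and bool(
        np.all(np.abs(sums - 1.0) <= _REL_TOL)
    )
    return OtuTable(numeric.astype(float), is_relative=is_relative)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table as TSV in samples-by-taxa orientation."""
    table.data.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV (taxon_id, family) taxonomy map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "family"], dtype=str)
    if df.empty:
        raise OtuTableError(f"empty taxonomy file {path}")
    if df["taxon"].duplicated().any():
        dup = df.loc[df["taxon"].duplicated(), "taxon"].iloc[0]
        raise OtuTableError(f"duplicate taxon id in taxonomy: {dup!r}")
    return TaxonomyMap(dict(zip(df["taxon"], df["family"])))


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    pd.DataFrame(sorted(taxonomy.mapping.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def to_relative(table: OtuTable) -> OtuTable:
    """Normalize each sample to relative abundance (rows sum to 1)."""
    sums = table.values.sum(axis=1)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise OtuTableError(
            f"cannot normalize all-zero sample {table.data.index[zero[0]]!r}"
        )
    return OtuTable(table.data.div(sums, axis=0), is_relative=True)


def rarefy(
    table: OtuTable, depth: int, seed: int
) -> tuple[OtuTable, list]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped.  Returns the
    rarefied table and the list of dropped sample ids.  Deterministic given
    ``seed``.
    """
    if table.is_relative:
        raise OtuTableError("rarefaction requires integer counts, not proportions")
    if depth <= 0:
        raise OtuTableError(f"depth must be positive, got {depth}")
    counts = np.rint(table.values).astype(np.int64)
    if not np.allclose(counts, table.values):
        raise OtuTableError("rarefaction requires integer counts")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    kept_rows = []
    kept_ids = []
    dropped = []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        if totals[i] == depth:
            kept_rows.append(counts[i])
        else:
            kept_rows.append(
                rng.multivariate_hypergeometric(counts[i], depth)
            )
        kept_ids.append(sid)
    data = pd.DataFrame(
        np.asarray(kept_rows, dtype=float).reshape(len(kept_ids), table.n_taxa),
        index=kept_ids,
        columns=table.data.columns,
    )
    return OtuTable(data, is_relative=False), dropped
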