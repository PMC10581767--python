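"""Input tables, validation, filtering, and compositional transforms.

The pipeline's universal substrate is a samples x ASVs read-count matrix
accompanied by a per-ASV taxonomy table (phylum..genus) and per-sample
metadata describing the pedigree design: parental colonies, founding
reproductives (alates) and offspring colonies, with caste and
parental-role labels.  All three tables are plain TSV with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AsvCountTable",
    "TaxonomyTable",
    "SampleMetadata",
    "RelAbundTable",
    "DataValidationError",
    "read_dataset",
    "read_counts",
    "read_taxonomy",
    "read_metadata",
    "filter_min_total_reads",
    "to_relative_abundance",
    "presence",
    "RANKS",
]

RANKS = ("phylum", "class", "order", "family", "genus")

GENERATIONS = frozenset({"parental", "founder", "offspring"})
PARENTAL_ROLES = frozenset({"maternal", "paternal", "na"})
CASTES = frozenset({"worker", "queen", "king", "larva", "alate"})

#: strings treated as an unresolved taxonomic rank (besides real NA cells)
_UNRESOLVED_TOKENS = frozenset({"", "na", "nan", "none", "unclassified"})


class DataValidationError(ValueError):
    """An input table violates a structural invariant."""


def _require_unique(values: Iterable[str], what: str) -> None:
    # an emptied axis is allowed (e.g. a read filter removing every ASV);
    # individual ids must be unique and non-blank
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise DataValidationError(f"duplicate {what}: {v!r}")
        if not v:
            raise DataValidationError(f"blank {what}")
        seen.add(v)


@dataclass(frozen=True)
class AsvCountTable:
    """Samples x ASVs matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _require_unique(df.index.astype(str), "sample_id")
        _require_unique(df.columns.astype(str), "asv_id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise DataValidationError("non-integer count in table")
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = df.columns[np.argwhere(values < 0)[0][1]]
            raise DataValidationError(f"negative count (ASV {bad!r})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_reads_per_asv(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-ASV taxonomic ranks; any rank may be unresolved (NA)."""

    ranks: pd.DataFrame  # indexed by asv_id, columns RANKS

    def __post_init__(self) -> None:
        _require_unique(self.ranks.index.astype(str), "asv_id")
        missing = [r for r in RANKS if r not in self.ranks.columns]
        if missing:
            raise DataValidationError(f"taxonomy missing rank column(s): {missing}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.ranks.index)

    @staticmethod
    def _resolved(value: object) -> bool:
        if pd.isna(value):
            return False
        return str(value).strip().lower() not in _UNRESOLVED_TOKENS

    def genus_labels(self) -> pd.Series:
        """Genus label per ASV with unresolved genera grouped.

        ASVs without a resolved genus are grouped as
        ``unclassified_<lowest resolved rank>`` so that genus-level
        partitions stay exhaustive and disjoint; ASVs with no resolved
        rank at all fall into ``unclassified_root``.
        """
        labels = {}
        for asv, row in self.ranks.iterrows():
            if self._resolved(row["genus"]):
                labels[asv] = str(row["genus"])
                continue
            for rank in ("family", "order", "class", "phylum"):
                if self._resolved(row[rank]):
                    labels[asv] = f"unclassified_{row[rank]}"
                    break
            else:
                labels[asv] = "unclassified_root"
        return pd.Series(labels, name="genus_label")

    def to_tsv(self, path: str | Path) -> None:
        self.ranks.rename_axis("asv_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample pedigree design labels.

    Columns: pedigree (NA allowed for the shared paternal colony),
    generation in {parental, founder, offspring}, parental_role in
    {maternal, paternal, na}, caste, colony_id, guts_pooled (>= 1).
    """

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.table
        _require_unique(df.index.astype(str), "sample_id")
        required = ["pedigree", "generation", "parental_role", "caste", "colony_id", "guts_pooled"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataValidationError(f"metadata missing column(s): {missing}")
        bad_gen = set(df["generation"]) - GENERATIONS
        if bad_gen:
            raise DataValidationError(f"unknown generation value(s): {sorted(bad_gen)}")
        bad_role = set(df["parental_role"].fillna("na")) - PARENTAL_ROLES
        if bad_role:
            raise DataValidationError(f"unknown parental_role value(s): {sorted(bad_role)}")
        bad_caste = set(df["caste"]) - CASTES
        if bad_caste:
            raise DataValidationError(f"unknown caste value(s): {sorted(bad_caste)}")
        pooled = pd.to_numeric(df["guts_pooled"], errors="raise")
        if (pooled < 1).any():
            raise DataValidationError("guts_pooled must be >= 1")
        founders = df[df["generation"] == "founder"]
        if founders["pedigree"].isna().any() or (founders["parental_role"] == "na").any():
            raise DataValidationError("founder samples must carry pedigree and parental_role")
        offspring = df[df["generation"] == "offspring"]
        if offspring["pedigree"].isna().any():
            raise DataValidationError("offspring samples must carry pedigree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def pedigrees(self) -> list[str]:
        peds = self.table["pedigree"].dropna().unique()
        return sorted(str(p) for p in peds)

    def select(
        self,
        *,
        generation: str | None = None,
        pedigree: str | None = None,
        pedigree_or_na: str | None = None,
        parental_role: str | None = None,
        castes: Iterable[str] | None = None,
    ) -> list[str]:
        """Sample ids matching all given filters.

        ``pedigree_or_na`` also admits samples without a pedigree label
        (the shared paternal parental colony).
        """
        df = self.table
        mask = pd.Series(True, index=df.index)
        if generation is not None:
            mask &= df["generation"] == generation
        if pedigree is not None:
            mask &= df["pedigree"] == pedigree
        if pedigree_or_na is not None:
            mask &= (df["pedigree"] == pedigree_or_na) | df["pedigree"].isna()
        if parental_role is not None:
            mask &= df["parental_role"] == parental_role
        if castes is not None:
            mask &= df["caste"].isin(set(castes))
        return list(df.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class RelAbundTable:
    """Per-sample relative abundances; rows sum to 1 unless the sample had
    zero reads, in which case the row is all-zero and listed in
    ``zero_total_samples``."""

    values: pd.DataFrame
    zero_total_samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1)
        for sample, total in sums.items():
            if sample in self.zero_total_samples:
                if total != 0:
                    raise DataValidationError(f"flagged zero-total sample {sample!r} has mass")
            elif abs(total - 1.0) > 1e-9:
                raise DataValidationError(f"relative abundances of {sample!r} sum to {total}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.values.columns)

    def mean_over_samples(self, sample_ids: Iterable[str]) -> pd.Series:
        """Per-ASV mean relative abundance over the given samples."""
        ids = list(sample_ids)
        if not ids:
            raise DataValidationError("mean_over_samples: empty sample list")
        return self.values.loc[ids].mean(axis=0)


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path) -> AsvCountTable:
    """Read a counts TSV; orientation auto-detected from the header.

    A first header token ``sample_id`` means samples as rows; ``asv_id``
    means ASVs as rows (the table is transposed on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    first = str(df.index.name or "").strip().lower()
    if first == "asv_id":
        df = df.T
    elif first != "sample_id":
        raise DataValidationError(
            f"counts header must start with 'sample_id' or 'asv_id', got {df.index.name!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AsvCountTable(df)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"guts_pooled": np.int64})
    df.index = df.index.astype(str)
    if "pedigree" in df.columns:
        df["pedigree"] = df["pedigree"].astype("object").where(df["pedigree"].notna(), None)
    if "parental_role" in df.columns:
        df["parental_role"] = df["parental_role"].fillna("na")
    return SampleMetadata(df)


def read_dataset(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> tuple[AsvCountTable, TaxonomyTable, SampleMetadata]:
    """Read and cross-validate the three input tables.

    Every counts sample must have metadata and every counts ASV must have
    taxonomy (errors); metadata samples absent from the counts only warn.
    """
    counts = read_counts(counts_path)
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = read_metadata(metadata_path)

    missing_meta = set(counts.sample_ids) - set(metadata.sample_ids)
    if missing_meta:
        raise DataValidationError(
            f"counts sample(s) absent from metadata: {sorted(missing_meta)}"
        )
    extra_meta = set(metadata.sample_ids) - set(counts.sample_ids)
    if extra_meta:
        warnings.warn(
            f"metadata sample(s) absent from counts: {sorted(extra_meta)}",
            stacklevel=2,
        )
    missing_tax = set(counts.asv_ids) - set(taxonomy.asv_ids)
    if missing_tax:
        raise DataValidationError(
            f"counts ASV(s) absent from taxonomy: {sorted(missing_tax)[:5]}"
        )
    return counts, taxonomy, metadata


# ---------------------------------------------------------------------------
# transforms


def filter_min_total_reads(table: AsvCountTable, threshold: int = 25) -> AsvCountTable:
    """Drop ASVs with fewer than ``threshold`` reads summed over all samples.

    The comparison is strict ("less than"): an ASV whose dataset-wide total
    equals the threshold is retained.  Samples are kept even if emptied.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = table.total_reads_per_asv()
    keep = totals.index[totals >= threshold]
    if len(keep) == 0:
        warnings.warn("filter removed every ASV", stacklevel=2)
    return AsvCountTable(table.counts.loc[:, keep])


def to_relative_abundance(table: AsvCountTable) -> RelAbundTable:
    """Divide each sample row by its total read count.

    Zero-total samples become all-zero rows and are flagged in the returned
    table's ``zero_total_samples``.
    """
    totals = table.counts.sum(axis=1)
    zero = frozenset(str(s) for s in totals.index[totals == 0])
    safe = totals.replace(0, 1)
    values = table.counts.div(safe, axis=0).astype(float)
    return RelAbundTable(values, zero_total_samples=zero)


def presence(table: AsvCountTable, min_count: int = 1) -> pd.DataFrame:
    """Boolean presence matrix: entry true iff count >= ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return table.counts.ge(min_count)
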