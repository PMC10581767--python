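"""Strict classification of vertical transmission and its summaries.

An ASV counts as vertically transmitted within a pedigree and parental
lineage when it is (i) present in at least one parental-colony worker
sample of that lineage, (ii) present in EVERY founding-reproductive
(alate) sample of that lineage and pedigree, and (iii) present in at
least one offspring-colony sample of the pedigree.  Presence is a
per-sample boolean (by default >= 1 read after dataset-level filtering).

Parental-colony presence is evaluated on worker samples only by default,
since workers house most of the colony microbiome; a ``parental_castes``
switch admits other castes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import RelAbundTable, SampleMetadata, TaxonomyTable

__all__ = [
    "InheritanceCall",
    "ParentageStatus",
    "classify_vertical",
    "classify_dataset",
    "attribute_parentage",
    "sample_inherited_summary",
    "pedigree_sharing",
    "genus_overlap",
    "founder_to_offspring_retention",
    "calls_to_frame",
]

Lineage = Literal["maternal", "paternal"]


@dataclass(frozen=True)
class InheritanceCall:
    """Per-(ASV, pedigree, lineage) transmission-stage flags."""

    asv_id: str
    pedigree: str
    lineage: Lineage
    present_in_parental_workers: bool
    in_all_founders: bool
    in_any_offspring: bool

    @property
    def transmitted_to_founders(self) -> bool:
        return self.present_in_parental_workers and self.in_all_founders

    @property
    def vertically_transmitted(self) -> bool:
        return self.transmitted_to_founders and self.in_any_offspring


@dataclass(frozen=True)
class ParentageStatus:
    """Which parental lineage(s) an ASV's inheritance traces to."""

    asv_id: str
    pedigree: str
    status: Literal["maternal", "paternal", "shared", "none"]


def classify_vertical(
    presence: pd.DataFrame,
    metadata: SampleMetadata,
    pedigree: str,
    lineage: Lineage,
    *,
    parental_castes: Sequence[str] = ("worker",),
) -> list[InheritanceCall]:
    """Classify every ASV's transmission stages for one pedigree x lineage.

    ``presence`` is a samples x ASVs boolean matrix.  The shared paternal
    parental colony may carry no pedigree label; its samples are admitted
    for any pedigree.
    """
    parental = metadata.select(
        generation="parental",
        parental_role=lineage,
        pedigree_or_na=pedigree,
        castes=parental_castes,
    )
    founders = metadata.select(generation="founder", parental_role=lineage, pedigree=pedigree)
    offspring = metadata.select(generation="offspring", pedigree=pedigree)
    for tier, ids in (
        ("parental workers", parental),
        ("founders", founders),
        ("offspring", offspring),
    ):
        if not ids:
            raise ValueError(
                f"no {tier} samples for pedigree={pedigree!r} lineage={lineage!r}"
            )
        missing = set(ids) - set(presence.index)
        if missing:
            raise ValueError(f"{tier} sample(s) missing from presence matrix: {sorted(missing)}")

    in_parental = presence.loc[parental].any(axis=0)
    in_all_founders = presence.loc[founders].all(axis=0)
    in_any_offspring = presence.loc[offspring].any(axis=0)
    return [
        InheritanceCall(
            asv_id=str(asv),
            pedigree=pedigree,
            lineage=lineage,
            present_in_parental_workers=bool(in_parental[asv]),
            in_all_founders=bool(in_all_founders[asv]),
            in_any_offspring=bool(in_any_offspring[asv]),
        )
        for asv in presence.columns
    ]


def classify_dataset(
    presence: pd.DataFrame,
    metadata: SampleMetadata,
    *,
    lineages: Sequence[Lineage] = ("maternal", "paternal"),
    parental_castes: Sequence[str] = ("worker",),
) -> dict[tuple[str, str], list[InheritanceCall]]:
    """Classify all pedigrees x lineages present in the metadata."""
    out: dict[tuple[str, str], list[InheritanceCall]] = {}
    for pedigree in metadata.pedigrees():
        for lineage in lineages:
            out[(pedigree, lineage)] = classify_vertical(
                presence, metadata, pedigree, lineage, parental_castes=parental_castes
            )
    return out


def attribute_parentage(
    maternal_calls: Sequence[InheritanceCall],
    paternal_calls: Sequence[InheritanceCall],
) -> list[ParentageStatus]:
    """Merge per-lineage calls into maternal / paternal / shared / none."""
    m = {c.asv_id: c for c in maternal_calls}
    p = {c.asv_id: c for c in paternal_calls}
    if set(m) != set(p):
        raise ValueError("maternal and paternal calls cover different ASV universes")
    peds_m = {c.pedigree for c in maternal_calls}
    peds_p = {c.pedigree for c in paternal_calls}
    if len(peds_m | peds_p) != 1:
        raise ValueError("calls span more than one pedigree")
    pedigree = next(iter(peds_m))
    out = []
    for asv in m:
        mt, pt = m[asv].vertically_transmitted, p[asv].vertically_transmitted
        if mt and pt:
            status = "shared"
        elif mt:
            status = "maternal"
        elif pt:
            status = "paternal"
        else:
            status = "none"
        out.append(ParentageStatus(asv_id=asv, pedigree=pedigree, status=status))
    return out


def _inherited_asvs(calls: Iterable[InheritanceCall | ParentageStatus]) -> set[str]:
    inherited: set[str] = set()
    for c in calls:
        if isinstance(c, ParentageStatus):
            if c.status != "none":
                inherited.add(c.asv_id)
        elif c.vertically_transmitted:
            inherited.add(c.asv_id)
    return inherited


def sample_inherited_summary(
    relabund: RelAbundTable,
    presence: pd.DataFrame,
    calls: Sequence[InheritanceCall | ParentageStatus],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample inherited fractions of community abundance and richness.

    ``inherited_relabund_fraction`` sums the relative abundances of
    inherited ASVs present in the sample; ``inherited_asv_fraction`` is the
    share of present ASVs that are inherited.  Samples with zero ASVs
    present get NaN fractions and ``defined`` False.
    """
    inherited = _inherited_asvs(calls)
    ids = list(sample_ids) if sample_ids is not None else list(presence.index)
    inherited_mask = presence.columns.isin(inherited)
    rows = []
    for sample in ids:
        pres = presence.loc[sample].to_numpy()
        n_present = int(pres.sum())
        if n_present == 0:
            rows.append((sample, np.nan, np.nan, 0, False))
            continue
        both = pres & inherited_mask
        rel = float(relabund.values.loc[sample].to_numpy()[both].sum())
        frac = float(both.sum()) / n_present
        rows.append((sample, rel, frac, n_present, True))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "inherited_relabund_fraction",
            "inherited_asv_fraction",
            "n_asvs_present",
            "defined",
        ],
    ).set_index("sample_id")


def pedigree_sharing(
    calls_by_pedigree: Mapping[str, Sequence[InheritanceCall]],
) -> dict[tuple[str, ...], int]:
    """Partition vertically transmitted ASVs by the pedigree set they occur in.

    Returns counts keyed by sorted pedigree tuples; every transmitted ASV
    falls in exactly one cell, so the cells sum to the union size.
    """
    if len(calls_by_pedigree) < 2:
        raise ValueError("pedigree_sharing needs >= 2 classified pedigrees")
    membership: dict[str, set[str]] = {}
    for pedigree, calls in calls_by_pedigree.items():
        for c in calls:
            if c.vertically_transmitted:
                membership.setdefault(c.asv_id, set()).add(pedigree)
    partition: dict[tuple[str, ...], int] = {}
    for peds in membership.values():
        key = tuple(sorted(peds))
        partition[key] = partition.get(key, 0) + 1
    return partition


def genus_overlap(
    calls_by_pedigree: Mapping[str, Sequence[InheritanceCall]],
    taxonomy: TaxonomyTable,
) -> pd.DataFrame:
    """Pairwise fraction of inherited genera shared between pedigrees.

    For pedigrees i, j with inherited-genus sets G_i, G_j the cell is
    |G_i & G_j| / mean(|G_i|, |G_j|); symmetric, diagonal 1, NaN where a
    pedigree inherited no genus.
    """
    genus_of = taxonomy.genus_labels()
    genera: dict[str, set[str]] = {}
    for pedigree, calls in calls_by_pedigree.items():
        inherited = _inherited_asvs(calls)
        missing = inherited - set(genus_of.index)
        if missing:
            raise ValueError(f"taxonomy does not cover inherited ASV(s): {sorted(missing)[:5]}")
        genera[pedigree] = {genus_of[a] for a in inherited}
    peds = sorted(genera)
    mat = pd.DataFrame(np.nan, index=peds, columns=peds, dtype=float)
    for i in peds:
        for j in peds:
            gi, gj = genera[i], genera[j]
            if not gi or not gj:
                continue  # undefined cell, left NaN
            if i == j:
                mat.loc[i, j] = 1.0
            else:
                mat.loc[i, j] = len(gi & gj) / ((len(gi) + len(gj)) / 2.0)
    return mat


def founder_to_offspring_retention(
    calls: Sequence[InheritanceCall],
) -> dict[str, float]:
    """Fraction of founder-transmitted ASVs retained in offspring colonies.

    Returned per pedigree plus a ``pooled`` entry over all calls; NaN where
    no ASV reached the founders.
    """
    by_ped: dict[str, list[InheritanceCall]] = {}
    for c in calls:
        by_ped.setdefault(c.pedigree, []).append(c)

    def _ratio(cs: Sequence[InheritanceCall]) -> float:
        denom = sum(c.transmitted_to_founders for c in cs)
        if denom == 0:
            return float("nan")
        return sum(c.vertically_transmitted for c in cs) / denom

    out = {ped: _ratio(cs) for ped, cs in sorted(by_ped.items())}
    out["pooled"] = _ratio(calls)
    return out


def calls_to_frame(calls: Sequence[InheritanceCall]) -> pd.DataFrame:
    """Tabular view of inheritance calls (for TSV export)."""
    return pd.DataFrame(
        {
            "asv_id": [c.asv_id for c in calls],
            "pedigree": [c.pedigree for c in calls],
            "lineage": [c.lineage for c in calls],
            "present_in_parental_workers": [c.present_in_parental_workers for c in calls],
            "in_all_founders": [c.in_all_founders for c in calls],
            "in_any_offspring": [c.in_any_offspring for c in calls],
            "transmitted_to_founders": [c.transmitted_to_founders for c in calls],
            "vertically_transmitted": [c.vertically_transmitted for c in calls],
        }
    )
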