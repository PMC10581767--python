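"""Within-genus abundance centering and transmission-association testing.

Relative abundances are centered by subtracting the genus mean from each
ASV, so that within-genus rank (is this strain abundant *for its genus*?)
is separated from between-genus composition.  A signed log transform
y(x) = sign(x) * ln(1 + |x| / 1e-5) spreads the centered values for
visualization while preserving sign and order.  The association between
centered abundance and transmission status is tested by permuting labels
within (pedigree, genus) strata, which controls both grouping factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import TaxonomyTable
from .null_model import NullSummary, permutation_pvalue

__all__ = [
    "CenteredAbundance",
    "center_within_genus",
    "signed_log_transform",
    "transmission_association",
]

#: pseudo-scale of the signed log transform (dimensionless abundance units)
SIGNED_LOG_SCALE = 1e-5


@dataclass(frozen=True)
class CenteredAbundance:
    asv_id: str
    context: str
    genus: str
    value: float


def center_within_genus(
    relabund: Mapping[str, float] | pd.Series,
    taxonomy: TaxonomyTable,
    context: str = "",
) -> list[CenteredAbundance]:
    """Subtract each genus's mean relative abundance from its ASVs.

    ``relabund`` holds one (typically sample-tier-averaged) relative
    abundance per ASV.  Unresolved genera use the grouped
    ``unclassified_*`` labels, so values within each group sum to zero.
    """
    s = pd.Series(relabund, dtype=float)
    genus_of = taxonomy.genus_labels()
    missing = set(s.index) - set(genus_of.index)
    if missing:
        raise ValueError(f"taxonomy does not cover ASV(s): {sorted(missing)[:5]}")
    genus = genus_of.loc[s.index]
    centered = s - s.groupby(genus).transform("mean")
    return [
        CenteredAbundance(asv_id=str(a), context=context, genus=str(genus[a]), value=float(v))
        for a, v in centered.items()
    ]


def signed_log_transform(x, scale: float = SIGNED_LOG_SCALE):
    """Odd, monotone log spread of centered abundances.

    y(x) = sign(x) * ln(1 + |x| / scale); y(0) = 0 and y(scale) = ln 2.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.log1p(np.abs(x) / scale)
    return out if out.ndim else float(out)


def transmission_association(
    centered: Sequence[CenteredAbundance],
    labels: Mapping[str, bool],
    strata: Mapping[str, object] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> NullSummary:
    """Stratified permutation test of centered abundance vs transmission.

    The statistic is the mean centered abundance of transmitted ASVs minus
    that of non-transmitted ASVs.  The null is built by shuffling labels
    within strata (default stratum: the genus recorded on each value;
    supply ``strata`` to stratify by (pedigree, genus) or similar), which
    keeps per-stratum label counts fixed.  Strata containing a single
    label class are uninformative and are dropped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.array([c.value for c in centered], dtype=float)
    asvs = [c.asv_id for c in centered]
    missing = set(asvs) - set(labels)
    if missing:
        raise ValueError(f"labels missing for ASV(s): {sorted(missing)[:5]}")
    lab = np.array([bool(labels[a]) for a in asvs])
    if strata is None:
        strat = [c.genus for c in centered]
    else:
        strat = [strata[a] for a in asvs]

    by_stratum: dict[object, list[int]] = {}
    for i, key in enumerate(strat):
        by_stratum.setdefault(key, []).append(i)
    keep = np.zeros(len(values), dtype=bool)
    groups: list[np.ndarray] = []
    for key, members in by_stratum.items():
        idx = np.asarray(members)
        if lab[idx].all() or (~lab[idx]).all():
            warnings.warn(f"stratum {key!r} has a single label class; dropped", stacklevel=2)
            continue
        keep[idx] = True
        groups.append(idx)
    if not groups:
        raise ValueError("every stratum is degenerate (single label class)")

    def _stat(labels_arr: np.ndarray) -> float:
        sel = labels_arr & keep
        not_sel = ~labels_arr & keep
        return float(values[sel].mean() - values[not_sel].mean())

    observed = _stat(lab)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = lab.copy()
        for idx in groups:
            perm[idx] = lab[idx][rng.permutation(len(idx))]
        null[i] = _stat(perm)
    return permutation_pvalue(observed, null, alternative="two_sided")
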