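"""Abundance-weighted resampling null model and permutation p-values.

The null model asks whether inheritance can be explained by abundance
alone: it repeatedly draws ASV sets of the observed inherited size from
the maternal-worker pool, with selection probability proportional to the
ASV's mean relative abundance in those workers, and summarizes each draw
(e.g. genus richness).  Observed statistics are compared to the null
distribution with proportion-based permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import TaxonomyTable

__all__ = [
    "NullDraws",
    "NullSummary",
    "draw_null_sets",
    "genus_richness_distribution",
    "permutation_pvalue",
]

Alternative = Literal["less", "greater", "two_sided"]


@dataclass(frozen=True)
class NullDraws:
    """Iterated abundance-weighted ASV selections."""

    iterations: int
    seed: int
    n_select: int
    draws: tuple[frozenset[str], ...]
    weight_source: str = "maternal_workers"

    def __post_init__(self) -> None:
        if len(self.draws) != self.iterations:
            raise ValueError("draws length must equal iterations")
        for d in self.draws:
            if len(d) != self.n_select:
                raise ValueError("every draw must contain exactly n_select ASVs")


@dataclass(frozen=True)
class NullSummary:
    """Observed statistic against its resampling null distribution.

    ``p_raw`` is the plain proportion of null values in the observed
    tail (ties included); ``p_corrected`` is the add-one version
    (count + 1) / (iterations + 1), which cannot be zero.
    """

    observed_statistic: float
    null_values: tuple[float, ...]
    p_raw: float
    p_corrected: float
    alternative: Alternative
    correction: Literal["raw", "add_one"] = "raw"

    @property
    def p(self) -> float:
        return self.p_raw if self.correction == "raw" else self.p_corrected


def draw_null_sets(
    weights: Mapping[str, float] | pd.Series,
    n_select: int,
    iterations: int = 100,
    seed: int = 0,
    weight_source: str = "maternal_workers",
) -> NullDraws:
    """Draw ``iterations`` ASV sets of size ``n_select`` without replacement.

    Each draw is a sequential weighted sample: at every step an ASV is
    selected with probability proportional to its weight among those not
    yet drawn.  Implemented with the exponential-race equivalence (each
    ASV gets an Exp(weight) arrival time; the ``n_select`` earliest form
    the draw), which has exactly the sequential-renormalization law.
    Zero-weight ASVs can never be drawn.
    """
    w = pd.Series(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    pool = w.index[w > 0]
    if len(pool) == 0:
        raise ValueError("all weights are zero")
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if n_select > len(pool):
        raise ValueError(
            f"n_select={n_select} exceeds positive-weight pool of {len(pool)} ASVs"
        )
    rng = np.random.default_rng(seed)
    wv = w.loc[pool].to_numpy()
    ids = np.asarray(pool, dtype=object)
    draws = []
    for _ in range(iterations):
        arrival = rng.standard_exponential(len(pool)) / wv
        chosen = ids[np.argpartition(arrival, n_select - 1)[:n_select]]
        draws.append(frozenset(str(a) for a in chosen))
    return NullDraws(
        iterations=iterations,
        seed=seed,
        n_select=n_select,
        draws=tuple(draws),
        weight_source=weight_source,
    )


def genus_richness_distribution(
    draws: NullDraws,
    taxonomy: TaxonomyTable,
) -> list[int]:
    """Distinct-genus count of each null draw (unclassified grouping applies)."""
    genus_of = taxonomy.genus_labels()
    drawn = set().union(*draws.draws) if draws.draws else set()
    missing = drawn - set(genus_of.index)
    if missing:
        raise ValueError(f"taxonomy does not cover drawn ASV(s): {sorted(missing)[:5]}")
    return [len({genus_of[a] for a in d}) for d in draws.draws]


def permutation_pvalue(
    observed: float,
    null_values: Sequence[float],
    alternative: Alternative,
    correction: Literal["raw", "add_one"] = "raw",
) -> NullSummary:
    """Proportion-based permutation p-value.

    ``alternative`` names the side on which the observed value is held to
    be extreme: with ``less``, p is the proportion of null values at or
    below the observed statistic (equivalently one minus the proportion
    strictly above it), so 96 of 100 null values above the observed gives
    p = 0.04.  Ties count toward the tail (conservative).  ``two_sided``
    doubles the smaller tail, capped at 1.  The add-one correction
    (count + 1) / (n + 1) is always reported alongside and never zero.
    """
    nv = np.asarray(null_values, dtype=float)
    if nv.size == 0:
        raise ValueError("null_values must be non-empty")
    n = nv.size
    c_less = int((nv <= observed).sum())
    c_greater = int((nv >= observed).sum())
    if alternative == "less":
        p_raw = c_less / n
        p_add = (c_less + 1) / (n + 1)
    elif alternative == "greater":
        p_raw = c_greater / n
        p_add = (c_greater + 1) / (n + 1)
    elif alternative == "two_sided":
        p_raw = min(1.0, 2.0 * min(c_less, c_greater) / n)
        p_add = min(1.0, 2.0 * (min(c_less, c_greater) + 1) / (n + 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return NullSummary(
        observed_statistic=float(observed),
        null_values=tuple(float(v) for v in nv),
        p_raw=p_raw,
        p_corrected=p_add,
        alternative=alternative,
        correction=correction,
    )
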