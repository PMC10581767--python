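"""Pedigree-structured synthetic ASV datasets with planted ground truth.

The generator emulates the study design the pipeline targets: several
maternal colonies crossed with a single shared paternal colony, each
cross giving one pedigree with three sample tiers — parental-colony
workers, founding reproductives (alates), and offspring-colony workers —
all observed as pooled-gut amplicon samples.

Community model, per colony:

* a global pool of ASVs nested in genera (genus sizes geometric);
* each colony carries a random subset of the pool with log-normal
  expected relative abundances;
* a planted *heritable* fraction of each colony's ASVs is boosted in
  founder samples (``founder_enrichment``) and is the only parental
  material that reaches offspring colonies;
* non-heritable parental ASVs drop out of each founder sample
  independently with probability ``founder_dropout``;
* offspring communities mix the maternal and paternal heritable sets
  with an environment-only ASV pool that never occurs in parents;
* read counts per sample are Dirichlet-multinomial at fixed depth.
  ``overdispersion`` is the per-taxon concentration at mean abundance
  (alpha_i = overdispersion * S * q_i for a community of S taxa):
  large values approach a pure multinomial, small values give strong
  compositional noise and presence/absence dropout.

By construction, planted heritable ASVs occur in parental workers, in
every founder sample of their lineage, and in offspring expected
compositions; with default (mild) noise the strict classification rule
recovers them nearly exactly, which is what the planted-truth regression
tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AsvCountTable, SampleMetadata, TaxonomyTable, RANKS
from .inheritance import InheritanceCall
from .network_assort import SignedNetwork

__all__ = [
    "SimParams",
    "GroundTruth",
    "generate_pedigree_dataset",
    "generate_signed_network",
    "recovery_scores",
    "DEFAULT_PEDIGREE_NAMES",
]

DEFAULT_PEDIGREE_NAMES = ("red", "yellow", "blue", "green")

HERITABLE_CLASSES = {
    "maternal": ("heritable_maternal", "heritable_shared"),
    "paternal": ("heritable_paternal", "heritable_shared"),
}


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults mirror the target study design."""

    n_pedigrees: int = 4
    n_genera: int = 60
    asvs_per_genus_mean: float = 5.0
    frac_heritable: float = 0.25
    founder_enrichment: float = 3.0
    founder_dropout: float = 0.8
    env_pool_size: int = 200
    depth: int = 50_000
    overdispersion: float = 50.0
    n_parental_workers: int = 2
    n_founders: int = 3
    n_offspring: int = 3
    lognormal_sigma: float = 0.8
    colony_occupancy: float = 0.8
    offspring_inherited_mass: float = 0.5
    env_occupancy: float = 0.6
    frac_unresolved_genus: float = 0.05
    seed: int = 1729

    def __post_init__(self) -> None:
        for name in (
            "frac_heritable",
            "founder_dropout",
            "colony_occupancy",
            "offspring_inherited_mass",
            "env_occupancy",
            "frac_unresolved_genus",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_pedigrees < 1:
            raise ValueError("n_pedigrees must be >= 1")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive (use math.inf for none)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-(ASV, pedigree) class labels.

    Classes: heritable_maternal, heritable_paternal, heritable_shared,
    parental_only, environmental; mutually exclusive per (asv, pedigree).
    """

    table: pd.DataFrame  # columns: asv_id, pedigree, planted_class

    def heritable_set(self, pedigree: str, lineage: str) -> set[str]:
        classes = HERITABLE_CLASSES[lineage]
        df = self.table
        mask = (df["pedigree"] == pedigree) & df["planted_class"].isin(classes)
        return set(df.loc[mask, "asv_id"])

    def pedigrees(self) -> list[str]:
        return sorted(self.table["pedigree"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _dirichlet_multinomial(
    rng: np.random.Generator,
    proportions: np.ndarray,
    depth: int,
    overdispersion: float,
) -> np.ndarray:
    """One pooled-gut sample: DM counts summing exactly to ``depth``."""
    q = np.asarray(proportions, dtype=float)
    if q.sum() <= 0:
        return np.zeros(len(q), dtype=np.int64)
    q = q / q.sum()
    pos = q > 0
    p = np.zeros(len(q))
    if np.isinf(overdispersion):
        p[pos] = q[pos]
    else:
        alpha = overdispersion * pos.sum() * q[pos]
        p[pos] = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


def _lognormal_abundances(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


def _build_taxonomy(rng: np.random.Generator, params: SimParams) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Global ASV pool: genus-nested core ASVs plus an environmental pool."""
    sizes = rng.geometric(1.0 / params.asvs_per_genus_mean, size=params.n_genera)
    core_ids: list[str] = []
    rows: dict[str, dict[str, object]] = {}
    counter = 0
    for g in range(params.n_genera):
        genus = f"g{g:03d}"
        family = f"fam{g // 3:03d}"
        order = f"ord{g // 6:02d}"
        clazz = f"cls{g // 12:02d}"
        phylum = f"phy{g // 20}"
        for _ in range(int(sizes[g])):
            asv = f"asv{counter:05d}"
            counter += 1
            core_ids.append(asv)
            unresolved = rng.random() < params.frac_unresolved_genus
            rows[asv] = {
                "phylum": phylum,
                "class": clazz,
                "order": order,
                "family": family,
                "genus": None if unresolved else genus,
            }
    env_ids: list[str] = []
    for _ in range(params.env_pool_size):
        g = int(rng.integers(params.n_genera))
        asv = f"env{len(env_ids):05d}"
        env_ids.append(asv)
        rows[asv] = {
            "phylum": f"phy{g // 20}",
            "class": f"cls{g // 12:02d}",
            "order": f"ord{g // 6:02d}",
            "family": f"fam{g // 3:03d}",
            "genus": f"g{g:03d}",
        }
    tax = pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)]
    return core_ids, tax, env_ids


def _colony_community(
    rng: np.random.Generator, core_ids: Sequence[str], params: SimParams
) -> pd.Series:
    """A colony's expected relative abundances over the core pool."""
    present = rng.random(len(core_ids)) < params.colony_occupancy
    if not present.any():
        present[int(rng.integers(len(core_ids)))] = True
    q = np.zeros(len(core_ids))
    q[present] = _lognormal_abundances(rng, int(present.sum()), params.lognormal_sigma)
    return pd.Series(q, index=list(core_ids))


def generate_pedigree_dataset(
    params: SimParams | None = None,
) -> tuple[AsvCountTable, TaxonomyTable, SampleMetadata, GroundTruth]:
    """Simulate the full pedigree dataset with planted inheritance truth."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    core_ids, tax_df, env_ids = _build_taxonomy(rng, params)
    all_ids = core_ids + env_ids

    ped_names = [
        DEFAULT_PEDIGREE_NAMES[i] if i < len(DEFAULT_PEDIGREE_NAMES) else f"ped{i + 1}"
        for i in range(params.n_pedigrees)
    ]

    paternal_q = _colony_community(rng, core_ids, params)
    paternal_present = set(paternal_q.index[paternal_q > 0])
    n_pat_her = int(round(params.frac_heritable * len(paternal_present)))
    paternal_heritable = set(
        rng.choice(sorted(paternal_present), size=n_pat_her, replace=False)
    ) if n_pat_her else set()

    maternal_q: dict[str, pd.Series] = {}
    maternal_heritable: dict[str, set[str]] = {}
    env_present: dict[str, set[str]] = {}
    for ped in ped_names:
        q = _colony_community(rng, core_ids, params)
        maternal_q[ped] = q
        present = sorted(q.index[q > 0])
        n_her = int(round(params.frac_heritable * len(present)))
        maternal_heritable[ped] = (
            set(rng.choice(present, size=n_her, replace=False)) if n_her else set()
        )
        env_present[ped] = {e for e in env_ids if rng.random() < params.env_occupancy}

    # --- ground truth -----------------------------------------------------
    truth_rows: list[tuple[str, str, str]] = []
    for ped in ped_names:
        m_her = maternal_heritable[ped]
        for asv in sorted(set(maternal_q[ped].index[maternal_q[ped] > 0]) | paternal_present):
            in_m = asv in m_her
            in_p = asv in paternal_heritable
            if in_m and in_p:
                klass = "heritable_shared"
            elif in_m:
                klass = "heritable_maternal"
            elif in_p:
                klass = "heritable_paternal"
            else:
                klass = "parental_only"
            truth_rows.append((asv, ped, klass))
        for asv in sorted(env_present[ped]):
            truth_rows.append((asv, ped, "environmental"))
    truth = GroundTruth(
        pd.DataFrame(truth_rows, columns=["asv_id", "pedigree", "planted_class"])
    )

    # --- samples ----------------------------------------------------------
    col_index = {a: i for i, a in enumerate(all_ids)}
    sample_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict[str, object]] = []

    def _expand(q: pd.Series) -> np.ndarray:
        full = np.zeros(len(all_ids))
        full[[col_index[a] for a in q.index]] = q.to_numpy()
        return full

    def _add_sample(name: str, q_full: np.ndarray, meta: dict[str, object]) -> None:
        counts = _dirichlet_multinomial(rng, q_full, params.depth, params.overdispersion)
        sample_rows.append(counts)
        sample_ids.append(name)
        meta_rows.append({"sample_id": name, "guts_pooled": int(rng.integers(5, 11)), **meta})

    def _founder_q(base: pd.Series, heritable: set[str]) -> pd.Series:
        """One founder sample's expected composition (fresh dropout mask)."""
        q = base.copy()
        her = q.index.isin(heritable)
        q[her] *= params.founder_enrichment
        non_her = (~her) & (q.to_numpy() > 0)
        drop = rng.random(len(q)) < params.founder_dropout
        q[non_her & drop] = 0.0
        return q

    # shared paternal parental workers (no pedigree label)
    for i in range(params.n_parental_workers):
        _add_sample(
            f"paternal_worker_{i + 1}",
            _expand(paternal_q),
            {
                "pedigree": None,
                "generation": "parental",
                "parental_role": "paternal",
                "caste": "worker",
                "colony_id": "paternal_colony",
            },
        )

    for ped in ped_names:
        m_q = maternal_q[ped]
        m_her = maternal_heritable[ped]
        for i in range(params.n_parental_workers):
            _add_sample(
                f"{ped}_maternal_worker_{i + 1}",
                _expand(m_q),
                {
                    "pedigree": ped,
                    "generation": "parental",
                    "parental_role": "maternal",
                    "caste": "worker",
                    "colony_id": f"{ped}_maternal_colony",
                },
            )
        for lineage, base, heritable, colony in (
            ("maternal", m_q, m_her, f"{ped}_maternal_colony"),
            ("paternal", paternal_q, paternal_heritable, "paternal_colony"),
        ):
            for i in range(params.n_founders):
                _add_sample(
                    f"{ped}_{lineage}_founder_{i + 1}",
                    _expand(_founder_q(base, heritable)),
                    {
                        "pedigree": ped,
                        "generation": "founder",
                        "parental_role": lineage,
                        "caste": "alate",
                        "colony_id": colony,
                    },
                )
        # offspring: inherited mixture plus environment-only ASVs
        inherited_w = pd.Series(0.0, index=all_ids)
        for asv in m_her:
            inherited_w[asv] += m_q[asv] * params.founder_enrichment
        for asv in paternal_heritable:
            inherited_w[asv] += paternal_q[asv] * params.founder_enrichment
        env_w = pd.Series(0.0, index=all_ids)
        env_list = sorted(env_present[ped])
        if env_list:
            env_w[env_list] = _lognormal_abundances(rng, len(env_list), params.lognormal_sigma)
        off_q = np.zeros(len(all_ids))
        if inherited_w.sum() > 0 and env_w.sum() > 0:
            off_q = (
                params.offspring_inherited_mass * inherited_w.to_numpy() / inherited_w.sum()
                + (1 - params.offspring_inherited_mass) * env_w.to_numpy() / env_w.sum()
            )
        elif inherited_w.sum() > 0:
            off_q = inherited_w.to_numpy() / inherited_w.sum()
        elif env_w.sum() > 0:
            off_q = env_w.to_numpy() / env_w.sum()
        for i in range(params.n_offspring):
            _add_sample(
                f"{ped}_offspring_worker_{i + 1}",
                off_q,
                {
                    "pedigree": ped,
                    "generation": "offspring",
                    "parental_role": "na",
                    "caste": "worker",
                    "colony_id": f"{ped}_offspring_pool",
                },
            )

    counts = AsvCountTable(
        pd.DataFrame(np.vstack(sample_rows), index=sample_ids, columns=all_ids)
    )
    taxonomy = TaxonomyTable(tax_df)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = SampleMetadata(
        meta[["pedigree", "generation", "parental_role", "caste", "colony_id", "guts_pooled"]]
    )
    return counts, taxonomy, metadata, truth


def generate_signed_network(
    n_nodes: int,
    block_labels: Sequence[object],
    p_within_positive: float,
    p_between_positive: float,
    p_negative: float,
    seed: int = 0,
) -> tuple[SignedNetwork, dict[str, object]]:
    """Planted-partition signed graph with known block labels.

    Positive edges appear with probability ``p_within_positive`` inside a
    block and ``p_between_positive`` between blocks; pairs without a
    positive edge get an independent negative edge with ``p_negative``.
    """
    for name, p in (
        ("p_within_positive", p_within_positive),
        ("p_between_positive", p_between_positive),
        ("p_negative", p_negative),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if len(block_labels) != n_nodes:
        raise ValueError("block_labels must have one entry per node")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:04d}" for i in range(n_nodes)]
    labels = {nodes[i]: block_labels[i] for i in range(n_nodes)}
    edges: list[tuple[str, str, str]] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = block_labels[i] == block_labels[j]
            p_pos = p_within_positive if same else p_between_positive
            if rng.random() < p_pos:
                edges.append((nodes[i], nodes[j], "positive"))
            elif rng.random() < p_negative:
                edges.append((nodes[i], nodes[j], "negative"))
    return SignedNetwork.from_edges(nodes, edges), labels


def recovery_scores(
    calls_by: Mapping[tuple[str, str], Sequence[InheritanceCall]],
    truth: GroundTruth,
) -> dict[str, float]:
    """Precision/recall of classified vs planted heritable sets.

    Micro-averaged over every classified (pedigree, lineage); also
    reports per-group values under ``"precision:<pedigree>:<lineage>"``
    keys.  Precision is 1.0 by convention when nothing was called.
    """
    tp = fp = fn = 0
    out: dict[str, float] = {}
    for (ped, lineage), calls in calls_by.items():
        planted = truth.heritable_set(ped, lineage)
        called = {c.asv_id for c in calls if c.vertically_transmitted}
        g_tp = len(called & planted)
        g_fp = len(called - planted)
        g_fn = len(planted - called)
        tp, fp, fn = tp + g_tp, fp + g_fp, fn + g_fn
        out[f"precision:{ped}:{lineage}"] = g_tp / (g_tp + g_fp) if called else 1.0
        out[f"recall:{ped}:{lineage}"] = g_tp / (g_tp + g_fn) if planted else 1.0
    out["n_called"] = float(tp + fp)
    out["n_planted"] = float(tp + fn)
    out["precision"] = tp / (tp + fp) if (tp + fp) else 1.0
    out["recall"] = tp / (tp + fn) if (tp + fn) else 1.0
    return out
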