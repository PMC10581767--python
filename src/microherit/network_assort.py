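"""Inheritance assortativity of signed ASV co-occurrence networks.

Signed networks (positive = co-occurrence, negative = co-exclusion)
arrive as edge lists from any inference tool.  Newman's categorical
assortativity coefficient is computed on the edge mixing matrix for the
node attribute "inherited vs non-inherited": r = +1 when edges only join
same-class nodes, negative when classes preferentially interconnect.
The observed coefficient is compared against labelings drawn from the
abundance-weighted null model on the same, fixed topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import AsvCountTable, filter_min_total_reads
from .null_model import NullDraws, permutation_pvalue

__all__ = [
    "SignedNetwork",
    "AssortResult",
    "prefilter_for_network",
    "subset_by_sign",
    "assortativity",
    "null_assortativity",
    "degree_features",
    "read_edgelist",
]

Sign = Literal["positive", "negative"]


@dataclass(frozen=True)
class SignedNetwork:
    """Undirected ASV graph whose edges carry a sign attribute."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if data.get("sign") not in ("positive", "negative"):
                raise ValueError(f"edge {u!r}-{v!r} lacks a valid sign")

    @classmethod
    def from_edges(
        cls,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str, Sign]] | Iterable[tuple[str, str, Sign, float]],
    ) -> "SignedNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for edge in edges:
            u, v, sign = edge[0], edge[1], edge[2]
            weight = float(edge[3]) if len(edge) > 3 else 1.0
            if not (g.has_node(u) and g.has_node(v)):
                raise ValueError(f"edge endpoint not in node set: {u!r}-{v!r}")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v, sign=sign, weight=weight)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class AssortResult:
    """Observed assortativity against the null-labeling distribution."""

    r: float | None
    edge_sign: Literal["positive", "negative", "all"]
    n_edges: int
    null_r: tuple[float, ...]
    p_raw: float
    p_add_one: float
    alternative: str = "greater"


def prefilter_for_network(table: AsvCountTable, threshold: int = 200) -> AsvCountTable:
    """Drop ASVs with fewer than ``threshold`` reads across all samples.

    Same strict-less-than rule as the dataset filter, with the higher
    default used before network construction.
    """
    return filter_min_total_reads(table, threshold)


def subset_by_sign(net: SignedNetwork, sign: Sign) -> SignedNetwork:
    """Keep only edges of one sign; all nodes are retained."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    kept = [(u, v, d) for u, v, d in net.graph.edges(data=True) if d["sign"] == sign]
    if not kept:
        warnings.warn(f"no {sign} edges in network", stacklevel=2)
    g.add_edges_from(kept)
    return SignedNetwork(g)


def assortativity(net: SignedNetwork, labels: Mapping[str, object]) -> float | None:
    """Newman categorical assortativity of node labels over the edges.

    Builds the symmetric edge mixing matrix e (each edge contributes half
    to (c_u, c_v) and half to (c_v, c_u)) and returns
    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) with a, b the
    marginals.  Returns None (undefined) when every edge joins nodes of a
    single class, where the denominator vanishes.
    """
    g = net.graph
    unlabeled = [n for n in g.nodes if n not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled node(s): {sorted(map(str, unlabeled))[:5]}")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("assortativity is undefined on an edgeless network")
    cats = sorted({str(labels[n]) for n in g.nodes})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in g.edges:
        cu, cv = idx[str(labels[u])], idx[str(labels[v])]
        e[cu, cv] += 1.0
        e[cv, cu] += 1.0
    e /= 2.0 * m
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    denom = 1.0 - float(a @ b)
    if denom == 0.0:
        return None
    return (float(np.trace(e)) - float(a @ b)) / denom


def null_assortativity(
    net: SignedNetwork,
    null_label_sets: NullDraws | Sequence[frozenset[str]] | Sequence[set[str]],
    observed_labels: Mapping[str, object],
    edge_sign: Literal["positive", "negative", "all"] = "all",
) -> AssortResult:
    """Compare observed assortativity to abundance-driven null labelings.

    Each null draw labels drawn nodes "inherited" and the rest
    "non-inherited" on the fixed topology; the permutation p-value uses
    alternative="greater" (is the observed network more assortative than
    abundance alone predicts?).  Draws naming nodes outside the network
    are an error: restrict the null-draw pool to network nodes upstream.
    """
    draws = null_label_sets.draws if isinstance(null_label_sets, NullDraws) else list(null_label_sets)
    node_set = set(net.graph.nodes)
    r_obs = assortativity(net, observed_labels)
    null_r = []
    for i, draw in enumerate(draws):
        stray = set(draw) - node_set
        if stray:
            raise ValueError(
                f"null draw {i} references node(s) absent from network: {sorted(stray)[:5]}"
            )
        lab = {n: ("inherited" if n in draw else "non-inherited") for n in node_set}
        r = assortativity(net, lab)
        if r is None:
            warnings.warn(f"null draw {i} yields undefined assortativity; skipped", stacklevel=2)
            continue
        null_r.append(r)
    if r_obs is None:
        raise ValueError("observed assortativity is undefined (single-class edges)")
    if not null_r:
        raise ValueError("no null draw yielded a defined assortativity")
    summary = permutation_pvalue(r_obs, null_r, alternative="greater")
    return AssortResult(
        r=r_obs,
        edge_sign=edge_sign,
        n_edges=net.n_edges,
        null_r=tuple(null_r),
        p_raw=summary.p_raw,
        p_add_one=summary.p_corrected,
    )


def degree_features(net: SignedNetwork) -> pd.DataFrame:
    """Per-node counts of incident positive and negative edges."""
    pos = {n: 0 for n in net.graph.nodes}
    neg = {n: 0 for n in net.graph.nodes}
    for u, v, d in net.graph.edges(data=True):
        target = pos if d["sign"] == "positive" else neg
        target[u] += 1
        target[v] += 1
    return pd.DataFrame(
        {"positive_degree": pd.Series(pos), "negative_degree": pd.Series(neg)}
    ).rename_axis("asv_id")


def read_edgelist(path: str | Path) -> SignedNetwork:
    """Read a signed edge list TSV: node_a, node_b, sign[, weight]."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    required = {"node_a", "node_b", "sign"}
    if not required <= set(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    nodes = sorted(set(df["node_a"]) | set(df["node_b"]))
    weights = df["weight"] if "weight" in df.columns else pd.Series(1.0, index=df.index)
    edges = [
        (row.node_a, row.node_b, row.sign, float(w))
        for row, w in zip(df.itertuples(), weights)
    ]
    return SignedNetwork.from_edges(nodes, edges)
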