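import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microherit import (
    AsvCountTable,
    SignedNetwork,
    assortativity,
    degree_features,
    generate_signed_network,
    null_assortativity,
    prefilter_for_network,
    subset_by_sign,
)
from microherit.network_assort import read_edgelist

from _oracles import mixing_matrix_assortativity


def net_from(edges, nodes=None):
    if nodes is None:
        nodes = sorted({n for e in edges for n in e[:2]})
    return SignedNetwork.from_edges(nodes, edges)


@pytest.mark.parametrize("total,kept", [(199, False), (200, True)])
def test_network_prefilter_boundary(total, kept):
    table = AsvCountTable(pd.DataFrame({"A": [total], "B": [500]}, index=["S1"]))
    out = prefilter_for_network(table)
    assert ("A" in out.asv_ids) is kept


def test_subset_by_sign_keeps_nodes():
    net = net_from(
        [("A", "B", "positive"), ("B", "C", "positive"), ("C", "D", "positive"),
         ("A", "D", "negative"), ("B", "D", "negative")],
    )
    pos = subset_by_sign(net, "positive")
    assert pos.n_edges == 3
    assert set(pos.nodes) == set(net.nodes)
    with pytest.warns(UserWarning, match="negative"):
        neg = subset_by_sign(subset_by_sign(net, "positive"), "negative")
    assert neg.n_edges == 0


def test_assortativity_examples():
    # two uniformly labeled components, no cross edges -> perfect assortativity
    net = net_from([("A", "B", "positive"), ("C", "D", "positive")])
    assert assortativity(net, {"A": "i", "B": "i", "C": "n", "D": "n"}) == pytest.approx(1.0)
    # mixing-matrix worked example: edges A-B, C-D, B-C -> r = 1/3
    net2 = net_from([("A", "B", "positive"), ("C", "D", "positive"), ("B", "C", "positive")])
    labels = {"A": "i", "B": "i", "C": "n", "D": "n"}
    assert assortativity(net2, labels) == pytest.approx(1 / 3)
    # single-class labeling -> undefined, flagged as None
    assert assortativity(net2, {k: "i" for k in "ABCD"}) is None


def test_assortativity_errors():
    net = net_from([("A", "B", "positive")])
    with pytest.raises(ValueError, match="unlabeled"):
        assortativity(net, {"A": "i"})
    empty = SignedNetwork.from_edges(["A", "B"], [])
    with pytest.raises(ValueError, match="edgeless"):
        assortativity(empty, {"A": "i", "B": "n"})


def test_assortativity_label_name_covariance_and_range():
    rng = np.random.default_rng(0)
    for _ in range(30):
        g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 30)))
        if g.number_of_edges() == 0:
            continue
        edges = [(f"n{u}", f"n{v}", "positive") for u, v in g.edges]
        net = net_from(edges, nodes=[f"n{i}" for i in range(8)])
        lab = {f"n{i}": ("x" if rng.random() < 0.5 else "y") for i in range(8)}
        r = assortativity(net, lab)
        if r is None:
            continue
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        swapped = {k: ("y" if v == "x" else "x") for k, v in lab.items()}
        assert assortativity(net, swapped) == pytest.approx(r)


def test_assortativity_matches_networkx():
    """Independent library cross-check on random labeled graphs."""
    rng = np.random.default_rng(1)
    checked = 0
    for trial in range(40):
        g = nx.gnp_random_graph(10, 0.3, seed=trial)
        if g.number_of_edges() == 0:
            continue
        lab = {n: ("i" if rng.random() < 0.5 else "n") for n in g.nodes}
        nx.set_node_attributes(g, lab, "inh")
        edges = [(str(u), str(v), "positive") for u, v in g.edges]
        net = net_from(edges, nodes=[str(n) for n in g.nodes])
        r = assortativity(net, {str(n): v for n, v in lab.items()})
        if r is None:
            continue
        expected = nx.attribute_assortativity_coefficient(g, "inh")
        assert r == pytest.approx(expected, abs=1e-12)
        checked += 1
    assert checked > 20


def test_null_assortativity_degenerate_and_planted():
    net, labels = generate_signed_network(
        40, ["a"] * 20 + ["b"] * 20, p_within_positive=0.4, p_between_positive=0.02,
        p_negative=0.05, seed=3)
    pos = subset_by_sign(net, "positive")
    observed = {n: ("inherited" if labels[n] == "a" else "non-inherited") for n in pos.nodes}
    inherited_set = frozenset(n for n in pos.nodes if labels[n] == "a")
    # null labelings identical to the observed labeling -> p_raw = 1
    degenerate = null_assortativity(pos, [inherited_set] * 20, observed)
    assert all(r == pytest.approx(degenerate.r) for r in degenerate.null_r)
    assert degenerate.p_raw == 1.0
    # random null labelings: planted block structure beats them all
    rng = np.random.default_rng(4)
    nodes = list(pos.nodes)
    random_sets = [frozenset(rng.choice(nodes, size=20, replace=False)) for _ in range(50)]
    result = null_assortativity(pos, random_sets, observed)
    assert result.r > max(result.null_r)
    assert result.p_raw <= 1 / 50
    # mean null assortativity under random labels is near zero
    assert abs(np.mean(result.null_r)) < 0.1


def test_null_assortativity_stray_node_errors():
    net = net_from([("A", "B", "positive"), ("B", "C", "positive")])
    observed = {"A": "inherited", "B": "inherited", "C": "non-inherited"}
    with pytest.raises(ValueError, match="absent"):
        null_assortativity(net, [frozenset({"Z"})], observed)


def test_degree_features_handshake():
    net = net_from(
        [("A", "B", "positive"), ("A", "C", "positive"), ("A", "D", "negative")],
        nodes=["A", "B", "C", "D", "E"],
    )
    deg = degree_features(net)
    assert tuple(deg.loc["A"]) == (2, 1)
    assert tuple(deg.loc["E"]) == (0, 0)
    assert deg["positive_degree"].sum() == 2 * 2
    assert deg["negative_degree"].sum() == 2 * 1


def test_edgelist_round_trip(tmp_path):
    df = pd.DataFrame(
        {"node_a": ["A", "B"], "node_b": ["B", "C"], "sign": ["positive", "negative"],
         "weight": [0.5, -0.2]}
    )
    df.to_csv(tmp_path / "edges.tsv", sep="\t", index=False)
    net = read_edgelist(tmp_path / "edges.tsv")
    assert net.n_edges == 2
    assert net.graph.edges["A", "B"]["sign"] == "positive"
    assert net.graph.edges["B", "C"]["weight"] == pytest.approx(-0.2)


def test_exhaustive_small_graph_oracle_spot():
    """Quick mixing-matrix oracle agreement on 4-node graphs (the full
    exhaustive sweep lives in the acceptance tests)."""
    from itertools import combinations
    nodes = ["A", "B", "C", "D"]
    pairs = list(combinations(nodes, 2))
    labels = {"A": "i", "B": "i", "C": "n", "D": "n"}
    for k in range(1, len(pairs) + 1):
        for subset in combinations(pairs, k):
            net = net_from([(u, v, "positive") for u, v in subset], nodes=nodes)
            r = assortativity(net, labels)
            expected = mixing_matrix_assortativity(list(subset), labels)
            if expected is None:
                assert r is None
            else:
                assert r == pytest.approx(expected, abs=1e-12)
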