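import numpy as np
import pandas as pd
import pytest

from microherit import (
    RelAbundTable,
    attribute_parentage,
    classify_vertical,
    founder_to_offspring_retention,
    genus_overlap,
    pedigree_sharing,
    sample_inherited_summary,
)
from microherit.inheritance import InheritanceCall

from conftest import make_metadata, make_taxonomy


def presence_frame(rows, asvs, data):
    return pd.DataFrame(data, index=rows, columns=asvs, dtype=bool)


SAMPLES = ["PW", "F1", "F2", "O1", "O2"]


def classify_one(pattern, metadata):
    pres = presence_frame(SAMPLES, ["X"], [[bool(b)] for b in pattern])
    (call,) = classify_vertical(pres, metadata, "A", "maternal")
    return call


def test_rule_examples(one_pedigree_metadata):
    # present in workers, all founders, one offspring -> transmitted
    assert classify_one([1, 1, 1, 1, 0], one_pedigree_metadata).vertically_transmitted
    # one founder missing -> founder transmission fails
    call = classify_one([1, 1, 0, 1, 1], one_pedigree_metadata)
    assert not call.transmitted_to_founders and not call.vertically_transmitted
    # absent from parental workers -> not transmitted despite founders+offspring
    assert not classify_one([0, 1, 1, 1, 1], one_pedigree_metadata).vertically_transmitted


def test_empty_tier_raises_naming_tier(one_pedigree_metadata):
    pres = presence_frame(SAMPLES, ["X"], [[True]] * 5)
    with pytest.raises(ValueError, match="parental workers"):
        classify_vertical(pres, one_pedigree_metadata, "A", "paternal")
    with pytest.raises(ValueError, match="offspring"):
        classify_vertical(pres, make_metadata([
            ("PW", "B", "parental", "maternal", "worker"),
            ("F1", "B", "founder", "maternal", "alate"),
        ]), "B", "maternal")


def test_queen_samples_excluded_from_parental_presence_by_default():
    metadata = make_metadata([
        ("PW", "A", "parental", "maternal", "worker"),
        ("PQ", "A", "parental", "maternal", "queen"),
        ("F1", "A", "founder", "maternal", "alate"),
        ("O1", "A", "offspring", "na", "worker"),
    ])
    pres = presence_frame(["PW", "PQ", "F1", "O1"], ["X"], [[False], [True], [True], [True]])
    (call,) = classify_vertical(pres, metadata, "A", "maternal")
    assert not call.vertically_transmitted
    (call,) = classify_vertical(pres, metadata, "A", "maternal",
                                parental_castes=("worker", "queen"))
    assert call.vertically_transmitted


def _call(asv, ped, lineage, vt):
    return InheritanceCall(asv, ped, lineage, vt, vt, vt)


def test_attribute_parentage():
    maternal = [_call("X", "A", "maternal", True), _call("Y", "A", "maternal", False),
                _call("Z", "A", "maternal", True)]
    paternal = [_call("X", "A", "paternal", False), _call("Y", "A", "paternal", False),
                _call("Z", "A", "paternal", True)]
    status = {s.asv_id: s.status for s in attribute_parentage(maternal, paternal)}
    assert status == {"X": "maternal", "Y": "none", "Z": "shared"}
    with pytest.raises(ValueError, match="universe"):
        attribute_parentage(maternal[:2], paternal)


def test_sample_inherited_summary_arithmetic():
    asvs = [f"A{i}" for i in range(10)]
    pres = presence_frame(["S1", "S2"], asvs, [[True] * 10, [False] * 10])
    rel = RelAbundTable(
        pd.DataFrame([[0.1] * 6 + [0.4 / 4] * 4, [0.0] * 10], index=["S1", "S2"],
                     columns=asvs),
        zero_total_samples=frozenset({"S2"}),
    )
    calls = [_call(a, "A", "maternal", i < 6) for i, a in enumerate(asvs)]
    out = sample_inherited_summary(rel, pres, calls)
    assert out.loc["S1", "inherited_relabund_fraction"] == pytest.approx(0.6)
    assert out.loc["S1", "inherited_asv_fraction"] == pytest.approx(0.6)
    # empty sample flagged undefined
    assert not out.loc["S2", "defined"]
    assert np.isnan(out.loc["S2", "inherited_relabund_fraction"])
    # no inherited ASVs present -> zero fractions, still defined
    none_calls = [_call(a, "A", "maternal", False) for a in asvs]
    out2 = sample_inherited_summary(rel, pres, none_calls)
    assert out2.loc["S1", "inherited_relabund_fraction"] == 0.0


def test_pedigree_sharing_partition_conserves_union():
    peds = ["A", "B", "C", "D"]
    rng = np.random.default_rng(5)
    calls_by = {
        p: [_call(f"X{i}", p, "maternal", bool(rng.random() < 0.4)) for i in range(40)]
        for p in peds
    }
    partition = pedigree_sharing(calls_by)
    union = {
        c.asv_id for calls in calls_by.values() for c in calls if c.vertically_transmitted
    }
    assert sum(partition.values()) == len(union)
    # an ASV transmitted everywhere lands in the ubiquitous cell
    calls_by2 = {p: [_call("U", p, "maternal", True)] for p in peds}
    assert pedigree_sharing(calls_by2) == {("A", "B", "C", "D"): 1}


def test_genus_overlap_pairwise():
    taxonomy = make_taxonomy({"X1": "a", "X2": "b", "Y1": "b", "Y2": "c", "Z1": "d"})
    calls_by = {
        "P": [_call("X1", "P", "maternal", True), _call("X2", "P", "maternal", True)],
        "Q": [_call("Y1", "Q", "maternal", True), _call("Y2", "Q", "maternal", True)],
        "R": [_call("Z1", "R", "maternal", True)],
    }
    mat = genus_overlap(calls_by, taxonomy)
    # G_P={a,b}, G_Q={b,c}: |intersection|=1, mean size 2 -> 1/2
    assert mat.loc["P", "Q"] == pytest.approx(0.5)
    assert mat.loc["Q", "P"] == pytest.approx(0.5)
    assert mat.loc["P", "P"] == 1.0
    assert mat.loc["P", "R"] == 0.0  # disjoint genera
    # pedigree with no inherited genus -> undefined cells
    calls_by["S"] = [_call("X1", "S", "maternal", False)]
    mat2 = genus_overlap(calls_by, taxonomy)
    assert np.isnan(mat2.loc["S", "P"]) and np.isnan(mat2.loc["S", "S"])


def test_founder_to_offspring_retention():
    calls = [
        InheritanceCall(f"A{i}", "P", "maternal", True, True, i < 8) for i in range(10)
    ]
    out = founder_to_offspring_retention(calls)
    assert out["P"] == pytest.approx(0.8)
    assert out["pooled"] == pytest.approx(0.8)
    # all retained -> 1.0; retention never exceeds 1 by the subset property
    full = [InheritanceCall("B", "Q", "maternal", True, True, True)]
    assert founder_to_offspring_retention(full)["Q"] == 1.0
    empty = [InheritanceCall("C", "R", "maternal", False, False, False)]
    assert np.isnan(founder_to_offspring_retention(empty)["R"])


def test_presence_monotonicity_never_loses_calls(one_pedigree_metadata):
    """Adding reads (flipping presence False->True) never un-transmits an ASV."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        base = rng.random((5, 12)) < 0.5
        more = base | (rng.random((5, 12)) < 0.3)
        asvs = [f"A{j}" for j in range(12)]
        calls_lo = classify_vertical(
            presence_frame(SAMPLES, asvs, base), one_pedigree_metadata, "A", "maternal")
        calls_hi = classify_vertical(
            presence_frame(SAMPLES, asvs, more), one_pedigree_metadata, "A", "maternal")
        lo = {c.asv_id for c in calls_lo if c.vertically_transmitted}
        hi = {c.asv_id for c in calls_hi if c.vertically_transmitted}
        assert lo <= hi
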