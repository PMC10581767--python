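import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microherit import (
    SampleMetadata,
    SimParams,
    TaxonomyTable,
    generate_pedigree_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_metadata(rows):
    """rows: list of (sample_id, pedigree, generation, parental_role, caste)."""
    df = pd.DataFrame(
        [
            {
                "sample_id": s,
                "pedigree": ped,
                "generation": gen,
                "parental_role": role,
                "caste": caste,
                "colony_id": f"col_{ped or 'pat'}",
                "guts_pooled": 5,
            }
            for s, ped, gen, role, caste in rows
        ]
    ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture
def one_pedigree_metadata():
    """1 maternal parental worker, 2 maternal founders, 2 offspring samples."""
    return make_metadata(
        [
            ("PW", "A", "parental", "maternal", "worker"),
            ("F1", "A", "founder", "maternal", "alate"),
            ("F2", "A", "founder", "maternal", "alate"),
            ("O1", "A", "offspring", "na", "worker"),
            ("O2", "A", "offspring", "na", "worker"),
        ]
    )


def make_taxonomy(genus_of, family_of=None):
    """TaxonomyTable from a {asv: genus-or-None} mapping."""
    rows = {}
    for asv, genus in genus_of.items():
        fam = (family_of or {}).get(asv, "famX")
        rows[asv] = {
            "phylum": "phyA",
            "class": "clsA",
            "order": "ordA",
            "family": fam,
            "genus": genus,
        }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture(scope="session")
def default_dataset():
    """The shipped-default synthetic pedigree dataset (fixed seed)."""
    return generate_pedigree_dataset(SimParams())


@pytest.fixture(scope="session")
def small_params():
    """Reduced-size generator settings for fast pipeline tests."""
    return SimParams(n_pedigrees=2, n_genera=20, env_pool_size=40, depth=20_000, seed=7)


@pytest.fixture
def tiny_tsv_dir(tmp_path):
    """Consistent 3-sample x 4-ASV TSV trio on disk."""
    counts = pd.DataFrame(
        [[5, 0, 2, 1], [0, 3, 0, 7], [1, 1, 1, 1]],
        index=["S1", "S2", "S3"],
        columns=["A1", "A2", "A3", "A4"],
    )
    counts.rename_axis("sample_id").to_csv(tmp_path / "counts.tsv", sep="\t")
    tax = pd.DataFrame(
        {
            "phylum": ["p1"] * 4,
            "class": ["c1"] * 4,
            "order": ["o1"] * 4,
            "family": ["f1", "f1", "f2", "f2"],
            "genus": ["g1", "g1", None, "g2"],
        },
        index=["A1", "A2", "A3", "A4"],
    )
    tax.rename_axis("asv_id").to_csv(tmp_path / "taxonomy.tsv", sep="\t")
    meta = pd.DataFrame(
        {
            "pedigree": ["A", "A", "A"],
            "generation": ["parental", "founder", "offspring"],
            "parental_role": ["maternal", "maternal", "na"],
            "caste": ["worker", "alate", "worker"],
            "colony_id": ["c1", "c1", "c2"],
            "guts_pooled": [5, 6, 10],
        },
        index=["S1", "S2", "S3"],
    )
    meta.rename_axis("sample_id").to_csv(tmp_path / "metadata.tsv", sep="\t")
    return tmp_path
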