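import numpy as np
import pytest

from viromass.taxonomy import TaxonomyTree, build_taxonomy, default_taxonomy


@pytest.fixture(scope="session")
def registry() -> TaxonomyTree:
    return default_taxonomy()


@pytest.fixture
def tiny_tree() -> TaxonomyTree:
    """root -> Viruses -> {ssDNA viruses -> {FamA, FamB -> GenB}, dsDNA viruses -> FamC}"""
    return build_taxonomy(
        [
            {"name": "root", "rank": "root", "parent": ""},
            {"name": "Viruses", "rank": "superkingdom", "parent": "root"},
            {"name": "ssDNA viruses", "rank": "other", "parent": "Viruses",
             "na_type": "ssDNA", "genome_min_kb": 1.8, "genome_max_kb": 24.9},
            {"name": "dsDNA viruses", "rank": "other", "parent": "Viruses",
             "na_type": "dsDNA"},
            {"name": "FamA", "rank": "family", "parent": "ssDNA viruses",
             "na_type": "ssDNA", "genome_min_kb": 1.8, "genome_max_kb": 2.1},
            {"name": "FamB", "rank": "family", "parent": "ssDNA viruses",
             "na_type": "ssDNA", "genome_min_kb": 4.4, "genome_max_kb": 6.1},
            {"name": "GenB", "rank": "genus", "parent": "FamB"},
            {"name": "FamC", "rank": "family", "parent": "dsDNA viruses",
             "na_type": "dsDNA", "genome_min_kb": 50, "genome_max_kb": 50},
        ]
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree with occasional na_type/genome annotations."""
    ranks = ["superkingdom", "order", "family", "genus", "species", "other"]
    records = [{"name": "n0", "rank": "root", "parent": ""}]
    for i in range(1, n_nodes):
        rec = {
            "name": f"n{i}",
            "rank": ranks[rng.integers(0, len(ranks))],
            "parent": f"n{rng.integers(0, i)}",
        }
        if rng.random() < 0.3:
            rec["na_type"] = "ssDNA" if rng.random() < 0.5 else "dsDNA"
        if rng.random() < 0.3:
            lo = float(rng.uniform(1, 50))
            rec["genome_min_kb"] = lo
            rec["genome_max_kb"] = lo + float(rng.uniform(0, 100))
        records.append(rec)
    return build_taxonomy(records)
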