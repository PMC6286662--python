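import numpy as np
import pandas as pd
import pytest

from ednabench.filtering import CountMatrix
from ednabench.taxonomy import AssignmentParams, TaxonomyDB


@pytest.fixture(scope="session")
def fish_db() -> TaxonomyDB:
    """Small fish taxonomy: root -> Chordata -> Actinopterygii ->
    {Salmonidae -> {Salmo -> S. salar, Coregonus -> C. artedi},
     Cyprinidae -> Chrosomus}."""
    nodes = {
        1: (1, "root", "root"),
        2: (1, "phylum", "Chordata"),
        3: (2, "class", "Actinopterygii"),
        4: (3, "family", "Salmonidae"),
        5: (4, "genus", "Salmo"),
        6: (5, "species", "Salmo salar"),
        7: (4, "genus", "Coregonus"),
        8: (7, "species", "Coregonus artedi"),
        9: (3, "family", "Cyprinidae"),
        10: (9, "genus", "Chrosomus"),
    }
    return TaxonomyDB(nodes)


@pytest.fixture(scope="session")
def coi_params() -> AssignmentParams:
    """The COI / eukaryotic-16S preset: floor 250, 5% window, 95/90 identity."""
    return AssignmentParams(
        min_bitscore=250.0, lca_window=0.05,
        species_min_identity=95.0, genus_min_identity=90.0,
    )


def make_matrix(counts: dict, meta: dict | None = None,
                taxon_meta: dict | None = None) -> CountMatrix:
    """Build a CountMatrix from plain dicts (column -> values)."""
    cdf = pd.DataFrame(counts)
    mdf = pd.DataFrame(meta, index=cdf.index) if meta is not None else None
    tdf = pd.DataFrame(taxon_meta, index=cdf.columns) if taxon_meta is not None else None
    return CountMatrix(cdf, mdf, tdf)


@pytest.fixture
def study_matrix_small():
    """A small simulated study (fewer bacteria) for pipeline-level tests."""
    from ednabench.simulate import default_study_scenario, simulate_counts

    scenario = default_study_scenario(seed=7, n_bacteria=30)
    matrix, truth = simulate_counts(scenario)
    return matrix, truth
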