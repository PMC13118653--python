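import math

import numpy as np
import pytest

from rivasm.simulate import SimConfig, preset, simulate_survey
from rivasm.tables import CommunityTable
from rivasm.trees import tree_from_newick

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return tree_from_newick(TOY_NEWICK)


@pytest.fixture
def toy_table():
    counts = np.array([[5, 0], [1, 2], [0, 7]])
    return CommunityTable(counts, ["A", "B", "C"], ["s1", "s2"])


def small_survey_config(seed: int = 1, **overrides) -> SimConfig:
    """A scaled-down two-season survey used across tests: 10 reaches x 2
    seasons x 2 replicates, 600 taxa, ~1.5k reads per sample."""
    base = dict(
        n_taxa=600,
        n_replicates=2,
        pool_sdlog=1.5,
        lib_meanlog=math.log(1500.0),
        lib_min=800,
        seed=seed,
    )
    base.update(overrides)
    return preset("study", **base)


@pytest.fixture(scope="session")
def survey():
    return simulate_survey(small_survey_config(seed=1))
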