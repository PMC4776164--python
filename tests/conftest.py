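import numpy as np
import pytest

from rivst import OtuTable, SampleDesign, SpatialPartition, SyntheticConfig
from rivst.synthetic_data import generate_community


SURVEY_GROUPS = {1: "riverine", 2: "riverine", 3: "estuarial"}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def survey_partition():
    """Riverine (units 1-2) vs estuarial (unit 3), as in a 3-section river."""
    return SpatialPartition(dict(SURVEY_GROUPS))


def survey_config(**overrides):
    """4 seasons x 3 sites, riverine/estuarial split."""
    kwargs = dict(
        n_taxa=300,
        n_sites=3,
        spatial_groups=dict(SURVEY_GROUPS),
        seed=0,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 3, 1, 0],
            [2, 2, 2, 2, 2],
            [0, 9, 1, 0, 4],
            [1, 1, 0, 6, 0],
        ]
    )
    return OtuTable(
        taxon_ids=[f"t{k}" for k in range(4)],
        sample_ids=[f"s{j}" for j in range(5)],
        counts=counts,
    )


@pytest.fixture
def grid_design():
    """Complete 4 seasons x 3 sites design with riverine/estuarial labels."""
    rows = []
    for i in range(1, 5):
        for j in range(1, 4):
            rows.append(
                SampleDesign(
                    sample_id=f"S{j}_T{i}",
                    season=i,
                    site=j,
                    spatial_group=SURVEY_GROUPS[j],
                )
            )
    return rows
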