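import numpy as np
import pandas as pd
import pytest

from azairway import (
    CohortConfig,
    FeatureTable,
    SampleMetadata,
    read_tree,
    simulate_cohort,
)


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); — the three-leaf workhorse."""
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return read_tree("(t1:1,t2:1,t3:1,t4:1);")


@pytest.fixture
def toy_table():
    return FeatureTable(
        pd.DataFrame(
            [[3, 0, 2], [1, 5, 0]],
            index=["S1", "S2"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def toy_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "patient_id": ["P1", "P1"],
                "site": ["LRT", "URT"],
                "phase": ["StartAZT", "StartAZT"],
                "time_months": [0.0, 0.0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but fully structured cohort reused across test modules."""
    cfg = CohortConfig(
        n_patients=8,
        n_asvs=80,
        n_genera=12,
        rarefaction_depth=2000,
        raw_depth_range=(2500, 4000),
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions."""
    return simulate_cohort(CohortConfig(seed=7))


def presence_sets(table, sample_a, sample_b):
    row_a = table.data.loc[sample_a]
    row_b = table.data.loc[sample_b]
    return set(row_a.index[row_a > 0]), set(row_b.index[row_b > 0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
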