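import numpy as np
import pandas as pd
import pytest

from levnet import synthetic as syn
from levnet.regions import DEFAULT_REGIONS, REFERENCE_REGION


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_suvr_cohort():
    """One-arm SUVr cohort with three planted blocks, 12 animals."""
    spec = syn.CohortSpec(n_per_group=12, sexes=("male",),
                          treatments=("vehicle",), seed=11)
    return syn.generate_suvr_cohort(spec)


@pytest.fixture(scope="session")
def planted_partition_arrays():
    """Region order + planted block labels used by the default specs."""
    part = syn.default_planted_partition(DEFAULT_REGIONS, 3)
    labels = np.array([part[r] for r in DEFAULT_REGIONS])
    return list(DEFAULT_REGIONS), labels


def make_random_cohort_table(rng, n_animals=8, regions=("r1", "r2", "r3", "r4")):
    """Unstructured cohort table for elementwise oracles."""
    data = {"animal_id": [f"X{i}" for i in range(n_animals)],
            "sex": ["male"] * n_animals, "genotype": ["WT"] * n_animals,
            "treatment": ["none"] * n_animals}
    for r in regions:
        data[r] = rng.uniform(0.5, 2.0, size=n_animals)
    data[REFERENCE_REGION] = rng.uniform(0.8, 1.2, size=n_animals)
    return pd.DataFrame(data)
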