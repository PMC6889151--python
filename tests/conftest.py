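import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import grskit as gk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundled_weights():
    return gk.glioma_discovery_weights()


@pytest.fixture(scope="session")
def default_distribution():
    """Exact genotype distribution under the default generating conditions."""
    return gk.exact_distribution(gk.SimulationSpec(seed=0))


@pytest.fixture()
def small_cohort(bundled_weights):
    """Hand-built 4-sample cohort over the five bundled SNPs."""
    dosage = np.array(
        [
            [2, 2, 2, 2, 2],
            [0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
            [1, 1, 1, 1, 1],
        ],
        dtype=float,
    )
    pheno = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "status": [1, 0, 0, 1],
            "sex": pd.Categorical(
                ["male", "female", "male", "female"], categories=["male", "female"]
            ),
            "age_group": pd.Categorical(
                ["7-9", "10-14", "15-19", "10-14"],
                categories=["7-9", "10-14", "15-19"],
            ),
            "country": pd.Categorical(
                ["SE", "NO", "DK", "CH"], categories=["SE", "NO", "DK", "CH"]
            ),
        }
    )
    return gk.CohortData(
        sample_ids=["s1", "s2", "s3", "s4"],
        dosage_matrix=dosage,
        weights=bundled_weights,
        phenotypes=pheno,
    )


@pytest.fixture(scope="session")
def simulated_cohort(default_distribution):
    """One default-conditions cohort (245 cases / 489 controls)."""
    cohort, truth = gk.sample_cohort(
        gk.SimulationSpec(seed=11), default_distribution
    )
    return cohort, truth
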