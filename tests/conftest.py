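import numpy as np
import pytest

from phenosom.cohort import CohortGenConfig, CohortMatrix, generate_cohort
from phenosom.som import SOMConfig, train_som


@pytest.fixture(scope="session")
def default_cohort():
    """Full synthetic cohort at the published sizes/means, sd 0.5."""
    return generate_cohort(CohortGenConfig(seed=7))


@pytest.fixture(scope="session")
def cognitive_matrix(default_cohort):
    cohort, _ = default_cohort
    cols = cohort.family_columns("cognitive")
    return CohortMatrix(cohort.scores[cols], {c: "cognitive" for c in cols})


@pytest.fixture(scope="session")
def trained_som(cognitive_matrix):
    return train_som(cognitive_matrix, SOMConfig(seed=11))


def small_cohort_config(seed=0, sd=0.5, scale=0.25):
    """Quarter-size cohort for the heavier Monte-Carlo checks."""
    sizes = [max(8, int(n * scale)) for n in [146, 121, 132, 131]]
    return CohortGenConfig(cluster_sizes=sizes, within_cluster_sd=sd,
                           seed=seed)
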