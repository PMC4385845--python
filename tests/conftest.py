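import numpy as np
import pandas as pd
import pytest

from dysmark.matrix import FeatureMatrix, Pair, PairedCohort
from dysmark.synthetic import CohortConfig, generate_cohort


def make_paired_matrix(tumor_values, normal_values, feature_id="GENE"):
    """Tiny FeatureMatrix + cohort from aligned tumor/normal value lists."""
    n = len(tumor_values)
    pids = [f"P{i}" for i in range(n)]
    tids = [f"P{i}-T" for i in range(n)]
    nids = [f"P{i}-N" for i in range(n)]
    values = pd.DataFrame(
        [list(tumor_values) + list(normal_values)],
        index=[feature_id],
        columns=tids + nids,
    )
    meta = pd.DataFrame(
        {
            "patient_id": pids + pids,
            "tissue": ["tumor"] * n + ["normal"] * n,
            "stage": ["I"] * 2 * n,
            "metastasis": ["no"] * 2 * n,
        },
        index=tids + nids,
    )
    cohort = PairedCohort([Pair(p, t, m) for p, t, m in zip(pids, tids, nids)])
    return FeatureMatrix(values=values, sample_meta=meta), cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
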