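import numpy as np
import pandas as pd
import pytest

from bulkqc.metrics import derive_metrics_frame
from bulkqc.synthetic import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A 100-sample cohort with 10 injected defects (2 per archetype)."""
    spec = default_cohort_spec(n_samples=100, defect_fraction=0.10, seed=7,
                               n_genes=2000)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    return derive_metrics_frame(cohort.qc, cohort.counts, cohort.gbc)


@pytest.fixture(scope="session")
def truth_labels(cohort):
    return cohort.truth["is_defect"].map({True: "low", False: "high"})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_flag_table(rng):
    mat = rng.choice([0.0, 0.5, 1.0], size=(20, 10))
    return pd.DataFrame(
        mat,
        index=[f"S{i:02d}" for i in range(20)],
        columns=[f"metric_{j}" for j in range(10)],
    ).rename_axis("sample_id")
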