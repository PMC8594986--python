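import numpy as np
import pytest

import biozscreen as bz
from biozscreen.features import attribute_columns


@pytest.fixture(scope="session")
def default_cohort():
    """The study-mirroring cohort: 53 subjects, 256 samples, no label noise."""
    table, truth = bz.generate_cohort(bz.CohortSpec(rng_seed=7))
    return table, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default cohort with 15% of subjects' recorded labels flipped."""
    table, truth = bz.generate_cohort(bz.CohortSpec(rng_seed=7, label_noise=0.15))
    return table, truth


@pytest.fixture(scope="session")
def cohort_arrays(default_cohort):
    table, _ = default_cohort
    cols = attribute_columns(table)
    return (
        table[cols].to_numpy(dtype=float),
        table["label"].to_numpy(dtype=int),
        list(table["subject_id"]),
        cols,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
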