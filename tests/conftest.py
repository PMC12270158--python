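from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methbin import synthetic_data
from methbin.io_formats import validate_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return synthetic_data.SimulationConfig(seed=7, n_cpgs=1500, n_chromosomes=2)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return synthetic_data.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_genome):
    return synthetic_data.generate_cohort(small_config, small_genome)


@pytest.fixture
def toy_metadata():
    """8 samples, one per base group x 2 stages."""
    rows = []
    i = 0
    for sex in ("male", "female"):
        for st in ("tissue", "cfDNA"):
            for stage in (1, 3):
                i += 1
                rows.append((f"X{i:02d}", f"SUBJ{i:02d}", sex, st, stage))
    return validate_metadata(
        pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "sex", "sample_type", "fibrosis_stage"]
        )
    )
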