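import numpy as np
import pandas as pd
import pytest

from cupcompass import SyntheticConfig
from cupcompass.io_formats import ExpressionProfile


@pytest.fixture
def small_config():
    """Small, fast cohort: 4 entities, clean separation structure."""
    return SyntheticConfig(
        seed=11,
        n_entities=4,
        samples_per_entity=5,
        queries_per_entity=2,
        n_genes=300,
        markers_per_entity=15,
        n_liver_genes=10,
        noise_cv=0.2,
        n_probes=500,
        cpgs_per_entity=25,
    )


@pytest.fixture
def zero_noise_config(small_config):
    import dataclasses

    return dataclasses.replace(small_config, noise_cv=0.0)


def make_profile(sample_id, values, genes=None, **kw):
    genes = genes or [f"g{i}" for i in range(1, len(values) + 1)]
    return ExpressionProfile(sample_id, pd.Series(values, index=genes, dtype=float), **kw)


@pytest.fixture
def profile_factory():
    return make_profile
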