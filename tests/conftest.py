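import numpy as np
import pandas as pd
import pytest

from metord.simulate import FixtureSpec, generate
from metord.tables import FeatureTable, SampleMetadata


def make_table(rng, n_samples, n_features, sparsity=0.0, prefix=""):
    """Random non-negative feature table (lognormal intensities)."""
    values = rng.lognormal(mean=5.0, sigma=1.0, size=(n_samples, n_features))
    if sparsity:
        values[rng.random(values.shape) < sparsity] = 0.0
    return FeatureTable(
        pd.DataFrame(
            values,
            index=[f"{prefix}s{i}" for i in range(n_samples)],
            columns=[f"{prefix}f{j}" for j in range(n_features)],
        )
    )


def make_metadata(sample_ids, **columns):
    return SampleMetadata(pd.DataFrame(columns, index=list(sample_ids)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_fixture():
    """One default synthetic study, shared across read-only tests."""
    return generate(FixtureSpec(seed=11))


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def metadata_factory():
    return make_metadata
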