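import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample_table(counts, dates, plant="P1", replicate_of=None, sample_ids=None):
    """Small SampleTable builder for unit tests."""
    from seasonflow.tables import SampleTable

    counts = np.atleast_2d(np.asarray(counts))
    n = counts.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    idx = pd.Index(sample_ids, name="sample_id")
    cdf = pd.DataFrame(
        counts, index=idx, columns=[f"t{j + 1}" for j in range(counts.shape[1])]
    )
    meta = pd.DataFrame(
        {
            "plant": plant if isinstance(plant, list) else [plant] * n,
            "date": pd.to_datetime(dates),
            "replicate_of": replicate_of if replicate_of is not None else [np.nan] * n,
        },
        index=idx,
    )
    return SampleTable(counts=cdf, meta=meta)


@pytest.fixture
def sample_table_builder():
    return make_sample_table
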