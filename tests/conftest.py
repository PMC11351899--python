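import numpy as np
import pytest

from eegimpute.tabular import TabularDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, n_rows=20, n_cols=5, missing_rate=0.0, prefix="f"):
    """Random numeric table with optional MCAR holes (at least one observed
    value per column)."""
    values = rng.normal(size=(n_rows, n_cols))
    if missing_rate > 0:
        mask = rng.random((n_rows, n_cols)) < missing_rate
        for j in range(n_cols):  # keep every column partially observed
            if mask[:, j].all():
                mask[rng.integers(n_rows), j] = False
        values = values.copy()
        values[mask] = np.nan
    return TabularDataset(values, [f"{prefix}{j}" for j in range(n_cols)],
                          np.arange(n_rows))


@pytest.fixture
def random_table_factory(rng):
    def make(**kwargs):
        return random_table(rng, **kwargs)
    return make
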