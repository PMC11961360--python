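import numpy as np
import pytest
from hypothesis import settings

from morqsar.preprocessing import DescriptorTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, ids=None, names=None, labels=None) -> DescriptorTable:
    """Build a DescriptorTable from a plain matrix with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return DescriptorTable(
        ids or [f"c{i}" for i in range(n)],
        names or [f"x{j}" for j in range(d)],
        values,
        labels,
    )


def separable_table(n_per_class=60, n_desc=10, gap=4.0, seed=0) -> DescriptorTable:
    """Linearly separable two-class table (binders shifted by *gap*)."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, n_desc))
    X1 = rng.normal(gap, 1.0, size=(n_per_class, n_desc))
    labels = np.array(["nonbinder"] * n_per_class + ["binder"] * n_per_class, dtype=object)
    return make_table(np.vstack([X0, X1]), labels=labels)
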