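import numpy as np
import pandas as pd
import pytest

import lymphocoda as lc


@pytest.fixture(scope="session")
def tree():
    return lc.default_tree()


@pytest.fixture(scope="session")
def small_cohort():
    """500-subject default cohort, shared across read-only tests."""
    return lc.generate_cohort(500, seed=42)


@pytest.fixture(scope="session")
def small_composition(small_cohort):
    """Zero-replaced composition derived through the percentage front door."""
    kept, _ = lc.validate_subjects(small_cohort.panel)
    comp = lc.to_composition(lc.derive_other(kept))
    return lc.replace_zeros(comp)


def random_composition(n, d, seed, names=None):
    """Generic-position compositions for small-D algebra tests."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=1.0, size=(n, d))
    x /= x.sum(axis=1, keepdims=True)
    cols = names or [f"P{i}" for i in range(d)]
    return lc.CompositionMatrix(proportions=pd.DataFrame(x, columns=cols))
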