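import numpy as np
import pandas as pd
import pytest

from coralfront import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paper_like_run():
    """One paper-like simulation shared by read-only tests."""
    design, params = synth.get_preset("paper-like", seed=7)
    counts, metadata, truth = synth.simulate_counts(design, params)
    return {"counts": counts, "metadata": metadata, "truth": truth,
            "design": design, "params": params}


@pytest.fixture
def small_counts():
    """Tiny hand-checkable count matrix (3 genes x 2 samples)."""
    return pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                        index=["g1", "g2", "g3"])
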