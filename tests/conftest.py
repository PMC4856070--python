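import numpy as np
import pandas as pd
import pytest

from bmnb import CountPanel


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def balanced_panel(I, J, K, n, counts=None, seed=0):
    """Small balanced panel; counts default to a seeded Poisson(3)."""
    rng = make_rng(seed)
    rows = {"env": [], "block": [], "line": [], "rep": [], "count": []}
    for i in range(I):
        for j in range(J):
            for k in range(K):
                for t in range(n):
                    rows["env"].append(f"E{i + 1}")
                    rows["line"].append(f"L{j + 1:03d}")
                    rows["block"].append(f"B{k + 1}")
                    rows["rep"].append(t + 1)
                    if counts is None:
                        rows["count"].append(int(rng.poisson(3)))
                    else:
                        rows["count"].append(int(counts.pop(0)))
    return CountPanel.from_frame(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return make_rng(1234)
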