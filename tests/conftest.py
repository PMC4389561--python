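import numpy as np
import pandas as pd
import pytest

from geoshift.simulate import (ExtinctReplicateError, SimConfig,
                               simulate_musse_tree)
from geoshift.trees import Chronogram


def simulate_surviving(n_states, lam, mu, q, seed, require_both_states=False,
                       **kwargs):
    """Simulate, retrying consecutive seeds past extinct replicates."""
    while True:
        try:
            cfg = SimConfig(n_states, lam, mu, q, seed=seed, **kwargs)
            tree, hist, states = simulate_musse_tree(cfg)
            if not require_both_states or states.nunique() >= 2:
                return tree, hist, states, seed
        except ExtinctReplicateError:
            pass
        seed += 1


@pytest.fixture(scope="session")
def quartet():
    """Balanced 4-tip tree with cherries (A,B) and (C,D)."""
    return Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def quartet_states():
    return pd.Series({"A": "x", "B": "x", "C": "y", "D": "y"})


@pytest.fixture(scope="session")
def tree100():
    """Fixed 100-tip two-state tree with its true history."""
    tree, hist, states, _ = simulate_surviving(
        2, [0.15, 0.15], 0.0, [[0, 0.04], [0.06, 0]], seed=17,
        max_taxa=100, require_both_states=True)
    return tree, hist, states


@pytest.fixture(scope="session")
def yule10():
    """Fixed 10-tip pure-birth tree (single state)."""
    tree, hist, states, _ = simulate_surviving(
        1, 0.15, 0.0, np.zeros((1, 1)), seed=7, max_taxa=10)
    return tree, states
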