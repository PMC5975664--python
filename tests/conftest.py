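import numpy as np
import pytest

from branchgp.model import GlobalBranching


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_branching():
    """A small hand-built global branching structure (N = 12)."""
    t = np.linspace(0.02, 0.98, 12)
    labels = np.where(t < 0.3, "trunk", np.where(np.arange(12) % 2 == 0, "1", "2"))
    return GlobalBranching(t, labels, 0.3, source="truth")


def random_instance(rng, n=10, branch_frac=0.6):
    """Random pseudotimes, labels and expression for property tests."""
    t = np.sort(rng.uniform(0, 1, n))
    gtime = float(np.quantile(t, 1 - branch_frac))
    labels = np.where(t < gtime, "trunk", rng.choice(["1", "2"], n))
    gb = GlobalBranching(t, labels, gtime, source="truth")
    y = rng.normal(size=n)
    return y, gb
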