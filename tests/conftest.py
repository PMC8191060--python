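import numpy as np
import pytest

from matchset import CountTable, MatchedDesign, Submodel


@pytest.fixture
def five_sample_sets():
    """Two sets of sizes 2 and 3: the canonical small matched design."""
    return np.array(["a", "a", "b", "b", "b"])


@pytest.fixture
def pair_design():
    """Four samples in two pairs with a binary trait alternating within pairs."""
    return MatchedDesign(
        sample_ids=["s1", "s2", "s3", "s4"],
        set_ids=np.array([1, 1, 2, 2]),
        submodels=[Submodel("trait", np.array([1.0, 0.0, 1.0, 0.0]))],
    )


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(8, 20))
    counts[:, 0] += 1  # keep every sample total positive
    return CountTable(
        counts,
        [f"s{i}" for i in range(8)],
        [f"otu{j}" for j in range(20)],
    )


def random_table(rng, n=8, J=20, depth=200):
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(J)), size=n)
    return CountTable(counts, [f"s{i}" for i in range(n)], [f"otu{j}" for j in range(J)])
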