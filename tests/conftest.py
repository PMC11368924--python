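import numpy as np
import pytest

from paretogen import ParetoPool, StateContext, ToyMDP, toy_objectives, uniform_policy

#: short but valid amino-acid sequence used wherever a protein is needed
PROTEIN = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"


@pytest.fixture
def toy_mdp() -> ToyMDP:
    return ToyMDP(vocabulary=("A", "B", "$"), max_len=3,
                  objectives=toy_objectives(["countA", "countB"]))


@pytest.fixture
def toy_policy(toy_mdp):
    return uniform_policy(toy_mdp)


@pytest.fixture
def context() -> StateContext:
    return StateContext(PROTEIN)


@pytest.fixture
def empty_pool() -> ParetoPool:
    return ParetoPool(dim=2)


def make_pool(hs, dim=None) -> ParetoPool:
    """Pool prefilled with metric vectors (tokens auto-named)."""
    from paretogen import MoleculeRecord

    hs = [np.asarray(h, float) for h in hs]
    pool = ParetoPool(dim=dim or len(hs[0]))
    for i, h in enumerate(hs):
        r = pool.reward_vector(h)
        pool.update(MoleculeRecord(f"mol{i}$", h, r, iteration=i))
    return pool
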