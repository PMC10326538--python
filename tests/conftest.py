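import numpy as np
import pytest

from imcoal import (
    GeneTree,
    IMParams,
    SimulationConfig,
    sample_blocks,
    simulate_loci,
)


def two_tip_tree(t, pops=(1, 2)):
    """A 2-tip tree with coalescence at time t."""
    labels = [f"P{p}_{i + 1}" for i, p in enumerate(pops)]
    return GeneTree.from_events(labels, pops, [(t, 0, 1)])


def four_tip_tree(t1=1.0, t2=2.0, t3=3.0):
    """Balanced 4-tip tree: pop-1 cherry at t1, pop-2 cherry at t2, root at t3."""
    return GeneTree.from_events(
        ["P1_1", "P1_2", "P2_1", "P2_2"],
        [1, 1, 2, 2],
        [(t1, 0, 1), (t2, 2, 3), (t3, 4, 5)],
    )


@pytest.fixture(scope="session")
def mig_params():
    return IMParams(10, 10, 10, 0.1, 0.0, 10)


@pytest.fixture(scope="session")
def mig_trees(mig_params):
    """Block trees of 200 non-recombining loci under unidirectional migration."""
    loci = simulate_loci(SimulationConfig(params=mig_params, rho=0.0), 200, seed=321)
    return sample_blocks(loci, seed=322)
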