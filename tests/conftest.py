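import numpy as np
import pytest

import mitocomp as mc


@pytest.fixture(scope="session")
def code5():
    return mc.get_code(5)


@pytest.fixture(scope="session")
def sim_genome():
    """One complete synthetic mitogenome (default study conditions)."""
    return mc.simulate_mitogenome(mc.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_alignment():
    """Small codon alignment with a marked foreground branch."""
    cfg = mc.SimulationConfig(seed=7, n_codons=120)
    aln, tree, classes = mc.simulate_codon_alignment(cfg)
    return aln, tree, classes


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
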