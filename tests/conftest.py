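import pytest

from circuitchain import GeneratorSpec, random_chains


@pytest.fixture(scope="session")
def random_chain_pool():
    """A reproducible mixed pool of random chains for round-trip properties."""
    pool = []
    pool += random_chains(GeneratorSpec(n_hard=3, n_soft=0, seed=11), 40)
    pool += random_chains(GeneratorSpec(n_hard=2, n_soft=2, seed=12), 40)
    pool += random_chains(GeneratorSpec(n_hard=3, n_soft=1, n_threads=2, seed=13), 40)
    pool += random_chains(GeneratorSpec(n_hard=0, n_soft=4, n_threads=1, seed=14), 40)
    return pool


YIBK = "(AB) C (BDE) (EF) (FDG) S^{+e} (HI) (IGA) H S C"


@pytest.fixture(scope="session")
def yibk_chain():
    """The methyltransferase worked example: 9 hard contacts in concerted
    groups plus one +e soft contact (a trefoil-forming entanglement)."""
    from circuitchain import parse_chain

    return parse_chain(YIBK)
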