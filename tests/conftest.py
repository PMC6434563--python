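import numpy as np
import pytest
from hypothesis import settings

from fishweb import trophic, webgen
from fishweb.lifehistory import insert_stages

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def web_from_adjacency(A, C_target=None, n=None):
    """Hand-built web around an explicit adjacency (niche triples are
    placeholders unless given)."""
    A = np.asarray(A, dtype=bool)
    S = A.shape[0]
    if n is None:
        n = np.linspace(0.1, 0.9, S)
    if C_target is None:
        C_target = A.sum() / S**2
    return webgen.NicheWeb(
        S=S, C_target=float(C_target), n=np.asarray(n, float),
        r=np.zeros(S), c=np.zeros(S), A=A,
    )


def chain_web(S):
    """Food chain 0 <- 1 <- ... <- S-1 (node 0 basal)."""
    A = np.zeros((S, S), dtype=bool)
    for i in range(1, S):
        A[i, i - 1] = True
    return web_from_adjacency(A)


@pytest.fixture(scope="session")
def standard_web():
    """A validated S=30, C=0.15 web with at least three consumers."""
    rng = np.random.default_rng([2024, 0])
    return webgen.generate_valid_web(30, 0.15, rng)


@pytest.fixture(scope="session")
def standard_annotation(standard_web):
    return trophic.annotate(standard_web)


@pytest.fixture(scope="session")
def staged_community(standard_web, standard_annotation):
    # stage-center draws are rejection-sampled like any web: walk seeds
    # until no stage has an empty diet
    from fishweb.lifehistory import EmptyStageDiet

    for seed in range(99, 199):
        try:
            return insert_stages(standard_web, standard_annotation, seed=seed)
        except EmptyStageDiet:
            continue
    raise RuntimeError("no staged web in 100 seeds")
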