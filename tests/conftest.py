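import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from moblue.engine import RateParams
from moblue.network import ReactionNetwork, Reaction, Species


@pytest.fixture(scope="session")
def params():
    """Neutral parameters for engine oracles (no bias, no templating)."""
    return RateParams(k_bi_base=1.0, k_nano=0.0, k_d=0.05)


def toy_network(species, reactions, max_nuclearity=None):
    """Assemble a hand-built network for oracle tests (not validated)."""
    if max_nuclearity is None:
        max_nuclearity = max(sp.nuclearity for sp in species)
    return ReactionNetwork(list(species), list(reactions), max_nuclearity)


@pytest.fixture
def dimerization_network():
    """A + A <-> A2 with exact (plain) constants."""
    def build(k_f=1.0, k_r=1.0):
        species = [Species("A", 1), Species("A2", 2)]
        reactions = [
            Reaction("synthesis", ("A", "A"), ("A2",), base_k=k_f, plain_rate=True),
            Reaction("degradation", ("A2",), ("A", "A"), base_k=k_r, plain_rate=True),
        ]
        return toy_network(species, reactions)
    return build


def dimer_stationary_mean(n_total: int, k_f: float, k_r: float) -> float:
    """Exact stationary mean dimer count of A+A<->A2 by detailed balance.

    The state is the dimer count d (a birth-death chain); with n = N - 2d
    monomers, the birth rate is k_f n(n-1)/2 and the death rate k_r d.
    """
    d_max = n_total // 2
    log_pi = np.zeros(d_max + 1)
    for d in range(d_max):
        n = n_total - 2 * d
        birth = k_f * n * (n - 1) / 2.0
        death = k_r * (d + 1)
        log_pi[d + 1] = log_pi[d] + np.log(birth) - np.log(death)
    pi = np.exp(log_pi - log_pi.max())
    pi /= pi.sum()
    return float(np.dot(np.arange(d_max + 1), pi))
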