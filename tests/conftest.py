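import numpy as np
import pytest

import netresil as nr


@pytest.fixture(scope="session")
def baseline9():
    """Fully connected 9-symptom network, tau=-2, w=0.5 (density 1)."""
    return nr.uniform_network(9, -2.0, 0.5)


@pytest.fixture(scope="session")
def baseline9_report(baseline9):
    return exact_report(baseline9)


def exact_report(net):
    return nr.resilience_exact(nr.sumscore_distribution(nr.joint_distribution(net)))


def random_network(n, rng, tau_range=(-4.0, 4.0), w_range=(-2.0, 2.0)):
    """Random symmetric network with n nodes for property tests."""
    tau = rng.uniform(*tau_range, size=n)
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(*w_range, size=len(iu[0]))
    W[iu] = vals
    W.T[iu] = vals
    return nr.make_network(tau, W)
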