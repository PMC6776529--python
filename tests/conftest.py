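import numpy as np
import pytest

from signalflow import (
    Hyperparams,
    make_fig_fixture,
    normalize_link_weights,
    to_adjacency,
)


@pytest.fixture(scope="session")
def hp_default():
    return Hyperparams()  # alpha=0.9, beta=0.1, tol=1e-6


@pytest.fixture(scope="session")
def cascade():
    """3-node activating cascade x1 -> x2 -> x3 (all degrees 1)."""
    return make_fig_fixture("a")


@pytest.fixture(scope="session")
def crosstalk():
    """Two cascades with crosstalk converging on x6."""
    return make_fig_fixture("b")


@pytest.fixture(scope="session")
def negative_loop():
    """3-node negative feedback loop x1 -> x2 -> x3 -| x1."""
    return make_fig_fixture("c")


def weights_of(net, mean="geometric"):
    return normalize_link_weights(to_adjacency(net), mean=mean)


@pytest.fixture(scope="session")
def random_solvable_instances():
    """Random signed weight matrices with rho(alpha*W) < 1, plus basal vectors."""
    from signalflow import erdos_renyi_signed, spectral_radius

    hp = Hyperparams()
    instances = []
    seed = 0
    while len(instances) < 30:
        seed += 1
        net = erdos_renyi_signed(8, 0.25, sign_probability=0.3, seed=seed)
        if net.n_links < 2:
            continue
        W = weights_of(net)
        if spectral_radius(hp.alpha * W.entries) >= 0.999:
            continue
        b = np.random.default_rng(seed).normal(size=8)
        instances.append((net, W, b))
    return instances
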