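import numpy as np
import pytest

from pollinet import (
    BipartiteNetwork,
    NetworkSpec,
    generate_nested_network,
    sample_params,
)

# Gauss-Hermite order used by the simulation-heavy tests.  With trait
# standard deviations far below the kernel width the expectation integrand
# is nearly polynomial over the trait distribution, so a low order is
# already exact to ~1e-10; the closed-form oracle tests use the default 21.
FAST_NODES = 7


@pytest.fixture(scope="session")
def two_species_net():
    return BipartiteNetwork(["p"], ["a"], np.array([[1.0]]))


@pytest.fixture(scope="session")
def net17():
    """17-species nested fixture (7 plants x 10 animals, C~0.29)."""
    spec = NetworkSpec(7, 10, 0.29, 0.29, seed=5)
    return generate_nested_network(spec, on_infeasible="best")


@pytest.fixture(scope="session")
def net30():
    """30-species fixture matching the artificial-ensemble design."""
    spec = NetworkSpec(15, 15, 0.42, 0.6, seed=4)
    return generate_nested_network(spec, on_infeasible="best")


@pytest.fixture(scope="session")
def net49():
    """~50-species nested revival fixture (21 plants x 28 animals)."""
    spec = NetworkSpec(21, 28, 0.17, 0.32, seed=42)
    return generate_nested_network(spec, on_infeasible="best")


@pytest.fixture(scope="session")
def ensemble():
    """The 10-network artificial ensemble: 30 species, C=0.42, NODF 0.3-1."""
    nets = []
    for i, target in enumerate(np.linspace(0.3, 1.0, 10)):
        spec = NetworkSpec(15, 15, 0.42, float(target), seed=i + 1)
        nets.append(generate_nested_network(spec, on_infeasible="best"))
    return nets


@pytest.fixture(scope="session")
def ensemble_sweeps(ensemble):
    """Forward and backward sweeps for every ensemble network (shared by
    the collapse-regime and hysteresis tests; ~1 min of integration)."""
    from pollinet import collapse_sweep, hysteresis_sweep

    out = []
    for i, net in enumerate(ensemble):
        p = sample_params(net, seed=i + 1, sigma="low", quadrature_nodes=FAST_NODES)
        fwd = collapse_sweep(net, p, seed=i + 1)
        bwd = hysteresis_sweep(net, p, seed=i + 1)
        out.append((net, fwd, bwd))
    return out
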