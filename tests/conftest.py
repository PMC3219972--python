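import pytest

from cfpath import SolverConfig, figure2_network, figueiredo_network, glcat_network


@pytest.fixture(scope="session")
def fig2():
    """Toy bundle plus its split network and carbon graph."""
    bundle = figure2_network()
    net, graph = bundle.prepare()
    return bundle, net, graph


@pytest.fixture(scope="session")
def fig5_shunt():
    bundle = figueiredo_network(with_glyoxylate_shunt=True)
    net, graph = bundle.prepare()
    return bundle, net, graph


@pytest.fixture(scope="session")
def fig5_noshunt():
    bundle = figueiredo_network(with_glyoxylate_shunt=False)
    net, graph = bundle.prepare()
    return bundle, net, graph


@pytest.fixture(scope="session")
def glcat():
    bundle = glcat_network()
    net, graph = bundle.prepare()
    return bundle, net, graph


@pytest.fixture(scope="session")
def config():
    return SolverConfig()
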