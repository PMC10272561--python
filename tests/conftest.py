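import numpy as np
import pytest

from coexscreen import synthetic


@pytest.fixture(scope="session")
def bulk():
    """Planted 4-module bulk dataset at the default study conditions."""
    spec = synthetic.ModulePlantSpec(seed=11, loading_spread=0.15)
    return synthetic.generate_bulk_expression(spec)


@pytest.fixture(scope="session")
def ppi():
    """500-node scale-free network with a designated hub cluster."""
    from coexscreen import proximity as px
    edges = synthetic.generate_ppi_network(synthetic.NetworkPlantSpec(seed=7))
    net = px.load_string_edges(edges)
    hubs = synthetic.choose_module_hubs(net.graph, 10, seed=7)
    return net, hubs, edges


@pytest.fixture(scope="session")
def cells():
    """Cell-type structured counts with the module up-shifted in Mic1."""
    module_genes = [f"G{i:04d}" for i in range(1, 21)]
    spec = synthetic.CellPopulationSpec(seed=3)
    return synthetic.generate_counts(spec, module_genes), module_genes


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
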