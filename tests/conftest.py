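import numpy as np
import pytest

import lcn.extract as ex
import lcn.synth as synth
from lcn.datatypes import LCNGraph


@pytest.fixture(scope="session")
def small_params():
    return synth.GeneratorParams(domain_size_um=(30.0, 30.0, 30.0), seed=3)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return synth.generate_ground_truth(small_params)


@pytest.fixture(scope="session")
def default_params():
    return synth.GeneratorParams(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_params):
    return synth.generate_ground_truth(default_params)


@pytest.fixture(scope="session")
def default_stack(default_truth, default_params):
    raw = synth.rasterize(default_truth, default_params)
    return synth.degrade(raw, default_params)


@pytest.fixture(scope="session")
def default_extraction(default_stack):
    return ex.extract_network(default_stack)


def make_empty_domain_params(**kw):
    base = dict(
        domain_size_um=(20.0, 12.0, 12.0),
        lacuna_number_density=0.0,
        target_node_density=0.0,
        target_can_density=0.0,
        unordered_fraction=0.0,
        noise_sd=0.0,
        background_gradient=0.0,
        seed=0,
    )
    base.update(kw)
    return synth.GeneratorParams(**base)


def make_manual_truth(params, graph, lacunae=()):
    """Ground truth wrapping a hand-built graph, for rasterization tests."""
    return synth.GroundTruth(
        graph=graph,
        lacunae=list(lacunae),
        region_label_field=np.zeros((1, 1, 1), dtype=np.uint8),
        interface_plane_x_um=None,
        per_region_targets={},
        realized={},
        params=params,
        seed=params.seed,
    )


def straight_tube_graph(p0, p1):
    g = LCNGraph()
    g.add_node(0, p0, "endpoint")
    g.add_node(1, p1, "endpoint")
    g.add_edge(0, 1, np.vstack([p0, p1]).astype(float))
    return g
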