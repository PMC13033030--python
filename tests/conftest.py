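import numpy as np
import pytest

import monodec as md


@pytest.fixture(scope="session")
def hex2():
    """2-ring regular hexagonal patch (19 cells) as a Monolayer."""
    top, r = md.fixture_hexagonal_patch(2)
    return md.Monolayer(top.cells, r)


@pytest.fixture(scope="session")
def hex3():
    top, r = md.fixture_hexagonal_patch(3)
    return md.Monolayer(top.cells, r)


@pytest.fixture(scope="session")
def sheared3():
    """Sheared 3-ring patch: edges no longer orthogonal to links."""
    top, r = md.fixture_hexagonal_patch(3)
    return md.Monolayer(top.cells, md.shear_positions(r, 0.3))


@pytest.fixture(scope="session")
def annulus1():
    top, r = md.fixture_annulus(4, holes=1)
    return md.Monolayer(top.cells, r)


@pytest.fixture(scope="session")
def annulus2():
    top, r = md.fixture_annulus(4, holes=2)
    return md.Monolayer(top.cells, r)


@pytest.fixture(scope="session")
def params():
    return md.VertexModelParams(rng_seed=11)


@pytest.fixture(scope="session")
def grown80(params):
    """Seeded disordered monolayer, 80 cells, relaxed to force_tol."""
    return md.grow_monolayer(80, params)


def random_edge_field(mono, rng, carrier="edges"):
    """Random vector field supported on retained (interior) edges."""
    v = np.zeros((mono.n_edges, 2))
    re = mono.reduced.retained_edges
    v[re] = rng.normal(size=(len(re), 2))
    return md.EdgeVectorField(carrier, v)
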