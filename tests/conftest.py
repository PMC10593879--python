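import numpy as np
import pytest

import polycortex as px


@pytest.fixture(scope="session")
def mesh2():
    """162-vertex icosphere with medial-wall caps."""
    return px.make_sphere_mesh(2, radius=50.0)


@pytest.fixture(scope="session")
def mesh3():
    """642-vertex icosphere with medial-wall caps."""
    return px.make_sphere_mesh(3, radius=50.0)


@pytest.fixture(scope="session")
def atlases3(mesh3):
    return px.make_atlases(mesh3, seed=42)


@pytest.fixture(scope="session")
def cohort50():
    return px.simulate_cohort(px.CohortSpec(n_subjects=50, n_scanners=2),
                              seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
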