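import numpy as np
import pytest
from hypothesis import settings

import wingshape as ws

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """A reduced study: 8 taxa, 3-4 specimens, coarser geometry — fast but
    exercising every stage."""
    return ws.SimulationSpec(
        seed=7,
        n_taxa=8,
        specimens_min=3,
        specimens_max=4,
        n_vertices=200,
        n_strips=200,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return ws.generate_dataset(small_spec)


@pytest.fixture(scope="session")
def tree3():
    return ws.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def landmark_cloud():
    """Ten noisy rotated/scaled/translated replicates of one 12-landmark
    configuration, with two semilandmarks."""
    rng = np.random.default_rng(42)
    base = rng.normal(size=(12, 2))
    out = []
    for _ in range(10):
        X = base + rng.normal(scale=0.02, size=(12, 2))
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        out.append(
            ws.LandmarkSet(
                coords=(X @ R.T) * rng.uniform(0.5, 2.0) + rng.normal(size=2),
                semilandmark_indices=(4, 7),
            )
        )
    return out


@pytest.fixture
def rectangle_outline():
    return ws.WingOutline(
        vertices=np.array([[0.0, -0.1], [1.0, -0.1], [1.0, 0.1], [0.0, 0.1]]),
        base_point=np.array([0.0, -0.1]),
        apex_point=np.array([1.0, -0.1]),
    )
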