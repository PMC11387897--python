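import numpy as np
import pytest

import skullfea as sf


@pytest.fixture(scope="session")
def material():
    return sf.MaterialProperties()  # 15000 MPa, nu = 0.29


@pytest.fixture(scope="session")
def cranium():
    """Default cranium proxy shared across tests (read-only)."""
    return sf.generate_proxy(sf.ProxyParams())


@pytest.fixture(scope="session")
def cranium_loads(cranium):
    """Muscle-only load case on the default cranium."""
    return sf.build_load_case(
        cranium, spec=sf.MuscleSpec(adductor_area=cranium.adductor_area)
    )


@pytest.fixture(scope="session")
def cranium_field(cranium, material, cranium_loads):
    return sf.solve(cranium.mesh, material, cranium_loads)


@pytest.fixture
def unit_tet():
    """Unit right tetrahedron: volume 1/6."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return sf.TetMesh(nodes, np.array([[0, 1, 2, 3]]))


@pytest.fixture
def cube_mesh():
    """Unit cube split into 6 tets (Kuhn decomposition)."""
    from skullfea.verification import tet_box

    return tet_box(1.0, 1.0, 1.0, 1, 1, 1)


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
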