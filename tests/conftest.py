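import numpy as np
import pytest
import trimesh

from tavrgen.anatomy_mesh import LabeledMesh, MeshConfig, build_base_mesh
from tavrgen.features import StructureLabel
from tavrgen.parameter_space import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_config():
    """Reduced-resolution configuration for fast unit tests."""
    return MeshConfig(circumferential=32, axial=48)


@pytest.fixture(scope="session")
def small_mesh(small_config):
    return build_base_mesh(small_config)


@pytest.fixture(scope="session")
def default_mesh():
    """The full default-resolution base mesh."""
    return build_base_mesh()


@pytest.fixture
def cylinder_mesh():
    """Analytic fixture: a closed cylinder of radius 10 mm labelled as the
    aorta (known diameter 20 mm)."""
    cyl = trimesh.creation.cylinder(radius=10.0, height=40.0, sections=128)
    return LabeledMesh(
        vertices=cyl.vertices,
        faces=cyl.faces,
        submeshes={StructureLabel.AORTA: np.arange(len(cyl.faces))},
    )
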