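"""Shared fixtures: small sphere meshes and sensor layouts, built once."""

import numpy as np
import pytest

from sensmap.conductivity import ConductivityField, assign_conductivities
from sensmap.meshing import build_layered_sphere_mesh
from sensmap.sensors import place_sensors


@pytest.fixture(scope="session")
def small_three_layer():
    """Tiny 3-shell mesh (~4k elements) for transfer/direct equivalence."""
    mesh = build_layered_sphere_mesh([20.0, 26.0, 32.0], 6.0, seed=5)
    cond = assign_conductivities(mesh, "3CI")
    return mesh, cond


@pytest.fixture(scope="session")
def four_layer_mesh():
    """Coarse 4-shell head mesh (edge 14 mm) for pipeline-level tests."""
    return build_layered_sphere_mesh([78.0, 80.0, 86.0, 92.0], 14.0, seed=1)


@pytest.fixture(scope="session")
def four_layer_cond(four_layer_mesh):
    return assign_conductivities(four_layer_mesh, "4CI")


@pytest.fixture(scope="session")
def four_layer_sensors(four_layer_mesh):
    return place_sensors(four_layer_mesh, 32, 24, coil_offset=20.0, seed=2)


@pytest.fixture(scope="session")
def homogeneous_sphere():
    """Single-shell sphere mesh with uniform conductivity for MEG tests."""
    mesh = build_layered_sphere_mesh([92.0], 12.0, seed=3, label_names=["brain"])
    cond = ConductivityField(
        np.tile(0.33 * np.eye(3), (mesh.n_elements, 1, 1)), "homogeneous"
    )
    return mesh, cond
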