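"""Shared fixtures: small meshes and forward-generated observation pairs.

Everything is generated programmatically at session scope so the expensive
FEM objects are built once and reused read-only across tests.
"""

import numpy as np
import pytest

from prolifmap.forward_model import FemOperators, ModelParams, run_forward
from prolifmap.inverse import ObservationPair, k_elem_from_regions
from prolifmap.mesh import (
    build_mesh,
    partition_regions,
    raster_to_nodal,
    tumor_elements,
)
import prolifmap.synthetic_data as sd


@pytest.fixture(scope="session")
def square_mesh():
    """~20x20 mm square domain meshed at the default 1.5 mm target edge."""
    mask = np.zeros((24, 24), dtype=bool)
    mask[2:22, 2:22] = True
    return build_mesh(mask, (1.0, 1.0), 1.5)


@pytest.fixture(scope="session")
def phantom8():
    """Standard 8-region phantom: 64x64 grid, 1 mm pixels, 8 mm tumor radius."""
    return sd.make_phantom(
        (64, 64),
        tumor_spec={"radius_mm": 8.0},
        k_field_spec={"values": np.linspace(-0.15, 0.1, 8)},
        D0=5e-3,
        seed=5,
    )


@pytest.fixture(scope="session")
def phantom_mesh(phantom8):
    domain = sd.mesh_domain_mask(phantom8)
    return build_mesh(domain, phantom8.pixel_spacing, 1.5, roi_mask=phantom8.roi_mask_per_time[0])


@pytest.fixture(scope="session")
def partition8(phantom_mesh, phantom8):
    """Partition of the tumor elements into exactly 8 k-means regions."""
    elems = tumor_elements(phantom_mesh, phantom8.roi_mask_per_time[0], phantom8.pixel_spacing)
    return partition_regions(
        phantom_mesh, elems, elements_per_region=max(1, int(np.ceil(elems.size / 8)))
    )


@pytest.fixture(scope="session")
def n0_nodal(phantom_mesh, phantom8):
    return np.clip(
        raster_to_nodal(phantom8.n0_frac, phantom_mesh, phantom8.pixel_spacing), 0.0, 1.0
    )


K_TRUE_8 = np.array([-0.18, -0.12, -0.07, -0.02, 0.02, 0.06, 0.11, 0.16])
D0_TRUE = 5e-3


def make_pair(mesh, partition, n0, params, k_true=K_TRUE_8, days=29.0):
    """Inverse-crime observation pair generated by the forward model itself."""
    k_elem = k_elem_from_regions(k_true[: partition.n_regions], partition, mesh.n_triangles)
    series = run_forward(n0, k_elem, params, days, mesh=mesh, input_is_fraction=True)
    return ObservationPair(
        pair_label="T01",
        n_start=series.n_frac[0],
        n_end=series.n_frac[-1],
        interval_days=days,
        roi_nodes=mesh.node_in_roi.copy(),
    )


@pytest.fixture(scope="session")
def decoupled_params():
    return ModelParams(D0=D0_TRUE, gamma=0.0, lam=0.0, theta=1.0)


@pytest.fixture(scope="session")
def coupled_params():
    return ModelParams(D0=D0_TRUE, gamma=1.0, lam=1.0, theta=1.0)


@pytest.fixture(scope="session")
def pair_decoupled(phantom_mesh, partition8, n0_nodal, decoupled_params):
    return make_pair(phantom_mesh, partition8, n0_nodal, decoupled_params)


@pytest.fixture(scope="session")
def pair_coupled(phantom_mesh, partition8, n0_nodal, coupled_params):
    return make_pair(phantom_mesh, partition8, n0_nodal, coupled_params)


@pytest.fixture(scope="session")
def ops_decoupled(phantom_mesh, decoupled_params):
    return FemOperators(phantom_mesh, decoupled_params)
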