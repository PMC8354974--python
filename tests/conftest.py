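"""Shared fixtures: analytic meshes and session-scoped phantoms.

Everything is generated programmatically; the lateral phantom at 0.3 mm
voxels is session-scoped because several suites exercise it.
"""

import numpy as np
import pytest

import aneusep as an
from aneusep.neck_curve import EdgeGraph


def make_uv_sphere(radius=1.0, n_lon=64, n_lat=32, center=(0.0, 0.0, 0.0)):
    """(TriangleMesh, ordered equator ring) — see aneusep.phantom.uv_sphere."""
    return an.phantom.uv_sphere(radius, n_lon, n_lat, center)


def make_tetrahedron():
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.5, np.sqrt(3) / 2, 0.0], [0.5, np.sqrt(3) / 6, 0.8]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [2, 0, 3]])
    return an.TriangleMesh(verts, faces)


def make_icosahedron():
    import trimesh
    ico = trimesh.creation.icosahedron()
    return an.TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def lateral_phantom():
    spec = an.lateral_preset(voxel=0.3, seed=1)
    mesh, gt = an.phantom_mesh(spec)
    return spec, mesh, gt


@pytest.fixture(scope="session")
def lateral_graph(lateral_phantom):
    _, mesh, _ = lateral_phantom
    return EdgeGraph.from_mesh(mesh)


@pytest.fixture(scope="session")
def lateral_curves(lateral_phantom, lateral_graph):
    """Ten simulated annotators (one outlier) on the lateral phantom."""
    spec, mesh, gt = lateral_phantom
    return an.simulated_annotators(mesh, spec, gt, n_users=10,
                                   graph=lateral_graph, seed=7)


@pytest.fixture(scope="session")
def gt_neck_curve(lateral_phantom, lateral_graph):
    """Neck curve built from picks placed exactly on the analytic neck."""
    spec, mesh, gt = lateral_phantom
    picks = an.PickedPointSet(gt[:: len(gt) // 10][:10])
    return an.build_neck_curve(mesh, picks, graph=lateral_graph)


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_uv_sphere(radius=10.0, n_lon=64, n_lat=32)


@pytest.fixture
def tetra():
    return make_tetrahedron()
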