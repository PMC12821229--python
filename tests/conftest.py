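"""Shared fixtures: expensive phantom/simulation artifacts are session-scoped
so the acceptance suite reuses them."""

import numpy as np
import pytest

from mammosim.phantom import PhantomSpec, make_breast_phantom, make_supine_truth
from mammosim.solver import SimulationConfig


@pytest.fixture(scope="session")
def coarse_model():
    """Default coarse phantom (~1.5-3k tets) used by the closed-loop tests."""
    return make_breast_phantom(PhantomSpec.coarse())


@pytest.fixture(scope="session")
def phantom_sim_config():
    return SimulationConfig(safety=0.3)


@pytest.fixture(scope="session")
def supine_truth(coarse_model, phantom_sim_config):
    """Ground truth at mu_B = 220 Pa, f = 6 (g_B per rule, tau = 0.01 s)."""
    return make_supine_truth(coarse_model, 220.0, 6.0, phantom_sim_config)


def brick_model(n=(4, 4, 4), size=(0.04, 0.04, 0.04), mu=500.0, k_ratio=50.0,
                g=0.0, tau=0.01, fixed_base=True):
    """Structured brick BodyModel for solver benchmarks: bottom (y = 0) nodes
    are the chest interface (fixed-tie contact clamps them)."""
    from mammosim.constitutive import MaterialSet, make_material
    from mammosim.geometry_io import TetMesh
    from mammosim.phantom import BodyModel, _kuhn_tets
    from mammosim.solver import ContactSpec

    nx, ny, nz = n
    xs = np.linspace(0, size[0], nx + 1)
    ys = np.linspace(0, size[1], ny + 1)
    zs = np.linspace(0, size[2], nz + 1)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    idx = np.arange(np.prod(shape)).reshape(shape)
    nodes = grid.reshape(-1, 3)
    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    offsets = [(b & 1, (b >> 1) & 1, (b >> 2) & 1) for b in range(8)]
    corners = np.stack([idx[ci + dx, cj + dy, ck + dz] for dx, dy, dz in offsets], axis=1)
    tets = _kuhn_tets(corners)
    mesh = TetMesh(nodes, tets, regions=np.full(len(tets), "breast"))
    flip = mesh.volumes() < 0
    mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]
    node_sets = {"nipple": np.array([int(np.argmax(nodes[:, 1]))])}
    if fixed_base:
        node_sets["chest_interface"] = np.flatnonzero(nodes[:, 1] < 1e-12)
    mesh.node_sets = node_sets
    mesh.__post_init__()
    from mammosim.geometry_io import LandmarkSet

    mats = MaterialSet.from_breast(make_material(mu, k_ratio=k_ratio, g=g, tau=tau), f=1.0)
    return BodyModel(
        mesh=mesh, chest_wall=None,
        landmarks=LandmarkSet({"nipple_prone": nodes[node_sets["nipple"][0]].copy()}),
        materials=mats, contact=ContactSpec(mode="fixed"))


@pytest.fixture
def small_brick():
    return brick_model(n=(3, 3, 3), size=(0.03, 0.03, 0.03))
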