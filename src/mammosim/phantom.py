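"""Synthetic breast phantoms.

A parametric "prone" phantom — half-ellipsoid breast body on a planar chest
wall, 1.5 mm extruded skin shell, spherical tumor inclusion, apex nipple
landmark, and the labeled boundary node sets the solver's symmetry/contact
conditions need — plus a forward-simulated "supine" ground truth with known
material parameters, so the calibration loop can be tested closed-loop
without patient data.

The interior is meshed natively: structured grid, 6-tet Kuhn split per cube,
all-corners-inside ellipsoid clip, and boundary-node snapping onto the
analytic surface.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mammosim.constitutive import MaterialSet, make_material
from mammosim.geometry_io import (
    LandmarkSet,
    TetMesh,
    TriSurface,
    deform_points,
    extrude_skin,
)
from mammosim.solver import ContactSpec, SimulationConfig, Trajectory, run_simulation

__all__ = [
    "PhantomSpec",
    "BodyModel",
    "SupineTruth",
    "make_breast_phantom",
    "make_bilateral_surface",
    "make_supine_truth",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric prone phantom (all lengths in metres).

    ``radii`` are the ellipsoid semi-axes (x: medial-lateral, y: posterior->
    anterior/gravity, z: caudal-cranial); the body is the y >= 0 half resting
    on the chest-wall plane y = 0.
    """

    radii: tuple = (0.060, 0.060, 0.055)
    skin_thickness: float = 0.0015
    tumor_center: tuple = (0.0, 0.012, 0.0)
    tumor_radius: float = 0.0075
    edge_length: float = 0.006
    chest_margin: float = 1.4  # chest-wall half-extent as multiple of radii
    jitter: float = 0.0
    seed: int = 0
    bilateral_gap: float = 0.030  # flat strip half-width for bilateral surfaces

    def __post_init__(self):
        a, b, c = self.radii
        if min(a, b, c) <= 0 or self.skin_thickness <= 0:
            raise ValueError("radii and skin thickness must be positive")
        if self.edge_length >= min(self.radii) / 4.0:
            raise ValueError("edge length must be < smallest semi-axis / 4")
        if self.jitter >= 0.1 * self.edge_length:
            raise ValueError("jitter must be < 0.1 * edge length")
        center = np.asarray(self.tumor_center, dtype=float)
        # tumor strictly inside the half-ellipsoid: probe sphere surface
        dirs = np.array([d for d in np.ndindex(3, 3, 3)], dtype=float) - 1.0
        dirs = dirs[np.any(dirs != 0, axis=1)]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        probes = center + self.tumor_radius * dirs
        ax = np.asarray(self.radii)
        if np.any(np.sum((probes / ax) ** 2, axis=1) >= 1.0) or np.any(probes[:, 1] <= 0):
            raise ValueError("tumor sphere is not strictly inside the breast body")

    @classmethod
    def coarse(cls, **overrides) -> "PhantomSpec":
        """Coarse setting (~1.5-3k tets) used by the closed-loop experiments."""
        overrides.setdefault("edge_length", 0.012)
        return cls(**overrides)


@dataclass
class BodyModel:
    """Deformable phantom ready for simulation."""

    mesh: TetMesh
    chest_wall: TriSurface
    landmarks: LandmarkSet
    materials: MaterialSet
    contact: ContactSpec = field(default_factory=ContactSpec)
    spec: PhantomSpec | None = None

    def with_materials(self, materials: MaterialSet) -> "BodyModel":
        return BodyModel(mesh=self.mesh, chest_wall=self.chest_wall,
                         landmarks=self.landmarks, materials=materials,
                         contact=self.contact, spec=self.spec)

    def with_contact(self, contact: ContactSpec) -> "BodyModel":
        return BodyModel(mesh=self.mesh, chest_wall=self.chest_wall,
                         landmarks=self.landmarks, materials=self.materials,
                         contact=contact, spec=self.spec)


# ---------------------------------------------------------------------------
# interior meshing


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_tets(cube_corner_ids: np.ndarray) -> np.ndarray:
    """Split cubes (n, 8) with corners indexed by bit pattern (x + 2y + 4z)
    into 6 tets each along the main diagonal (conforming across cubes)."""
    tets = []
    for perm in _KUHN_PERMS:
        b1 = 1 << perm[0]
        b2 = b1 | (1 << perm[1])
        tets.append(np.stack([
            cube_corner_ids[:, 0], cube_corner_ids[:, b1],
            cube_corner_ids[:, b2], cube_corner_ids[:, 7],
        ], axis=1))
    return np.concatenate(tets, axis=0)


def _ellipsoid_phi(points: np.ndarray, radii) -> np.ndarray:
    ax = np.asarray(radii, dtype=float)
    return np.sum((points / ax) ** 2, axis=-1)


def _mesh_half_ellipsoid(spec: PhantomSpec):
    """Structured interior tet mesh of the y >= 0 half-ellipsoid with
    boundary nodes snapped onto the analytic surface."""
    a, b, c = spec.radii
    h = spec.edge_length
    nx = int(np.ceil(a / h))
    ny = int(np.ceil(b / h))
    nz = int(np.ceil(c / h))
    xs = np.arange(-nx, nx + 1) * h
    ys = np.arange(0, ny + 1) * h
    zs = np.arange(-nz, nz + 1) * h
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    grid = np.stack([gx, gy, gz], axis=-1)
    shape = grid.shape[:3]
    # keep cubes whose center is inside (volume-unbiased staircase)
    centers = 0.5 * (grid[:-1, :-1, :-1] + grid[1:, 1:, 1:])
    keep = _ellipsoid_phi(centers, spec.radii) <= 1.0
    if not keep.any():
        raise ValueError("edge length too coarse: no interior cube fits the body")

    idx = -np.ones(shape, dtype=np.int64)
    corner_offsets = [(bit & 1, (bit >> 1) & 1, (bit >> 2) & 1) for bit in range(8)]
    ci, cj, ck = np.nonzero(keep)
    used = np.zeros(shape, dtype=bool)
    for dx, dy, dz in corner_offsets:
        used[ci + dx, cj + dy, ck + dz] = True
    ui, uj, uk = np.nonzero(used)
    idx[ui, uj, uk] = np.arange(len(ui))
    nodes = grid[ui, uj, uk].astype(float)

    corners = np.stack(
        [idx[ci + dx, cj + dy, ck + dz] for dx, dy, dz in corner_offsets], axis=1)
    tets = _kuhn_tets(corners)
    mesh = TetMesh(nodes, tets, regions=np.full(len(tets), "breast"))
    vols = mesh.volumes()
    flip = vols < 0
    mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]

    # classify boundary nodes of the staircase
    bfaces = mesh.boundary_faces()
    fnormals = TriSurface(mesh.nodes, bfaces).face_normals()
    lateral_faces = bfaces[np.abs(fnormals[:, 1] + 1.0) > 1e-9]  # not the y=0 base
    lateral_nodes = np.unique(lateral_faces)
    base = np.abs(mesh.nodes[:, 1]) < 1e-12
    snap_3d = lateral_nodes[~base[lateral_nodes]]
    snap_rim = lateral_nodes[base[lateral_nodes]]

    target = mesh.nodes.copy()
    phi_n = _ellipsoid_phi(mesh.nodes[snap_3d], spec.radii)
    target[snap_3d] = mesh.nodes[snap_3d] / np.sqrt(phi_n)[:, None]
    rim_phi = (mesh.nodes[snap_rim, 0] / a) ** 2 + (mesh.nodes[snap_rim, 2] / c) ** 2
    rim_scale = 1.0 / np.sqrt(np.maximum(rim_phi, 1e-30))
    target[snap_rim, 0] = mesh.nodes[snap_rim, 0] * rim_scale
    target[snap_rim, 2] = mesh.nodes[snap_rim, 2] * rim_scale

    # snap with per-node relaxation: back off nodes whose move would create
    # inverted or sliver elements (quality floor relative to the median)
    blend = np.ones(mesh.n_nodes)
    floor = 0.04 * float(np.median(mesh.volumes()))
    result = None
    for it in range(24):
        cand = mesh.nodes + blend[:, None] * (target - mesh.nodes)
        vols = mesh.volumes(cand)
        if np.all(vols > 1e-16) and result is None:
            result = cand.copy()  # best inversion-free fallback so far
        bad = vols <= (floor if it < 12 else 1e-16)
        if not bad.any():
            result = cand
            break
        blend[np.unique(mesh.tets[bad])] *= 0.5
    if result is None:
        raise ValueError("boundary snapping failed to keep all tets positive")
    mesh.nodes = result

    _smooth_interior(mesh, np.unique(bfaces))

    boundary_set = set(np.unique(bfaces).tolist())
    return mesh, lateral_faces, boundary_set


def _smooth_interior(mesh: TetMesh, boundary_nodes: np.ndarray,
                     iterations: int = 4, relax: float = 0.5) -> None:
    """Laplacian smoothing of interior nodes (boundary fixed) to relieve the
    sliver elements that boundary snapping can produce; each pass is backed
    off if it would invert an element."""
    free = np.ones(mesh.n_nodes, dtype=bool)
    free[boundary_nodes] = False
    t = mesh.tets
    pairs = np.concatenate([t[:, [0, 1]], t[:, [0, 2]], t[:, [0, 3]],
                            t[:, [1, 2]], t[:, [1, 3]], t[:, [2, 3]]])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    deg = np.bincount(src, minlength=mesh.n_nodes).astype(float)
    for _ in range(iterations):
        mean = np.zeros((mesh.n_nodes, 3))
        for k in range(3):
            mean[:, k] = np.bincount(src, weights=mesh.nodes[dst, k],
                                     minlength=mesh.n_nodes)
        mean /= np.maximum(deg, 1.0)[:, None]
        step = relax
        for _ in range(6):
            cand = mesh.nodes.copy()
            cand[free] += step * (mean[free] - mesh.nodes[free])
            if np.all(mesh.volumes(cand) > 0):
                mesh.nodes = cand
                break
            step *= 0.5


def make_breast_phantom(spec: PhantomSpec, *, materials: MaterialSet | None = None,
                        contact: ContactSpec | None = None) -> BodyModel:
    """Build the prone phantom `BodyModel` for a spec.

    The tet mesh carries regions breast/skin/tumor and node sets
    ``junction`` (medial x-extreme strip, u_x = 0), ``superior_inferior``
    (z-extreme strips, u_z = 0), ``chest_interface`` (nodes on the y = 0
    plane) and ``nipple`` (single anterior apex node on the outer skin).
    """
    interior, lateral_faces, _ = _mesh_half_ellipsoid(spec)
    h = spec.edge_length
    rng = np.random.default_rng(spec.seed)

    # jitter interior nodes only (keep boundary & base geometry exact)
    if spec.jitter > 0:
        bnodes = np.unique(interior.boundary_faces())
        mask = np.ones(interior.n_nodes, dtype=bool)
        mask[bnodes] = False
        noise = rng.uniform(-spec.jitter, spec.jitter, size=(interior.n_nodes, 3))
        interior.nodes[mask] += noise[mask]
        if np.any(interior.volumes() <= 0):
            raise ValueError("jitter inverted interior elements; reduce amplitude")
    else:
        rng.uniform(-1, 1, size=3)  # consume state so seeds stay comparable

    # tumor labeling by element-centroid-in-sphere
    centroids = interior.nodes[interior.tets].mean(axis=1)
    center = np.asarray(spec.tumor_center, dtype=float)
    in_tumor = np.linalg.norm(centroids - center, axis=1) <= spec.tumor_radius
    interior.regions = np.where(in_tumor, "tumor", "breast")

    # skin shell over the lateral (curved) surface
    sub_ids = np.unique(lateral_faces)
    remap = -np.ones(interior.n_nodes, dtype=np.int64)
    remap[sub_ids] = np.arange(len(sub_ids))
    outer_patch = TriSurface(interior.nodes[sub_ids], remap[lateral_faces])
    for smooth in (2, 4, 8):
        try:
            shell, shell_outer = extrude_skin(outer_patch, spec.skin_thickness,
                                              smooth_normals=smooth)
            break
        except ValueError:
            if smooth == 8:
                raise

    # merge: shell inner nodes coincide with interior boundary nodes
    n_int = interior.n_nodes
    n_patch = len(sub_ids)
    shell_map = np.concatenate([sub_ids, n_int + np.arange(n_patch)])
    nodes = np.vstack([interior.nodes, shell.nodes[n_patch:]])
    tets = np.vstack([interior.tets, shell_map[shell.tets]])
    regions = np.concatenate([interior.regions, shell.regions])

    # flatten the skin rim onto the chest plane so the contact set is exact
    rim = np.abs(nodes[:, 1]) <= 0.75 * spec.skin_thickness
    nodes[rim, 1] = 0.0

    mesh = TetMesh(nodes, tets, regions=regions)
    if np.any(mesh.volumes() <= 0):
        raise ValueError("phantom assembly produced inverted elements")

    x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
    strip = 0.6 * h
    node_sets = {
        "junction": np.flatnonzero(x <= x.min() + strip),
        "superior_inferior": np.flatnonzero(
            (z >= z.max() - strip) | (z <= z.min() + strip)),
        "chest_interface": np.flatnonzero(np.abs(y) <= 1e-12),
        "nipple": np.array([int(np.argmax(y))]),
    }
    mesh.node_sets = node_sets
    mesh.__post_init__()

    nipple_pos = nodes[node_sets["nipple"][0]].copy()
    landmarks = LandmarkSet({"nipple_prone": nipple_pos})

    a, b, c = spec.radii
    chest_wall = _chest_plane(spec.chest_margin * a, spec.chest_margin * c)

    if materials is None:
        materials = MaterialSet.from_breast(make_material(220.0, g=0.8), f=6.0)
    if contact is None:
        contact = ContactSpec()
    return BodyModel(mesh=mesh, chest_wall=chest_wall, landmarks=landmarks,
                     materials=materials, contact=contact, spec=spec)


def _chest_plane(half_x: float, half_z: float, n: int = 4) -> TriSurface:
    """Rigid chest-wall plane y = 0 triangulated n x n, normals along +y."""
    xs = np.linspace(-half_x, half_x, n + 1)
    zs = np.linspace(-half_z, half_z, n + 1)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    verts = np.stack([gx.ravel(), np.zeros(gx.size), gz.ravel()], axis=1)
    faces = []
    for i in range(n):
        for j in range(n):
            v00 = i * (n + 1) + j
            v01 = v00 + 1
            v10 = v00 + (n + 1)
            v11 = v10 + 1
            faces.append([v00, v01, v11])  # +y normal (x cross z ordering)
            faces.append([v00, v11, v10])
    return TriSurface(verts, np.asarray(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# bilateral surface (alignment fixtures)


def make_bilateral_surface(spec: PhantomSpec, n_per_edge: float = 1.0):
    """Connected bilateral chest surface: two breast mounds with a flat
    intermammary strip between them.

    Returns ``(surface, landmarks)``; the surface labels ground-truth vertex
    sets ``strip`` (the built-in flat region) and ``left``/``right`` breast
    mounds, and the landmarks hold both nipples.
    """
    a, b, c = spec.radii
    gap = spec.bilateral_gap
    d = a + gap  # breast center offset from the midline
    h = spec.edge_length / n_per_edge
    half_x = d + 1.25 * a
    half_z = 0.9 * c  # grid ends before the mounds do: the strip is the only
    # flat region connected to the point between the breasts
    nx = int(np.ceil(2 * half_x / h))
    nz = int(np.ceil(2 * half_z / h))
    nx += nx % 2  # even counts -> grid line exactly on the midline and apexes
    nz += nz % 2
    xs = np.linspace(-half_x, half_x, nx + 1)
    zs = np.linspace(-half_z, half_z, nz + 1)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")

    def bump(cx):
        r2 = ((gx - cx) / a) ** 2 + (gz / c) ** 2
        return b * np.sqrt(np.clip(1.0 - r2, 0.0, None))

    gy = bump(d) + bump(-d)
    rng = np.random.default_rng(spec.seed)
    if spec.jitter > 0:
        gy = gy + rng.uniform(-spec.jitter, spec.jitter, size=gy.shape)
    verts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    faces = []
    for i in range(nx):
        for j in range(nz):
            v00 = i * (nz + 1) + j
            v01 = v00 + 1
            v10 = v00 + (nz + 1)
            v11 = v10 + 1
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    surf = TriSurface(verts, np.asarray(faces, dtype=np.int64))

    flat = bump(d).ravel() + bump(-d).ravel() == 0.0
    # strip label = interior flat vertices between the breasts (vertices whose
    # entire one-ring is flat, so their normals are exactly planar)
    interior_flat = flat.copy()
    for e0, e1 in surf.edges():
        if not flat[e0]:
            interior_flat[e1] = False
        if not flat[e1]:
            interior_flat[e0] = False
    strip = interior_flat & (np.abs(verts[:, 0]) <= gap)
    surf.labels = {
        "strip": np.flatnonzero(strip),
        "right": np.flatnonzero(verts[:, 0] > 0),
        "left": np.flatnonzero(verts[:, 0] < 0),
    }
    right_ids = surf.labels["right"]
    left_ids = surf.labels["left"]
    nip_r = right_ids[np.argmax(verts[right_ids, 1])]
    nip_l = left_ids[np.argmax(verts[left_ids, 1])]
    landmarks = LandmarkSet({
        "nipple_right": verts[nip_r].copy(),
        "nipple_left": verts[nip_l].copy(),
    })
    return surf, landmarks


# ---------------------------------------------------------------------------
# forward-simulated supine ground truth


@dataclass
class SupineTruth:
    """Forward-simulated supine state with known material parameters."""

    surface: TriSurface
    nipple: np.ndarray
    tumor_centroid: np.ndarray
    trajectory: Trajectory
    sample_time: float
    mu_B: float
    f: float
    g_B: float


def make_supine_truth(model: BodyModel, mu_B: float, f: float,
                      config: SimulationConfig,
                      sample_time: float | None = None,
                      g_B: float | None = None, tau: float = 0.01,
                      k_ratio: float = 100.0) -> SupineTruth:
    """Simulate the prone phantom into the supine pose with known
    parameters and extract the state at ``sample_time``.

    ``g_B`` defaults to the piecewise calibration rule at ``mu_B``.
    """
    if not 80.0 <= mu_B <= 400.0:
        raise ValueError("ground-truth mu_B outside the plausible range [80, 400] Pa")
    if g_B is None:
        from mammosim.calibration import g_from_mu

        g_B = g_from_mu(mu_B)
    materials = MaterialSet.from_breast(
        make_material(mu_B, g=g_B, tau=tau, k_ratio=k_ratio), f=f)
    sim_model = model.with_materials(materials)
    traj = run_simulation(sim_model, config)
    if sample_time is None:
        sample_time = 0.5 * config.total_time
    idx = int(np.argmin(np.abs(traj.times - sample_time)))
    u = traj.displacements[idx]
    mesh = model.mesh
    surface = TriSurface(mesh.nodes + u, mesh.boundary_faces())
    nipple = traj.nipple_positions[idx].copy()
    prone_centroid = mesh.region_centroid("tumor")
    tumor = deform_points(mesh, u, prone_centroid)[0]
    return SupineTruth(surface=surface, nipple=nipple, tumor_centroid=tumor,
                       trajectory=traj, sample_time=float(traj.times[idx]),
                       mu_B=mu_B, f=f, g_B=g_B)
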