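"""Surface/volume mesh containers, STL and Slicer-markups I/O, skin-shell
extrusion, mesh geodesics, and barycentric field interpolation.

Internal units are SI metres; STL and markups files are interpreted as
millimetres by default (``unit_scale = 1e-3``).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "TriSurface",
    "LandmarkSet",
    "TetMesh",
    "read_surface",
    "write_surface",
    "read_markups",
    "write_markups",
    "extrude_skin",
    "geodesic_distance",
    "deform_points",
    "icosphere",
]


class STLParseError(ValueError):
    """Malformed STL content; message carries the byte offset."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class TriSurface:
    """Triangulated surface: ``vertices`` (n, 3) metres, ``faces`` (m, 3)
    vertex-index triples, optional named vertex subsets in ``labels``."""

    vertices: np.ndarray
    faces: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.where(norms > 0, norms, 1.0)
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals."""
        fn = self.face_normals(normalized=False)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.where(norms > 0, norms, 1.0)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Signed enclosed volume (divergence theorem); meaningful for
        closed surfaces with consistent winding."""
        v = self.vertices
        f = self.faces
        return float(np.einsum("ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))) / 6.0

    def volume_centroid(self) -> np.ndarray:
        """Centroid of the enclosed solid (divergence theorem); requires a
        closed surface with consistent winding."""
        v = self.vertices
        f = self.faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        det = np.einsum("ij,ij->i", a, np.cross(b, c))
        vol = det.sum() / 6.0
        if abs(vol) < 1e-18:
            raise ValueError("surface is not closed (zero enclosed volume)")
        moment = (a + b + c) / 4.0 * det[:, None] / 6.0  # tets (origin, a, b, c)
        return moment.sum(axis=0) / vol

    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def translated(self, offset) -> "TriSurface":
        return TriSurface(self.vertices + np.asarray(offset, float), self.faces.copy(),
                          dict(self.labels))

    def check(self) -> "TriSurface":
        """Validate invariants: in-range indices, no degenerate triangle."""
        areas = self.face_areas()
        bad = np.flatnonzero(areas <= 1e-18)
        if bad.size:
            raise ValueError(f"degenerate (zero-area) triangles at face indices {bad[:10].tolist()}")
        return self


@dataclass
class LandmarkSet:
    """Named 3-D points (metres) with a coordinate-frame tag."""

    points: dict
    frame: str = "internal"

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            if name in clean:
                raise ValueError(f"duplicate landmark label {name!r}")
            clean[name] = p
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self):
        return list(self.points)


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with per-element region labels and named node
    sets (``junction``, ``superior_inferior``, ``chest_interface``,
    ``nipple``)."""

    nodes: np.ndarray
    tets: np.ndarray
    regions: np.ndarray  # string label per element
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.regions = np.asarray(self.regions)
        if len(self.regions) != len(self.tets):
            raise ValueError("one region label required per element")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise ValueError("tet indices out of range")
        for name, ids in self.node_sets.items():
            ids = np.asarray(ids, dtype=np.int64).ravel()
            if ids.size and (ids.min() < 0 or ids.max() >= len(self.nodes)):
                raise ValueError(f"node set {name!r} references invalid nodes")
            self.node_sets[name] = ids
        if "nipple" in self.node_sets and len(self.node_sets["nipple"]) != 1:
            raise ValueError("nipple node set must contain exactly one node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """Signed tet volumes (positive for correct orientation)."""
        x = self.nodes if nodes is None else nodes
        t = self.tets
        d1 = x[t[:, 1]] - x[t[:, 0]]
        d2 = x[t[:, 2]] - x[t[:, 0]]
        d3 = x[t[:, 3]] - x[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def volume(self) -> float:
        return float(self.volumes().sum())

    def check(self) -> "TetMesh":
        vols = self.volumes()
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise ValueError(f"non-positive tet volumes at elements {bad[:10].tolist()}")
        return self

    def region_mask(self, label: str) -> np.ndarray:
        return self.regions == label

    def region_centroid(self, label: str, nodes: np.ndarray | None = None) -> np.ndarray:
        """Volume-weighted centroid of a labeled region."""
        x = self.nodes if nodes is None else nodes
        mask = self.region_mask(label)
        if not mask.any():
            raise ValueError(f"no elements labeled {label!r}")
        t = self.tets[mask]
        vols = np.abs(self.volumes(x)[mask])
        cents = x[t].mean(axis=1)
        return (vols[:, None] * cents).sum(axis=0) / vols.sum()

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary triangles (faces shared by one tet)."""
        t = self.tets
        # local faces ordered so the outward normal points away from the 4th node
        faces = np.concatenate([
            t[:, [0, 2, 1]], t[:, [0, 1, 3]], t[:, [1, 2, 3]], t[:, [0, 3, 2]],
        ])
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def surface(self) -> TriSurface:
        return TriSurface(self.nodes.copy(), self.boundary_faces())


# ---------------------------------------------------------------------------
# STL I/O


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = 0.0):
    """Merge duplicate vertices (exact or within tol) and reindex faces."""
    if tol > 0:
        key = np.round(vertices / tol).astype(np.int64)
    else:
        key = vertices
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[idx[order]], rank[inv][faces]


def read_surface(path, unit_scale: float = 1e-3, weld_tol: float = 1e-9) -> TriSurface:
    """Read a binary or ASCII STL file into a `TriSurface`.

    Vertices are multiplied by ``unit_scale`` (default mm -> m) and exactly
    coincident vertices are welded.
    """
    path = str(path)
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) == 0:
        raise STLParseError(f"{path}: empty file (byte offset 0)")
    if data.lstrip()[:5].lower() == b"solid" and b"facet" in data[:4096]:
        tris = _parse_ascii_stl(data, path)
    else:
        tris = _parse_binary_stl(data, path)
    if len(tris) == 0:
        raise STLParseError(f"{path}: no facets found")
    tris = np.asarray(tris, dtype=float) * unit_scale
    vertices = tris.reshape(-1, 3)
    faces = np.arange(len(vertices)).reshape(-1, 3)
    vertices, faces = _weld(vertices, faces, tol=weld_tol * 1e-3)
    surf = TriSurface(vertices, faces)
    # orient closed surfaces outward: flip if signed volume is negative
    if abs(surf.volume()) > 1e-15 and surf.volume() < 0:
        surf.faces = surf.faces[:, [0, 2, 1]]
    return surf


def _parse_binary_stl(data: bytes, path: str):
    if len(data) < 84:
        raise STLParseError(f"{path}: truncated binary STL header (byte offset {len(data)})")
    (n_tri,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * n_tri
    if len(data) < expected:
        raise STLParseError(
            f"{path}: binary STL declares {n_tri} facets but file ends at byte offset {len(data)}"
            f" (expected {expected})")
    raw = np.frombuffer(data, dtype=np.uint8, count=50 * n_tri, offset=84)
    rec = raw.reshape(n_tri, 50)[:, :48].copy().view("<f4").reshape(n_tri, 12)
    return rec[:, 3:12].astype(float).reshape(n_tri, 3, 3)


def _parse_ascii_stl(data: bytes, path: str):
    tris = []
    current = []
    offset = 0
    for line in data.splitlines(keepends=True):
        stripped = line.strip().lower()
        if stripped.startswith(b"vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise STLParseError(f"{path}: malformed vertex line at byte offset {offset}")
            try:
                current.append([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise STLParseError(
                    f"{path}: non-numeric vertex at byte offset {offset}") from exc
        elif stripped.startswith(b"endfacet"):
            if len(current) != 3:
                raise STLParseError(
                    f"{path}: facet with {len(current)} vertices at byte offset {offset}")
            tris.append(current)
            current = []
        offset += len(line)
    if current:
        raise STLParseError(f"{path}: unterminated facet at byte offset {offset}")
    return np.asarray(tris, dtype=float) if tris else np.zeros((0, 3, 3))


def write_surface(path, surface: TriSurface, unit_scale: float = 1e-3,
                  binary: bool = True, name: str = "mammosim") -> None:
    """Write a `TriSurface` as STL; vertices are divided by ``unit_scale``
    (default: metres stored as millimetres)."""
    v = surface.vertices / unit_scale
    f = surface.faces
    normals = surface.face_normals()
    path = str(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(name.encode().ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(f)))
            rec = np.zeros((len(f), 50), dtype=np.uint8)
            flat = np.concatenate(
                [normals, v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]], axis=1
            ).astype("<f4")
            rec[:, :48] = flat.view(np.uint8).reshape(len(f), 48)
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(f"solid {name}\n")
            for k, face in enumerate(f):
                n = normals[k]
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for vid in face:
                    p = v[vid]
                    fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")


# ---------------------------------------------------------------------------
# Slicer markups JSON


def read_markups(path, unit_scale: float = 1e-3, frame: str | None = None) -> LandmarkSet:
    """Read labeled control points from a Slicer ``.mrk.json`` file.

    Coordinates are converted to metres. Files declaring an LPS coordinate
    system are converted to the internal RAS-like frame by negating x and y;
    ``frame`` overrides the file's declaration ("RAS" or "LPS").
    """
    with open(path) as fh:
        doc = json.load(fh)
    markups = doc.get("markups")
    if not markups:
        raise ValueError(f"{path}: no 'markups' list")
    points = {}
    for m_idx, markup in enumerate(markups):
        declared = markup.get("coordinateSystem", "LPS")
        system = (frame or declared).upper()
        for c_idx, cp in enumerate(markup.get("controlPoints", [])):
            label = cp.get("label")
            pos = cp.get("position")
            if label is None or pos is None:
                raise ValueError(
                    f"{path}: control point {c_idx} of markup {m_idx} is missing "
                    f"{'label' if label is None else 'position'}")
            p = np.asarray(pos, dtype=float) * unit_scale
            if system == "LPS":
                p = p * np.array([-1.0, -1.0, 1.0])
            elif system != "RAS":
                raise ValueError(f"{path}: unknown coordinate system {system!r}")
            if label in points:
                raise ValueError(f"{path}: duplicate control point label {label!r}")
            points[label] = p
    return LandmarkSet(points=points, frame="internal")


def write_markups(path, landmarks: LandmarkSet, unit_scale: float = 1e-3,
                  coordinate_system: str = "RAS") -> None:
    """Write landmarks as a minimal Slicer markups fiducial file."""
    sign = np.array([-1.0, -1.0, 1.0]) if coordinate_system.upper() == "LPS" else np.ones(3)
    control_points = [
        {
            "id": str(i + 1),
            "label": name,
            "position": list((p * sign) / unit_scale),
        }
        for i, (name, p) in enumerate(landmarks.points.items())
    ]
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": coordinate_system.upper(),
                "controlPoints": control_points,
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# skin extrusion


def extrude_skin(surface: TriSurface, thickness: float, smooth_normals: int = 0):
    """Extrude a surface patch outward along vertex normals into a one-prism
    -thick tetrahedral shell.

    Each triangle becomes a prism split into 3 tets with the
    lowest-global-index diagonal rule (deterministic, globally consistent
    across shared quad faces).  ``smooth_normals`` rounds of one-ring normal
    averaging regularize the offset direction on rough meshes.  Returns
    ``(shell TetMesh, outer TriSurface)``; shell elements are labeled
    ``"skin"``.
    """
    if thickness <= 0:
        raise ValueError("skin thickness must be positive")
    vn = surface.vertex_normals()
    if smooth_normals > 0:
        edges = surface.edges()
        src = np.concatenate([edges[:, 0], edges[:, 1]])
        dst = np.concatenate([edges[:, 1], edges[:, 0]])
        for _ in range(smooth_normals):
            acc = vn.copy()
            for k in range(3):
                acc[:, k] += np.bincount(src, weights=vn[dst, k],
                                         minlength=len(vn))
            vn = acc / np.linalg.norm(acc, axis=1, keepdims=True)
    inner = surface.vertices
    outer = inner + thickness * vn
    n = len(inner)
    nodes = np.vstack([inner, outer])
    tets = []
    for tri in surface.faces:
        # order prism corners by global index so the diagonal rule (lowest
        # bottom index -> highest top index on every quad) is identical for
        # the two prisms sharing a side face
        orig = [int(v) for v in tri]
        i, j, k = sorted(orig)
        prism = [[i, j, k, k + n], [i, j, k + n, j + n], [i, j + n, k + n, i + n]]
        # odd permutations of the winding mirror the tets; restore parity so
        # that only genuine self-intersection yields negative volumes
        even = [orig, [orig[1], orig[2], orig[0]], [orig[2], orig[0], orig[1]]]
        if [i, j, k] not in even:
            prism = [[t[0], t[1], t[3], t[2]] for t in prism]
        tets.extend(prism)
    tets = np.asarray(tets, dtype=np.int64)
    shell = TetMesh(nodes, tets, regions=np.full(len(tets), "skin"))
    vols = shell.volumes()
    if np.any(vols <= 0):
        bad_tets = shell.tets[vols <= 0]
        bad_vertices = np.unique(bad_tets % n)
        raise ValueError(
            "skin extrusion self-intersects (offset too large for local "
            f"curvature) near vertices {bad_vertices[:10].tolist()}")
    outer_surface = TriSurface(nodes.copy(), surface.faces + n, dict(surface.labels))
    return shell, outer_surface


# ---------------------------------------------------------------------------
# geodesics


def _geodesic_graph(surface: TriSurface):
    """Graph over vertices + edge midpoints with complete per-triangle
    connectivity, reducing the Dijkstra metric overestimate of pure edge
    graphs (documented at ~1-2 % on sphere benchmarks)."""
    v = surface.vertices
    edges = surface.edges(unique=True)
    n = len(v)
    mid_index = {tuple(e): n + i for i, e in enumerate(map(tuple, edges))}
    mids = 0.5 * (v[edges[:, 0]] + v[edges[:, 1]])
    pts = np.vstack([v, mids])

    rows, cols = [], []
    for tri in surface.faces:
        a, b, c = (int(x) for x in tri)
        m_ab = mid_index[tuple(sorted((a, b)))]
        m_bc = mid_index[tuple(sorted((b, c)))]
        m_ca = mid_index[tuple(sorted((c, a)))]
        nodes = [a, b, c, m_ab, m_bc, m_ca]
        for i in range(6):
            for j in range(i + 1, 6):
                rows.append(nodes[i])
                cols.append(nodes[j])
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    w = np.linalg.norm(pts[rows] - pts[cols], axis=1)
    m = len(pts)
    graph = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                       shape=(m, m)).tocsr()
    return graph


def geodesic_distance(surface: TriSurface, sources) -> np.ndarray:
    """Per-vertex geodesic distance from a set of source vertex ids.

    Shortest paths on the midpoint-refined triangle graph (Dijkstra).
    Unreachable vertices get ``+inf``.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    if sources.size == 0:
        raise ValueError("at least one source vertex required")
    if sources.min() < 0 or sources.max() >= surface.n_vertices:
        raise ValueError("source vertex id out of range")
    graph = _geodesic_graph(surface)
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    return dist[: surface.n_vertices]


# ---------------------------------------------------------------------------
# displacement interpolation


class PointLocationError(ValueError):
    """Query point not inside any tetrahedron."""


def _barycentric(mesh: TetMesh, points: np.ndarray, candidates: np.ndarray):
    """Barycentric coordinates of each point wrt each candidate tet.

    Returns array (n_points, n_candidates, 4)."""
    x = mesh.nodes
    t = mesh.tets[candidates]
    p0 = x[t[:, 0]]
    T = np.stack([x[t[:, 1]] - p0, x[t[:, 2]] - p0, x[t[:, 3]] - p0], axis=-1)
    rhs = points[:, None, :] - p0[None, :, :]
    sol = np.linalg.solve(
        np.broadcast_to(T[None], (len(points),) + T.shape), rhs[..., None]
    )[..., 0]
    lam0 = 1.0 - sol.sum(axis=-1, keepdims=True)
    return np.concatenate([lam0, sol], axis=-1)


def locate_points(mesh: TetMesh, points: np.ndarray, tol: float = 1e-9):
    """Find the containing tet and barycentric weights for each point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    tree = cKDTree(centroids)
    k = min(32, mesh.n_tets)
    _, neigh = tree.query(points, k=k)
    neigh = np.atleast_2d(neigh)
    elem = np.full(len(points), -1, dtype=np.int64)
    weights = np.zeros((len(points), 4))
    for i, p in enumerate(points):
        found = False
        for cand in (neigh[i], np.arange(mesh.n_tets)):
            lam = _barycentric(mesh, p[None], np.asarray(cand))[0]
            inside = np.flatnonzero((lam >= -tol).all(axis=1))
            if inside.size:
                j = inside[0]
                elem[i] = cand[j]
                weights[i] = lam[j]
                found = True
                break
        if not found:
            lam = _barycentric(mesh, p[None], np.arange(mesh.n_tets))[0]
            best = int(np.argmax(lam.min(axis=1)))
            raise PointLocationError(
                f"point {p.tolist()} lies outside the mesh; nearest element "
                f"{best} has min barycentric coordinate {lam[best].min():.3g}")
    return elem, weights


def deform_points(mesh: TetMesh, displacements: np.ndarray, points) -> np.ndarray:
    """Carry arbitrary points through a nodal displacement field.

    Each point is interpolated barycentrically inside its containing tet
    (exact for globally affine fields).
    """
    displacements = np.asarray(displacements, dtype=float).reshape(-1, 3)
    if len(displacements) != mesh.n_nodes:
        raise ValueError("displacement field size mismatch")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    elem, weights = locate_points(mesh, points)
    u = np.einsum("pk,pkd->pd", weights, displacements[mesh.tets[elem]])
    return points + u


# ---------------------------------------------------------------------------
# primitive meshes (fixtures for tests and phantoms)


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0.0, 0.0, 0.0)) -> TriSurface:
    """Geodesic sphere by repeated midpoint subdivision of an icosahedron."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(subdivisions):
        cache = {}
        verts_list = list(verts)

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=np.int64)
    return TriSurface(verts * radius + np.asarray(center, float), faces)
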