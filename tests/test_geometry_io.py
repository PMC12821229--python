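"""Surface/volume containers, STL + markups I/O, skin extrusion, geodesics,
and barycentric interpolation."""

import json

import numpy as np
import pytest

from mammosim.geometry_io import (
    LandmarkSet,
    PointLocationError,
    STLParseError,
    TetMesh,
    TriSurface,
    deform_points,
    extrude_skin,
    geodesic_distance,
    icosphere,
    read_markups,
    read_surface,
    write_markups,
    write_surface,
)

CUBE_ASCII_STL = """solid cube
facet normal 0 0 -1
 outer loop
  vertex 0 0 0
  vertex 1 1 0
  vertex 1 0 0
 endloop
endfacet
facet normal 0 0 -1
 outer loop
  vertex 0 0 0
  vertex 0 1 0
  vertex 1 1 0
 endloop
endfacet
facet normal 0 0 1
 outer loop
  vertex 0 0 1
  vertex 1 0 1
  vertex 1 1 1
 endloop
endfacet
facet normal 0 0 1
 outer loop
  vertex 0 0 1
  vertex 1 1 1
  vertex 0 1 1
 endloop
endfacet
facet normal 0 -1 0
 outer loop
  vertex 0 0 0
  vertex 1 0 0
  vertex 1 0 1
 endloop
endfacet
facet normal 0 -1 0
 outer loop
  vertex 0 0 0
  vertex 1 0 1
  vertex 0 0 1
 endloop
endfacet
facet normal 0 1 0
 outer loop
  vertex 0 1 0
  vertex 1 1 1
  vertex 1 1 0
 endloop
endfacet
facet normal 0 1 0
 outer loop
  vertex 0 1 0
  vertex 0 1 1
  vertex 1 1 1
 endloop
endfacet
facet normal -1 0 0
 outer loop
  vertex 0 0 0
  vertex 0 0 1
  vertex 0 1 1
 endloop
endfacet
facet normal -1 0 0
 outer loop
  vertex 0 0 0
  vertex 0 1 1
  vertex 0 1 0
 endloop
endfacet
facet normal 1 0 0
 outer loop
  vertex 1 0 0
  vertex 1 1 0
  vertex 1 1 1
 endloop
endfacet
facet normal 1 0 0
 outer loop
  vertex 1 0 0
  vertex 1 1 1
  vertex 1 0 1
 endloop
endfacet
endsolid cube
"""


@pytest.fixture
def cube_stl(tmp_path):
    path = tmp_path / "cube.stl"
    path.write_text(CUBE_ASCII_STL)
    return path


class TestSTL:
    def test_unit_cube_ascii(self, cube_stl):
        surf = read_surface(cube_stl, unit_scale=1.0)
        assert surf.n_vertices == 8  # welded
        assert surf.n_faces == 12
        assert surf.volume() == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_binary(self, cube_stl, tmp_path):
        surf = read_surface(cube_stl, unit_scale=1e-3)
        out = tmp_path / "out.stl"
        write_surface(out, surf, unit_scale=1e-3, binary=True)
        again = read_surface(out, unit_scale=1e-3)
        assert again.n_vertices == surf.n_vertices
        # max deviation < 1e-6 mm = 1e-9 m
        a = surf.vertices[np.lexsort(surf.vertices.T)]
        b = again.vertices[np.lexsort(again.vertices.T)]
        assert np.abs(a - b).max() < 1e-9

    def test_round_trip_ascii(self, tmp_path):
        sph = icosphere(radius=0.013, subdivisions=2)
        out = tmp_path / "s.stl"
        write_surface(out, sph, binary=False)
        again = read_surface(out)
        a = sph.vertices[np.lexsort(sph.vertices.T)]
        b = again.vertices[np.lexsort(again.vertices.T)]
        assert np.abs(a - b).max() < 1e-9

    def test_unit_scale(self, tmp_path):
        sph = icosphere(radius=1.0, subdivisions=1)  # bbox edge 2 in file units
        out = tmp_path / "s.stl"
        write_surface(out, sph, unit_scale=1.0)
        scaled = read_surface(out, unit_scale=1e-3)
        bbox = scaled.vertices.max(0) - scaled.vertices.min(0)
        np.testing.assert_allclose(bbox, 0.002, rtol=1e-6)

    def test_empty_file_error(self, tmp_path):
        path = tmp_path / "empty.stl"
        path.write_bytes(b"")
        with pytest.raises(STLParseError, match="byte offset"):
            read_surface(path)

    def test_truncated_binary_error(self, tmp_path):
        path = tmp_path / "trunc.stl"
        path.write_bytes(b"\0" * 80 + (100).to_bytes(4, "little") + b"\0" * 10)
        with pytest.raises(STLParseError, match="byte offset"):
            read_surface(path)

    def test_malformed_ascii_error(self, tmp_path):
        path = tmp_path / "bad.stl"
        path.write_text("solid x\nfacet normal 0 0 1\nouter loop\nvertex 1 2\n")
        with pytest.raises(STLParseError):
            read_surface(path)

    def test_outward_winding_after_load(self, tmp_path):
        sph = icosphere(radius=0.01, subdivisions=2)
        sph.faces = sph.faces[:, [0, 2, 1]]  # deliberately inverted
        out = tmp_path / "inv.stl"
        write_surface(out, sph)
        again = read_surface(out)
        assert again.volume() > 0


class TestMarkups:
    def test_single_point_mm_to_m(self, tmp_path):
        doc = {"markups": [{"coordinateSystem": "RAS",
                            "controlPoints": [{"label": "nipple", "position": [10, 20, 30]}]}]}
        path = tmp_path / "n.mrk.json"
        path.write_text(json.dumps(doc))
        marks = read_markups(path)
        np.testing.assert_allclose(marks["nipple"], [0.010, 0.020, 0.030])

    def test_lps_negates_xy(self, tmp_path):
        cp = [{"label": "p", "position": [10, 20, 30]}]
        for system, expected in (("RAS", [0.01, 0.02, 0.03]), ("LPS", [-0.01, -0.02, 0.03])):
            path = tmp_path / f"{system}.mrk.json"
            path.write_text(json.dumps(
                {"markups": [{"coordinateSystem": system, "controlPoints": cp}]}))
            np.testing.assert_allclose(read_markups(path)["p"], expected)

    def test_duplicate_labels_error(self, tmp_path):
        cp = [{"label": "p", "position": [1, 2, 3]}, {"label": "p", "position": [4, 5, 6]}]
        path = tmp_path / "d.mrk.json"
        path.write_text(json.dumps({"markups": [{"controlPoints": cp}]}))
        with pytest.raises(ValueError, match="duplicate"):
            read_markups(path)

    def test_missing_position_error(self, tmp_path):
        path = tmp_path / "m.mrk.json"
        path.write_text(json.dumps({"markups": [{"controlPoints": [{"label": "q"}]}]}))
        with pytest.raises(ValueError, match="control point 0"):
            read_markups(path)

    def test_write_read_round_trip(self, tmp_path):
        marks = LandmarkSet({"nipple_prone": np.array([0.01, -0.02, 0.035])})
        path = tmp_path / "w.mrk.json"
        write_markups(path, marks)
        again = read_markups(path)
        np.testing.assert_allclose(again["nipple_prone"], marks["nipple_prone"], atol=1e-12)

    def test_landmark_invariants(self):
        with pytest.raises(ValueError):
            LandmarkSet({"a": [np.nan, 0, 0]})


class TestExtrudeSkin:
    def test_flat_square_volume(self):
        # 10 x 10 mm square, thickness 1.5 mm -> 150 mm^3
        verts = np.array([[0, 0, 0], [0.01, 0, 0], [0.01, 0.01, 0], [0, 0.01, 0]])
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        shell, outer = extrude_skin(TriSurface(verts, faces), 0.0015)
        assert shell.volume() * 1e9 == pytest.approx(150.0, abs=1e-9 * 1e9 * 1e-9)
        assert np.all(shell.volumes() > 0)
        assert set(shell.regions) == {"skin"}
        np.testing.assert_allclose(outer.vertices[outer.faces].reshape(-1, 3)[:, 2].min(), 0.0015)

    def test_sphere_shell_volume(self):
        r, t = 0.050, 0.0015
        sph = icosphere(radius=r, subdivisions=3)  # ~6 mm edges
        shell, _ = extrude_skin(sph, t)
        expected = 4.0 / 3.0 * np.pi * ((r + t) ** 3 - r ** 3)
        assert shell.volume() == pytest.approx(expected, rel=0.02)

    def test_zero_thickness_error(self):
        sph = icosphere(radius=0.05, subdivisions=1)
        with pytest.raises(ValueError):
            extrude_skin(sph, 0.0)

    def test_excess_curvature_error(self):
        sph = icosphere(radius=0.001, subdivisions=1)
        with pytest.raises(ValueError, match="vertices"):
            # inward-facing normals force inverted prisms
            inv = TriSurface(sph.vertices, sph.faces[:, [0, 2, 1]])
            extrude_skin(inv, 0.0015)

    def test_area_times_thickness_first_order(self):
        # curvature correction ~ t/r, so use a gentle curvature (r >> 10 t)
        r, t = 0.30, 0.0015
        sph = icosphere(radius=r, subdivisions=3)
        shell, _ = extrude_skin(sph, t)
        assert shell.volume() == pytest.approx(sph.area() * t, rel=0.02)


class TestGeodesics:
    def test_source_to_itself(self):
        sph = icosphere(subdivisions=1)
        d = geodesic_distance(sph, [5])
        assert d[5] == 0.0
        assert np.all(d >= 0)

    def test_straight_chain(self):
        # path graph embedded as a degenerate-free triangle strip
        n = 6
        verts = []
        for i in range(n):
            verts.append([i * 1.0, 0.0, 0.0])
            verts.append([i * 1.0, 1.0, 0.0])
        faces = []
        for i in range(n - 1):
            a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
            faces += [[a, c, b], [b, c, d]]
        surf = TriSurface(np.array(verts, float), np.array(faces))
        d = geodesic_distance(surf, [0])
        assert d[2 * (n - 1)] == pytest.approx(n - 1.0, rel=1e-9)

    def test_sphere_antipode(self):
        sph = icosphere(radius=1.0, subdivisions=4)
        pole = int(np.argmax(sph.vertices[:, 2]))
        antipode = int(np.argmin(sph.vertices[:, 2]))
        d = geodesic_distance(sph, [pole])
        assert d[antipode] == pytest.approx(np.pi, rel=0.03)

    def test_symmetry_small_mesh(self):
        sph = icosphere(subdivisions=1)  # 42 vertices
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, b = rng.integers(0, sph.n_vertices, 2)
            da = geodesic_distance(sph, [int(a)])
            db = geodesic_distance(sph, [int(b)])
            assert da[b] == pytest.approx(db[a], rel=1e-9)

    def test_disconnected_inf(self):
        s1 = icosphere(subdivisions=1)
        s2 = icosphere(subdivisions=1, center=(5, 0, 0))
        both = TriSurface(np.vstack([s1.vertices, s2.vertices]),
                          np.vstack([s1.faces, s2.faces + s1.n_vertices]))
        d = geodesic_distance(both, [0])
        assert np.isinf(d[s1.n_vertices])

    def test_empty_sources_error(self):
        with pytest.raises(ValueError):
            geodesic_distance(icosphere(subdivisions=1), [])


def brick_tet_mesh(n=2, size=0.01):
    """Small structured brick for interpolation tests."""
    from mammosim.phantom import _kuhn_tets

    xs = np.linspace(0, size, n + 1)
    grid = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    idx = np.arange(np.prod(shape)).reshape(shape)
    nodes = grid.reshape(-1, 3)
    ci, cj, ck = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    offsets = [(b & 1, (b >> 1) & 1, (b >> 2) & 1) for b in range(8)]
    corners = np.stack([idx[ci + dx, cj + dy, ck + dz] for dx, dy, dz in offsets], axis=1)
    tets = _kuhn_tets(corners)
    mesh = TetMesh(nodes, tets, regions=np.full(len(tets), "breast"))
    flip = mesh.volumes() < 0
    mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]
    return mesh


class TestDeformPoints:
    def test_node_coincident(self):
        mesh = brick_tet_mesh()
        rng = np.random.default_rng(1)
        disp = 1e-4 * rng.standard_normal((mesh.n_nodes, 3))
        i = 13
        out = deform_points(mesh, disp, mesh.nodes[i])
        np.testing.assert_allclose(out[0], mesh.nodes[i] + disp[i], atol=1e-15)

    def test_affine_exact(self):
        mesh = brick_tet_mesh()
        rng = np.random.default_rng(2)
        A = 0.1 * rng.standard_normal((3, 3))
        b = 1e-3 * rng.standard_normal(3)
        disp = mesh.nodes @ A.T + b
        pts = mesh.nodes.min(0) + rng.random((20, 3)) * (mesh.nodes.max(0) - mesh.nodes.min(0))
        out = deform_points(mesh, disp, pts)
        np.testing.assert_allclose(out, pts + pts @ A.T + b, atol=1e-12)

    def test_matches_per_element_shape_functions(self):
        # brute-force oracle: explicit barycentric solve in the containing tet
        mesh = brick_tet_mesh(n=3)
        rng = np.random.default_rng(3)
        disp = 1e-3 * np.sin(300 * mesh.nodes) + 1e-4 * rng.standard_normal((mesh.n_nodes, 3))
        pts = 0.001 + rng.random((10, 3)) * 0.008
        out = deform_points(mesh, disp, pts)
        for p, o in zip(pts, out):
            found = None
            for e in range(mesh.n_tets):
                xs = mesh.nodes[mesh.tets[e]]
                M = np.vstack([xs.T, np.ones(4)])
                lam = np.linalg.solve(M, np.append(p, 1.0))
                if np.all(lam >= -1e-9):
                    found = lam @ disp[mesh.tets[e]]
                    break
            assert found is not None
            np.testing.assert_allclose(o, p + found, atol=1e-12)

    def test_outside_error(self):
        mesh = brick_tet_mesh()
        with pytest.raises(PointLocationError, match="nearest"):
            deform_points(mesh, np.zeros((mesh.n_nodes, 3)), [[1.0, 1.0, 1.0]])


class TestTetMesh:
    def test_invariants(self):
        mesh = brick_tet_mesh()
        assert np.all(mesh.volumes() > 0)
        with pytest.raises(ValueError, match="nipple"):
            TetMesh(mesh.nodes, mesh.tets, mesh.regions, {"nipple": np.array([0, 1])})

    def test_boundary_faces_closed(self):
        mesh = brick_tet_mesh()
        surf = mesh.surface()
        # boundary of a brick encloses the brick volume
        assert surf.volume() == pytest.approx(mesh.volume(), rel=1e-12)

    def test_volume_centroid_of_sphere(self):
        c = icosphere(0.0075, 2, center=(0.01, -0.02, 0.003)).volume_centroid()
        np.testing.assert_allclose(c, [0.01, -0.02, 0.003], atol=1e-12)

    def test_volume_centroid_open_surface_error(self):
        flat = TriSurface(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                          np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="closed"):
            flat.volume_centroid()

    def test_degenerate_triangle_check(self):
        surf = TriSurface(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]), np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="degenerate"):
            surf.check()
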