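"""Rigid prone/supine alignment.

Detects the flat intermammary patch on the prone surface, transfers its
boundary to the supine surface through nipple-centered geodesic radii, runs
point-based rigid registration (ICP with a Kabsch inner step), and applies
the optional cranial-caudal nipple leveling shift.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from mammosim.geometry_io import LandmarkSet, TriSurface, geodesic_distance

__all__ = [
    "RigidTransform",
    "detect_intermammary",
    "transfer_boundary",
    "rigid_register",
    "apply_transform",
    "align_surfaces",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-9 or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix().tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            m = np.asarray(json.load(fh)["matrix"], dtype=float)
        return cls(m[:3, :3], m[:3, 3])


def apply_transform(t: RigidTransform, geometry):
    """Apply a rigid motion to points (n, 3), a `TriSurface`, or a
    `LandmarkSet`; distances are preserved to round-off."""
    if isinstance(geometry, TriSurface):
        return TriSurface(apply_transform(t, geometry.vertices), geometry.faces.copy(),
                          dict(geometry.labels))
    if isinstance(geometry, LandmarkSet):
        return LandmarkSet({k: apply_transform(t, v[None])[0] for k, v in geometry.points.items()},
                           frame=geometry.frame)
    pts = np.asarray(geometry, dtype=float)
    return pts @ t.rotation.T + t.translation


# ---------------------------------------------------------------------------
# intermammary patch


def _vertex_adjacency(surface: TriSurface):
    adj = [[] for _ in range(surface.n_vertices)]
    for a, b in surface.edges():
        adj[a].append(b)
        adj[b].append(a)
    return adj


def detect_intermammary(prone: TriSurface, nipples: LandmarkSet,
                        flat_threshold_deg: float = 10.0) -> np.ndarray:
    """Flat connected vertex patch between the two breasts.

    Region-grows from the vertex nearest the midpoint of the nipples,
    accepting neighbours whose normal deviates from the running patch mean
    normal by less than the threshold.  Returns vertex ids.
    """
    nipple_names = [n for n in nipples.names() if "nipple" in n.lower()]
    if len(nipple_names) < 2:
        raise ValueError("bilateral surface with two nipple landmarks required")
    p1 = nipples[nipple_names[0]]
    p2 = nipples[nipple_names[1]]
    mid = 0.5 * (p1 + p2)
    normals = prone.vertex_normals()
    # the midpoint floats above the chest: seed on the surface point between
    # the breasts in the chest plane (x, z), not in 3-D
    tree = cKDTree(prone.vertices[:, [0, 2]])
    _, cands = tree.query(mid[[0, 2]], k=min(8, prone.n_vertices))
    cands = np.atleast_1d(cands)
    seed = int(cands[np.argmin(prone.vertices[cands, 1])])
    cos_thresh = np.cos(np.deg2rad(flat_threshold_deg))

    adj = _vertex_adjacency(prone)
    seed_star = [seed] + adj[seed]
    star_dots = normals[seed_star] @ normals[seed]
    if np.any(star_dots < cos_thresh):
        raise ValueError(
            "no flat region at the seed between the nipples; increase the "
            f"flatness threshold (currently {flat_threshold_deg:g} degrees)")

    patch = {seed}
    mean_n = normals[seed].copy()
    queue = deque(adj[seed])
    seen = set(patch) | set(adj[seed])
    while queue:
        v = queue.popleft()
        if normals[v] @ (mean_n / np.linalg.norm(mean_n)) >= cos_thresh:
            patch.add(v)
            mean_n += normals[v]
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
    if len(patch) < 3:
        raise ValueError("flat region degenerate; increase the flatness threshold")
    return np.array(sorted(patch), dtype=np.int64)


def transfer_boundary(supine: TriSurface, supine_nipples: LandmarkSet,
                      radii: dict) -> np.ndarray:
    """Transfer the prone intermammary boundary to the supine surface.

    ``radii`` maps nipple landmark names to the prone geodesic distance from
    that nipple to the intermammary boundary.  The returned patch holds the
    vertices farther than each radius from the corresponding nipple,
    restricted to the band between the two nipples (x between them).
    Radius 0 returns the whole band.
    """
    tree = cKDTree(supine.vertices)
    names = list(radii)
    if len(names) < 2:
        raise ValueError("radii for both nipples required")
    dists = {}
    for name in names:
        vid = int(tree.query(supine_nipples[name])[1])
        dists[name] = geodesic_distance(supine, [vid])
        reachable = dists[name][np.isfinite(dists[name])]
        if radii[name] > reachable.max():
            raise ValueError(
                f"radius {radii[name]:g} m from {name} exceeds the surface "
                f"extent ({reachable.max():g} m)")
    x = supine.vertices[:, 0]
    x_lo = min(supine_nipples[n][0] for n in names)
    x_hi = max(supine_nipples[n][0] for n in names)
    band = (x >= x_lo) & (x <= x_hi)
    mask = band.copy()
    for name in names:
        mask &= dists[name] >= radii[name]
    patch = np.flatnonzero(mask)
    if patch.size == 0:
        raise ValueError("transferred boundary radius leaves an empty patch")
    return patch


# ---------------------------------------------------------------------------
# rigid registration


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping paired source points onto target."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:
        R[:, 2] *= -1
    return R


def rigid_register(source_points, target_points, *, level_nipples: bool = False,
                   nipples: dict | None = None, max_iterations: int = 100,
                   tol: float = 1e-6, init: RigidTransform | None = None,
                   trim_fraction: float = 0.2, residual_history: list | None = None):
    """ICP rigid registration of a source patch onto a target patch.

    Nearest-vertex correspondences, Kabsch inner step, centroid +
    principal-axes initialization (or an explicit ``init`` transform, e.g.
    from paired nipple landmarks, which disambiguates the in-plane symmetry
    of flat patches); iterates until the mean correspondence distance
    changes by less than ``tol`` metres.  With ``level_nipples`` a final
    z-only translation equalizes the source and target nipple z
    (cranial-caudal leveling); ``nipples`` must then provide ``source`` and
    ``target`` points.  Returns ``(RigidTransform, mean_residual_m)``.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("at least 3 points per patch required")
    for pts, name in ((src, "source"), (tgt, "target")):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] < 1e-12 * max(s[0], 1e-300):
            raise ValueError(f"{name} patch is collinear/degenerate")

    tree = cKDTree(tgt)
    if init is not None:
        transform = init
    else:
        # principal-axes initialization; axis signs are ambiguous (especially
        # on near-planar patches), so pick the proper-rotation hypothesis
        # with the lowest initial correspondence residual
        As, At = _principal_axes(src), _principal_axes(tgt)
        best_init = None
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            S = np.diag([sx, sy, sx * sy])  # keeps det = +1
            R0 = At @ S @ As.T
            cand = RigidTransform(R0, tgt.mean(axis=0) - R0 @ src.mean(axis=0))
            r = float(tree.query(apply_transform(cand, src))[0].mean())
            if best_init is None or r < best_init[0]:
                best_init = (r, cand)
        transform = best_init[1]
    prev = np.inf
    residual = np.inf
    for _ in range(max_iterations):
        moved = apply_transform(transform, src)
        d, idx = tree.query(moved)
        # trimmed ICP: discard the worst correspondences so non-overlapping
        # patch boundaries do not bias the fit
        if trim_fraction > 0 and len(src) >= 10:
            keep = d <= np.quantile(d, 1.0 - trim_fraction)
        else:
            keep = slice(None)
        residual = float(d.mean())
        if residual_history is not None:
            residual_history.append(residual)
        step = _kabsch(src[keep], tgt[idx[keep]])
        transform = step
        if abs(prev - residual) < tol:
            break
        prev = residual
    else:
        warnings.warn(f"ICP did not converge in {max_iterations} iterations "
                      f"(residual {residual:g} m); returning best transform")

    if level_nipples:
        if not nipples or "source" not in nipples or "target" not in nipples:
            raise ValueError("level_nipples requires source and target nipple points")
        src_nip = apply_transform(transform, np.asarray(nipples["source"], float)[None])[0]
        dz = np.asarray(nipples["target"], float)[2] - src_nip[2]
        transform = RigidTransform(transform.rotation,
                                   transform.translation + np.array([0.0, 0.0, dz]))
    return transform, residual


def align_surfaces(prone: TriSurface, prone_marks: LandmarkSet,
                   supine: TriSurface, supine_marks: LandmarkSet,
                   level_nipples: bool = False,
                   flat_threshold_deg: float = 10.0):
    """Full rigid-alignment flow: intermammary patch detection on the prone
    surface, geodesic-radius boundary transfer to the supine surface, and
    ICP registration initialized from the paired nipple landmarks.

    Returns ``(RigidTransform, mean_residual_m)`` mapping prone -> supine.
    """
    nip_names = sorted(n for n in prone_marks.names() if "nipple" in n.lower())
    if len(nip_names) < 2:
        raise ValueError("both nipple landmarks required")
    patch = detect_intermammary(prone, prone_marks, flat_threshold_deg)
    tree = cKDTree(prone.vertices)
    radii = {}
    for name in nip_names[:2]:
        vid = int(tree.query(prone_marks[name])[1])
        d = geodesic_distance(prone, [vid])
        radii[name] = float(d[patch].min())
    supine_patch = transfer_boundary(supine, supine_marks, radii)
    src = prone.vertices[patch]
    tgt = supine.vertices[supine_patch]
    # paired-landmark initialization breaks the in-plane symmetry of the
    # flat patch: nipples + patch centroids give three exact correspondences
    init = _kabsch(
        np.vstack([[prone_marks[n] for n in nip_names[:2]], src.mean(axis=0)[None]]),
        np.vstack([[supine_marks[n] for n in nip_names[:2]], tgt.mean(axis=0)[None]]))
    nipples = None
    if level_nipples:
        nipples = {"source": prone_marks[nip_names[0]],
                   "target": supine_marks[nip_names[0]]}
    return rigid_register(src, tgt, init=init, level_nipples=level_nipples,
                          nipples=nipples)
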