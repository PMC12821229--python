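"""Tumor-localization accuracy metrics and the machine-readable report.

Two metrics: the Euclidean distance between estimated and reference supine
tumor centroids, and the distance between their closest-point projections
onto the deformed skin surface (incision-planning proxy).  Both are
reported in millimetres.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json

import numpy as np

from mammosim.geometry_io import TriSurface

__all__ = [
    "EvaluationReport",
    "tumor_distance",
    "tumor_skin_projection_distance",
    "closest_point_on_surface",
]


@dataclass
class EvaluationReport:
    tumor_distance_mm: float
    tumor_skin_projection_distance_mm: float
    t_star: float
    nipple_residual_mm: float
    provenance: dict

    def __post_init__(self):
        for v in (self.tumor_distance_mm, self.tumor_skin_projection_distance_mm,
                  self.nipple_residual_mm):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError("distances must be finite and non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def tumor_distance(estimated, reference) -> float:
    """Euclidean distance between tumor centroids, in mm (inputs in metres)."""
    estimated = np.asarray(estimated, dtype=float).reshape(3)
    reference = np.asarray(reference, dtype=float).reshape(3)
    if not (np.all(np.isfinite(estimated)) and np.all(np.isfinite(reference))):
        raise ValueError("centroids must be finite")
    return float(np.linalg.norm(estimated - reference) * 1000.0)


def closest_point_on_surface(surface: TriSurface, point) -> np.ndarray:
    """Closest point on a triangulated surface (exact point-to-triangle
    minimization over all facets, vectorized)."""
    if surface.n_faces == 0:
        raise ValueError("empty surface")
    p = np.asarray(point, dtype=float).reshape(3)
    v = surface.vertices
    tri = surface.faces
    a, b, c = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    # Ericson-style closest point on triangle, batched over facets
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def fill(mask, pts):
        sel = mask & ~done
        result[sel] = pts[sel] if pts.ndim > 1 else pts
        done[sel] = True

    fill((d1 <= 0) & (d2 <= 0), np.broadcast_to(a, a.shape) * 1.0)
    fill((d3 >= 0) & (d4 <= d3), np.broadcast_to(b, b.shape) * 1.0)
    fill((d6 >= 0) & (d5 <= d6), np.broadcast_to(c, c.shape) * 1.0)

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    fill((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    fill((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    fill((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc[:, None] * (c - b))

    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    w_b = vb / denom
    w_c = vc / denom
    interior = a + w_b[:, None] * ab + w_c[:, None] * ac
    result[~done] = interior[~done]

    d = np.linalg.norm(result - p, axis=1)
    return result[int(np.argmin(d))]


def tumor_skin_projection_distance(estimated, reference, skin: TriSurface) -> float:
    """Distance (mm) between the closest-skin-point projections of the
    estimated and reference tumor centroids on the deformed outer surface."""
    proj_est = closest_point_on_surface(skin, estimated)
    proj_ref = closest_point_on_surface(skin, reference)
    return float(np.linalg.norm(proj_est - proj_ref) * 1000.0)
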