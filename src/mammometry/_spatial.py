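"""Nearest-point-on-mesh queries.

A cKDTree over triangle centroids proposes candidate faces; the exact
closest point on each candidate triangle is then computed with the
standard Voronoi-region case analysis, and the best candidate wins.
Queried points in this package are always close to the surface (sticker
centroids, guideline intersections), so a generous candidate count is
both safe and cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(tri: np.ndarray, p: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` on each triangle, with barycentric coordinates.

    ``tri`` is (m, 3, 3); returns points (m, 3) and barycentric (m, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
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
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    m = len(tri)
    bary = np.zeros((m, 3))
    done = np.zeros(m, dtype=bool)

    def settle(mask, b1, b2, b3):
        mask = mask & ~done
        bary[mask, 0] = b1 if np.isscalar(b1) else b1[mask]
        bary[mask, 1] = b2 if np.isscalar(b2) else b2[mask]
        bary[mask, 2] = b3 if np.isscalar(b3) else b3[mask]
        done[mask] = True

    settle((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)                    # vertex A
    settle((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)                   # vertex B
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1.0 - v_ab, v_ab, 0.0)  # edge AB
    settle((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)                   # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1.0 - w_ac, 0.0, w_ac)  # edge AC
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           0.0, 1.0 - w_bc, w_bc)                                   # edge BC
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)          # interior
    v = vb / denom
    w = vc / denom
    settle(np.ones(m, dtype=bool), 1.0 - v - w, v, w)

    points = np.einsum("ik,ikj->ij", bary, tri)
    return points, bary


class NearestSurface:
    """Reusable nearest-surface-point queries on one triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray,
                 candidates: int = 48):
        self.V = np.asarray(vertices, dtype=float)
        self.F = np.asarray(faces, dtype=np.int64)
        self.tri = self.V[self.F]
        self.k = min(candidates, len(self.F))
        self._tree = cKDTree(self.tri.mean(axis=1))

    def query(self, points: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest surface points: (positions, face indices, barycentric)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        out_p = np.empty_like(points)
        out_f = np.empty(len(points), dtype=np.int64)
        out_b = np.empty((len(points), 3))
        for i, p in enumerate(points):
            faces = cand[i]
            cp, bary = closest_point_on_triangles(self.tri[faces], p)
            dist = np.linalg.norm(cp - p, axis=1)
            # when the point sits on a shared edge or vertex several faces
            # tie; take the lowest face index so the choice is stable under
            # rigid motion of the mesh
            eligible = np.nonzero(dist <= dist.min() + 1e-9)[0]
            best = int(eligible[np.argmin(faces[eligible])])
            out_p[i] = cp[best]
            out_f[i] = faces[best]
            out_b[i] = np.clip(bary[best], 0.0, 1.0)
            out_b[i] /= out_b[i].sum()
        return out_p, out_f, out_b
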