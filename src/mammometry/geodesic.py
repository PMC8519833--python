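"""Discrete geodesics: edge-graph shortest paths with Steiner subdivision.

The over-surface distance between two :class:`~mammometry.mesh_io.SurfacePoint`
objects is the digital analog of a tape measure laid on the skin.  The
algorithm:

1. subdivide every mesh edge with a fixed number of Steiner points
   (default 3 per edge);
2. connect all vertex/Steiner nodes on the boundary of each face with
   straight segments (the complete intra-face graph);
3. run Dijkstra on the resulting graph (scipy's sparse csgraph);
4. shorten the recovered polyline by iteratively sliding each interior
   node along its supporting mesh edge (red-black coordinate descent with
   a vectorized ternary search).

Step 4 removes the angular quantization of the node graph: on a planar
mesh the straightened path converges to the exact straight line, and on
curved meshes the path remains on the surface because each segment stays
inside the face that produced it.  Query endpoints become temporary graph
nodes wired to every node of their containing face.

Distances are exactly symmetric because endpoint pairs are put in a
canonical order before the query.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .errors import MeasurementError
from .mesh_io import SurfacePoint, TexturedMesh

DEFAULT_STEINER_PER_EDGE = 3


class SurfaceGeodesics:
    """Reusable geodesic solver for one mesh.

    Building the node graph is the expensive step; reuse one instance for
    all queries on the same mesh.
    """

    def __init__(self, mesh: TexturedMesh | tuple[np.ndarray, np.ndarray],
                 steiner_per_edge: int = DEFAULT_STEINER_PER_EDGE):
        if isinstance(mesh, TexturedMesh):
            V, F = mesh.vertices, mesh.faces
        else:
            V, F = mesh
        self.V = np.ascontiguousarray(V, dtype=np.float64)
        self.F = np.ascontiguousarray(F, dtype=np.int64)
        self.s = int(steiner_per_edge)
        if self.s < 0:
            raise ValueError("steiner_per_edge must be >= 0")
        self._build()

    def _build(self) -> None:
        V, F, s = self.V, self.F, self.s
        n, m = len(V), len(F)
        e_all = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
        E, inv = np.unique(np.sort(e_all, axis=1), axis=0, return_inverse=True)
        ne = len(E)
        if s > 0:
            fr = (np.arange(1, s + 1) / (s + 1))[None, :, None]
            steiner = V[E[:, 0]][:, None, :] * (1 - fr) + V[E[:, 1]][:, None, :] * fr
            nodes = np.vstack([V, steiner.reshape(-1, 3)])
        else:
            nodes = V.copy()
        # supporting edge per node; a vertex node is pinned (lo == hi)
        node_edge = np.empty((len(nodes), 2), dtype=np.int64)
        node_edge[:n, 0] = node_edge[:n, 1] = np.arange(n)
        if s > 0:
            node_edge[n:] = np.repeat(E, s, axis=0)

        fe = inv.reshape(3, m).T  # edge ids per face in corner order
        K = 3 + 3 * s
        ids = np.empty((m, K), dtype=np.int64)
        ids[:, :3] = F
        for k in range(3):
            ids[:, 3 + k * s: 3 + (k + 1) * s] = (n + fe[:, k][:, None] * s
                                                  + np.arange(s)[None, :])
        iu, ju = np.triu_indices(K, 1)
        I = ids[:, iu].ravel()
        J = ids[:, ju].ravel()
        lo = np.minimum(I, J)
        hi = np.maximum(I, J)
        _, keep = np.unique(lo * len(nodes) + hi, return_index=True)
        self._gi = lo[keep]
        self._gj = hi[keep]
        self._gw = np.linalg.norm(nodes[self._gi] - nodes[self._gj], axis=1)
        self.nodes = nodes
        self.node_edge = node_edge
        self.face_nodes = ids
        self.n_base = len(nodes)

    # ------------------------------------------------------------------ queries

    def position(self, p: SurfacePoint) -> np.ndarray:
        if not 0 <= p.face_index < len(self.F):
            raise MeasurementError(f"surface point face {p.face_index} out of range")
        return np.asarray(p.barycentric, float) @ self.V[self.F[p.face_index]]

    def distance(self, a: SurfacePoint, b: SurfacePoint,
                 with_path: bool = True) -> tuple[float, np.ndarray]:
        """Geodesic length (cm) and on-surface polyline between two points."""
        # canonical endpoint order makes d(a, b) and d(b, a) bit-identical
        ka = (a.face_index, tuple(a.barycentric))
        kb = (b.face_index, tuple(b.barycentric))
        if kb < ka:
            length, path = self.distance(b, a, with_path=with_path)
            return length, path[::-1].copy()
        results = self.distances_from(a, [b], with_paths=with_path)
        return results[0]

    def distances_from(self, source: SurfacePoint, targets: list[SurfacePoint],
                       with_paths: bool = True) -> list[tuple[float, np.ndarray]]:
        """One Dijkstra run from ``source`` to several targets."""
        src_pos = self.position(source)
        tgt_pos = [self.position(t) for t in targets]
        N = self.n_base
        nt = len(targets)
        all_nodes = np.vstack([self.nodes, src_pos[None]] + [p[None] for p in tgt_pos])

        extra_i: list[np.ndarray] = []
        extra_j: list[np.ndarray] = []
        extra_w: list[np.ndarray] = []

        def wire(temp_id: int, pos: np.ndarray, face: int) -> None:
            fn = self.face_nodes[face]
            extra_i.append(np.full(len(fn), temp_id))
            extra_j.append(fn)
            extra_w.append(np.linalg.norm(self.nodes[fn] - pos, axis=1))

        wire(N, src_pos, source.face_index)
        for k, (t, p) in enumerate(zip(targets, tgt_pos)):
            wire(N + 1 + k, p, t.face_index)
            if t.face_index == source.face_index:
                extra_i.append(np.array([N]))
                extra_j.append(np.array([N + 1 + k]))
                extra_w.append(np.array([np.linalg.norm(p - src_pos)]))

        gi = np.concatenate([self._gi] + extra_i)
        gj = np.concatenate([self._gj] + extra_j)
        gw = np.concatenate([self._gw] + extra_w)
        graph = sp.csr_matrix((gw, (gi, gj)), shape=(N + 1 + nt, N + 1 + nt))
        dist, pred = dijkstra(graph, directed=False, indices=N,
                              return_predecessors=True)

        out: list[tuple[float, np.ndarray]] = []
        for k in range(nt):
            tid = N + 1 + k
            if not np.isfinite(dist[tid]):
                raise MeasurementError(
                    "surface points lie on different connected components "
                    "(was the crop too aggressive?)")
            chain = [tid]
            while chain[-1] != N:
                chain.append(int(pred[chain[-1]]))
            chain.reverse()
            pts = all_nodes[chain]
            interior = np.array(chain[1:-1], dtype=np.int64)
            edges = np.zeros((len(pts), 2), dtype=np.int64)
            if len(interior):
                edges[1:-1] = self.node_edge[interior]
            path = _straighten(self.V, pts, edges)
            length = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
            out.append((length, path if with_paths else path[[0, -1]]))
        return out


def _straighten(V: np.ndarray, pts: np.ndarray, edges: np.ndarray,
                sweeps: int = 60, tern_iters: int = 30,
                rel_tol: float = 1e-9) -> np.ndarray:
    """Slide interior path points along their supporting edges to shorten.

    Red-black (odd/even) Gauss-Seidel sweeps; each update is the 1D convex
    problem min_t |A - p(t)| + |B - p(t)| on the segment, solved by a
    vectorized ternary search.  Points pinned at mesh vertices (or the two
    endpoints) do not move.  Sweeps stop early once the total length
    improvement per sweep falls below ``rel_tol``.
    """
    P = pts.copy()
    k = len(P)
    if k < 3:
        return P
    movable = edges[:, 0] != edges[:, 1]
    movable[0] = movable[-1] = False
    if not movable.any():
        return P
    A0 = V[edges[:, 0]]
    Ed = V[edges[:, 1]] - V[edges[:, 0]]
    index = np.arange(k)

    def seglen(pts: np.ndarray) -> float:
        d = np.diff(pts, axis=0)
        return float(np.sqrt(np.einsum("ij,ij->i", d, d)).sum())

    prev_len = seglen(P)
    parities = [index[movable & (index % 2 == p)] for p in (1, 0)]
    for _ in range(sweeps):
        for idx in parities:
            if len(idx) == 0:
                continue
            A = P[idx - 1]
            B = P[idx + 1]
            a0 = A0[idx]
            ed = Ed[idx]
            lo = np.zeros(len(idx))
            hi = np.ones(len(idx))
            for _ in range(tern_iters):
                t1 = lo + (hi - lo) / 3
                t2 = hi - (hi - lo) / 3
                p1 = a0 + t1[:, None] * ed
                p2 = a0 + t2[:, None] * ed
                d1a = A - p1
                d1b = B - p1
                d2a = A - p2
                d2b = B - p2
                f1 = (np.sqrt(np.einsum("ij,ij->i", d1a, d1a))
                      + np.sqrt(np.einsum("ij,ij->i", d1b, d1b)))
                f2 = (np.sqrt(np.einsum("ij,ij->i", d2a, d2a))
                      + np.sqrt(np.einsum("ij,ij->i", d2b, d2b)))
                first = f1 < f2
                hi = np.where(first, t2, hi)
                lo = np.where(first, lo, t1)
            P[idx] = a0 + 0.5 * (lo + hi)[:, None] * ed
        cur_len = seglen(P)
        if prev_len - cur_len < rel_tol * max(cur_len, 1e-12):
            break
        prev_len = cur_len
    return P
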