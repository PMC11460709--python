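"""Triangle-mesh spatial queries: segment intersection, containment, distance.

A uniform voxel hash over triangle bounding boxes provides the broad phase;
the narrow phase is a vectorized Moller-Trumbore segment/triangle test.
Containment uses ray-crossing parity along a fixed non-axis-aligned
direction (marching-cubes surfaces have many axis-aligned features, so an
axis ray would be degenerate).  Point-to-surface distance is an exact
point-triangle distance, brute-forced in chunks -- simple and adequate for
the mesh sizes this pipeline produces.

All coordinates in mm.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TriangleCollider", "point_mesh_distance"]

_RAY_DIR = np.array([0.8017837257372732, 0.5345224838248488, 0.2672612419124244])


class TriangleCollider:
    """Static triangle set with a voxel-hash broad phase.

    Parameters
    ----------
    triangles : (m, 3, 3) float array
        Triangle vertices, mm.
    tags : (m,) int array, optional
        Per-triangle tag (e.g. region code) returned with hits.
    cell_size : float, optional
        Hash cell edge; defaults to twice the median triangle extent.
    """

    def __init__(self, triangles: np.ndarray, tags: np.ndarray | None = None,
                 cell_size: float | None = None):
        tri = np.asarray(triangles, dtype=float)
        if tri.ndim != 3 or tri.shape[1:] != (3, 3):
            raise ValueError("triangles must be (m, 3, 3)")
        self.triangles = tri
        self.tags = (np.zeros(len(tri), dtype=np.int64) if tags is None
                     else np.asarray(tags, dtype=np.int64))
        lo = tri.min(axis=1)
        hi = tri.max(axis=1)
        self.bounds = np.array([lo.min(axis=0), hi.max(axis=0)])
        if cell_size is None:
            ext = np.median(hi - lo)
            cell_size = max(2.0 * float(ext), 1e-3)
        self.cell = float(cell_size)
        self._hash: dict[tuple[int, int, int], list[int]] = {}
        ilo = np.floor((lo - self.bounds[0]) / self.cell).astype(np.int64)
        ihi = np.floor((hi - self.bounds[0]) / self.cell).astype(np.int64)
        for t in range(len(tri)):
            for i in range(ilo[t, 0], ihi[t, 0] + 1):
                for j in range(ilo[t, 1], ihi[t, 1] + 1):
                    for k in range(ilo[t, 2], ihi[t, 2] + 1):
                        self._hash.setdefault((i, j, k), []).append(t)
        # precompute edges for Moller-Trumbore
        self._e1 = tri[:, 1] - tri[:, 0]
        self._e2 = tri[:, 2] - tri[:, 0]
        self._v0 = tri[:, 0]

    # -------------------------------------------------------------- broad
    def _cells_of_aabb(self, lo: np.ndarray, hi: np.ndarray):
        ilo = np.floor((lo - self.bounds[0]) / self.cell).astype(np.int64)
        ihi = np.floor((hi - self.bounds[0]) / self.cell).astype(np.int64)
        for i in range(ilo[0], ihi[0] + 1):
            for j in range(ilo[1], ihi[1] + 1):
                for k in range(ilo[2], ihi[2] + 1):
                    cell = self._hash.get((i, j, k))
                    if cell:
                        yield cell

    def _candidates(self, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
        lo = np.minimum(p0, p1)
        hi = np.maximum(p0, p1)
        out: list[int] = []
        for cell in self._cells_of_aabb(lo, hi):
            out.extend(cell)
        if not out:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.asarray(out, dtype=np.int64))

    # ------------------------------------------------------------- narrow
    def _segment_hits_one(self, p0: np.ndarray, p1: np.ndarray, cand: np.ndarray,
                          eps: float = 1e-12):
        """Parametric hit positions t in (0, 1] of one segment against candidates."""
        d = p1 - p0
        e1 = self._e1[cand]
        e2 = self._e2[cand]
        v0 = self._v0[cand]
        h = np.cross(np.broadcast_to(d, e2.shape), e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > eps
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = p0 - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * np.einsum("ij,ij->i", np.broadcast_to(d, q.shape), q)
        t = f * np.einsum("ij,ij->i", e2, q)
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9) & (t > 1e-9) & (t <= 1.0 + 1e-12)
        return t, hit

    def first_hit(self, p0: np.ndarray, p1: np.ndarray):
        """First intersection of segment p0->p1, or None.

        Returns ``(t, triangle_index, point)`` with t the segment parameter.
        """
        cand = self._candidates(p0, p1)
        if len(cand) == 0:
            return None
        t, hit = self._segment_hits_one(p0, p1, cand)
        if not hit.any():
            return None
        idx = np.argmin(np.where(hit, t, np.inf))
        tri = int(cand[idx])
        tt = float(t[idx])
        return tt, tri, p0 + tt * (p1 - p0)

    def segment_hits(self, p0: np.ndarray, p1: np.ndarray):
        """Batch first-hit query.

        Returns ``(hit_mask, t, tri_index)`` arrays over the n segments;
        segments whose bounding boxes touch no occupied hash cell are
        rejected in the broad phase.
        """
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        n = len(p0)
        hit_mask = np.zeros(n, dtype=bool)
        t_out = np.full(n, np.nan)
        tri_out = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            res = self.first_hit(p0[i], p1[i])
            if res is not None:
                hit_mask[i] = True
                t_out[i], tri_out[i] = res[0], res[1]
        return hit_mask, t_out, tri_out

    # ---------------------------------------------------------- containment
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Ray-parity containment test for a closed surface."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        span = float(np.linalg.norm(self.bounds[1] - self.bounds[0])) + 1.0
        far = points + span * _RAY_DIR
        out = np.zeros(len(points), dtype=bool)
        for i, (p, q) in enumerate(zip(points, far)):
            cand = self._candidates(p, q)
            if len(cand) == 0:
                continue
            t, hit = self._segment_hits_one(p, q, cand)
            out[i] = (int(hit.sum()) % 2) == 1
        return out

    def contains_grid(self, gx: np.ndarray, gy: np.ndarray, gz: np.ndarray,
                      jitter: float = 2.5e-4) -> np.ndarray:
        """Containment of a structured grid by vertical-column ray parity.

        One ray per (x, y) column; each grid node's parity is the number of
        surface crossings below it.  A tiny deterministic jitter moves the
        columns off the axis-aligned features a discretized surface has.
        """
        gx = np.asarray(gx, dtype=float)
        gy = np.asarray(gy, dtype=float)
        gz = np.asarray(gz, dtype=float)
        z0 = min(gz[0], self.bounds[0][2]) - 1.0
        z1 = max(gz[-1], self.bounds[1][2]) + 1.0
        out = np.zeros((len(gx), len(gy), len(gz)), dtype=bool)
        for i, x in enumerate(gx):
            for j, y in enumerate(gy):
                p0 = np.array([x + jitter, y + jitter, z0])
                p1 = np.array([x + jitter, y + jitter, z1])
                cand = self._candidates(p0, p1)
                if len(cand) == 0:
                    continue
                t, hit = self._segment_hits_one(p0, p1, cand)
                if not hit.any():
                    continue
                crossings = np.sort(z0 + t[hit] * (z1 - z0))
                below = np.searchsorted(crossings, gz)
                out[i, j] = (below % 2) == 1
        return out

    def normals(self, tri_index: np.ndarray) -> np.ndarray:
        n = np.cross(self._e1[tri_index], self._e2[tri_index])
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm


def point_mesh_distance(points: np.ndarray, triangles: np.ndarray,
                        chunk: int = 64):
    """Exact minimum distance from each point to a triangle set.

    Returns ``(distance, nearest_triangle_index)``.  Brute force over all
    triangles, chunked over points to bound memory.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(triangles, dtype=float)
    dists = np.empty(len(points))
    nearest = np.empty(len(points), dtype=np.int64)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        d = _point_triangle_distance(p, tri)
        dists[s:s + chunk] = d.min(axis=1)
        nearest[s:s + chunk] = d.argmin(axis=1)
    return dists, nearest


def _point_segment_distance(P: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(n, m) distances from points P[:,None] to segments A->B (broadcast)."""
    AB = B - A
    denom = np.maximum(np.einsum("...i,...i->...", AB, AB), 1e-300)
    t = np.clip(np.einsum("...i,...i->...", P - A, AB) / denom, 0.0, 1.0)
    closest = A + t[..., None] * AB
    return np.linalg.norm(P - closest, axis=-1)


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """(n, m) exact distances: plane projection if it falls inside the
    triangle, otherwise the nearest of the three edges."""
    A = tri[:, 0][None, :, :]
    Bv = tri[:, 1][None, :, :]
    C = tri[:, 2][None, :, :]
    P = points[:, None, :]
    E0 = Bv - A
    E1 = C - A
    n = np.cross(E0, E1)
    nn = np.maximum(np.einsum("...i,...i->...", n, n), 1e-300)
    w = P - A
    dist_plane = np.einsum("...i,...i->...", w, n) / np.sqrt(nn)
    # barycentric coordinates of the in-plane projection
    d00 = np.einsum("...i,...i->...", E0, E0)
    d01 = np.einsum("...i,...i->...", E0, E1)
    d11 = np.einsum("...i,...i->...", E1, E1)
    d20 = np.einsum("...i,...i->...", w, E0)
    d21 = np.einsum("...i,...i->...", w, E1)
    det = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    v = (d11 * d20 - d01 * d21) / det
    u = (d00 * d21 - d01 * d20) / det
    inside = (v >= 0) & (u >= 0) & (v + u <= 1)
    d_edges = np.minimum.reduce([
        _point_segment_distance(P, A, Bv),
        _point_segment_distance(P, Bv, C),
        _point_segment_distance(P, C, A),
    ])
    return np.where(inside, np.abs(dist_plane), d_edges)
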