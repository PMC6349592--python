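"""Chunked vectorized ray/triangle intersection (Moller-Trumbore).

Shared low-level primitive for shape-diameter-function ray casting and
point-in-mesh parity tests.  Works on plain vertex/face arrays so it has no
dependency on the mesh container.
"""

from __future__ import annotations

import numpy as np

try:  # JIT kernel preferred; numpy chunked path is the fallback
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["raycast_nearest", "points_inside"]

_EPS = 1e-12


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _raycast_kernel(origins, directions, v0, e1, e2, exclude, t_min):  # pragma: no cover
        n_rays = origins.shape[0]
        n_tris = v0.shape[0]
        out_t = np.full(n_rays, np.inf)
        out_f = np.full(n_rays, -1, dtype=np.int64)
        for r in range(n_rays):
            ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
            dx, dy, dz = directions[r, 0], directions[r, 1], directions[r, 2]
            best = np.inf
            bi = -1
            for j in range(n_tris):
                if j == exclude[r]:
                    continue
                e1x, e1y, e1z = e1[j, 0], e1[j, 1], e1[j, 2]
                e2x, e2y, e2z = e2[j, 0], e2[j, 1], e2[j, 2]
                px = dy * e2z - dz * e2y
                py = dz * e2x - dx * e2z
                pz = dx * e2y - dy * e2x
                det = e1x * px + e1y * py + e1z * pz
                if -1e-12 < det < 1e-12:
                    continue
                inv = 1.0 / det
                tx = ox - v0[j, 0]
                ty = oy - v0[j, 1]
                tz = oz - v0[j, 2]
                u = (tx * px + ty * py + tz * pz) * inv
                if u < -1e-10 or u > 1.0 + 1e-10:
                    continue
                qx = ty * e1z - tz * e1y
                qy = tz * e1x - tx * e1z
                qz = tx * e1y - ty * e1x
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < -1e-10 or u + v > 1.0 + 1e-10:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if t > t_min and t < best:
                    best = t
                    bi = j
            out_t[r] = best
            out_f[r] = bi
        return out_t, out_f


def _tri_arrays(vertices: np.ndarray, faces: np.ndarray):
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    return v0, e1, e2


def raycast_nearest(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    exclude_face: np.ndarray | None = None,
    t_min: float = 1e-9,
    chunk_pairs: int = 4_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest intersection of each ray with a triangle soup.

    Parameters
    ----------
    origins, directions : (R, 3) arrays. Directions need not be unit length;
        returned ``t`` is in units of the direction vector.
    exclude_face : optional (R,) face index that each ray must ignore
        (used when rays start on a face of the same mesh).

    Returns
    -------
    t : (R,) parameter of the nearest hit (inf where no hit).
    hit_face : (R,) face index of the nearest hit (-1 where no hit).
    """
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    n_rays = origins.shape[0]
    n_tris = faces.shape[0]
    v0, e1, e2 = _tri_arrays(vertices, faces)

    if _HAVE_NUMBA:
        excl = (
            np.asarray(exclude_face, dtype=np.int64)
            if exclude_face is not None
            else np.full(n_rays, -1, dtype=np.int64)
        )
        return _raycast_kernel(
            np.ascontiguousarray(origins),
            np.ascontiguousarray(directions),
            np.ascontiguousarray(v0),
            np.ascontiguousarray(e1),
            np.ascontiguousarray(e2),
            excl,
            t_min,
        )

    best_t = np.full(n_rays, np.inf)
    best_f = np.full(n_rays, -1, dtype=np.int64)

    rows = max(1, int(chunk_pairs // max(n_tris, 1)))
    for lo in range(0, n_rays, rows):
        hi = min(lo + rows, n_rays)
        o = origins[lo:hi, None, :]          # (r,1,3)
        d = directions[lo:hi, None, :]
        pvec = np.cross(d, e2[None, :, :])   # (r,T,3)
        det = np.einsum("rtk,tk->rt", pvec, e1)
        inv_det = np.where(np.abs(det) > _EPS, 1.0 / det, 0.0)
        tvec = o - v0[None, :, :]
        u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rtk,rk->rt", qvec, directions[lo:hi]) * inv_det
        t = np.einsum("rtk,tk->rt", qvec, e2) * inv_det
        ok = (
            (np.abs(det) > _EPS)
            & (u >= -1e-10)
            & (v >= -1e-10)
            & (u + v <= 1.0 + 1e-10)
            & (t > t_min)
        )
        if exclude_face is not None:
            cols = np.arange(n_tris)[None, :]
            ok &= cols != exclude_face[lo:hi, None]
        t = np.where(ok, t, np.inf)
        amin = np.argmin(t, axis=1)
        tm = t[np.arange(hi - lo), amin]
        best_t[lo:hi] = tm
        best_f[lo:hi] = np.where(np.isfinite(tm), amin, -1)
    return best_t, best_f


def points_inside(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    bins: int = 64,
) -> np.ndarray:
    """Parity point-in-mesh test for a closed surface.

    Casts one ray per point along a fixed irrational direction and counts
    crossings; odd parity means inside.  Triangles are binned on the plane
    perpendicular to the ray direction so each point is only tested against
    the triangles whose footprint overlaps its bin.
    """
    points = np.asarray(points, dtype=float)
    n_pts = points.shape[0]
    if n_pts == 0:
        return np.zeros(0, dtype=bool)
    # Fixed direction with irrational components: robust against hitting
    # lattice-aligned edges/vertices exactly.
    d = np.array([0.57321354, 0.71216342, 0.40563781])
    d /= np.linalg.norm(d)
    a1 = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(d, a1)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    v0, e1, e2 = _tri_arrays(vertices, faces)

    # 2-D footprint of each triangle in the (t1, t2) plane
    p2 = vertices @ np.column_stack([t1, t2])            # (N,2)
    tri2 = p2[faces]                                     # (T,3,2)
    tmin = tri2.min(axis=1)
    tmax = tri2.max(axis=1)
    q2 = points @ np.column_stack([t1, t2])              # (R,2)
    lo = np.minimum(tmin.min(axis=0), q2.min(axis=0)) - 1e-9
    hi = np.maximum(tmax.max(axis=0), q2.max(axis=0)) + 1e-9
    span = np.maximum(hi - lo, 1e-12)
    nb = max(4, min(bins, int(np.sqrt(len(faces))) + 1))
    inv_cell = nb / span

    def cell_of(xy):
        c = np.floor((xy - lo) * inv_cell).astype(np.int64)
        return np.clip(c, 0, nb - 1)

    cmin = cell_of(tmin)
    cmax = cell_of(tmax)
    # expand triangle footprints into (bin, tri) pairs
    wx = cmax[:, 0] - cmin[:, 0] + 1
    wy = cmax[:, 1] - cmin[:, 1] + 1
    reps = wx * wy
    tri_rep = np.repeat(np.arange(len(faces)), reps)
    offs = np.concatenate([np.arange(r) for r in reps]) if len(reps) else np.zeros(0, np.int64)
    ox = offs % np.repeat(wy, reps)  # local y offset
    oy = offs // np.repeat(wy, reps)
    bx = np.repeat(cmin[:, 0], reps) + oy
    by = np.repeat(cmin[:, 1], reps) + ox
    bin_id = bx * nb + by
    order = np.argsort(bin_id, kind="stable")
    bin_id = bin_id[order]
    tri_rep = tri_rep[order]
    starts = np.searchsorted(bin_id, np.arange(nb * nb))
    ends = np.searchsorted(bin_id, np.arange(nb * nb), side="right")

    qc = cell_of(q2)
    q_bin = qc[:, 0] * nb + qc[:, 1]
    q_order = np.argsort(q_bin, kind="stable")

    counts = np.zeros(n_pts, dtype=np.int64)
    pvec_all = np.cross(d, e2)                           # (T,3)
    det_all = np.einsum("tk,tk->t", pvec_all, e1)
    inv_det_all = np.where(np.abs(det_all) > _EPS, 1.0 / det_all, 0.0)

    i = 0
    nq = len(q_order)
    while i < nq:
        b = q_bin[q_order[i]]
        j = i
        while j < nq and q_bin[q_order[j]] == b:
            j += 1
        idx = q_order[i:j]
        tris = tri_rep[starts[b]:ends[b]]
        i = j
        if len(tris) == 0:
            continue
        o = points[idx][:, None, :]
        tvec = o - v0[tris][None, :, :]
        u = np.einsum("rtk,tk->rt", tvec, pvec_all[tris]) * inv_det_all[tris][None, :]
        qvec = np.cross(tvec, e1[tris][None, :, :])
        v = (qvec @ d) * inv_det_all[tris][None, :]
        t = np.einsum("rtk,tk->rt", qvec, e2[tris]) * inv_det_all[tris][None, :]
        ok = (
            (np.abs(det_all[tris])[None, :] > _EPS)
            & (u >= 0.0)
            & (v >= 0.0)
            & (u + v <= 1.0)
            & (t > 0.0)
        )
        counts[idx] = ok.sum(axis=1)
    return (counts % 2) == 1
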