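"""Shape-diameter-function segmentation and automatic appendage isolation.

The shape diameter function (SDF) assigns each face the local object
diameter, estimated by casting a cone of rays from the face centroid into
the interior (opposite the outward normal).  False intersections — hits
whose surface normal points the same way as the source normal — are
discarded; surviving ray lengths are median/std filtered and averaged with
weights inverse to the angle from the cone axis.  The field is
pose-invariant and scales linearly with the mesh, which makes it a robust
basis for separating the atrial chamber, pulmonary veins and appendage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from . import _ray
from .mesh_core import TriSurfaceMesh, boundary_loops

logger = logging.getLogger(__name__)

__all__ = [
    "SDFField",
    "RegionLabels",
    "compute_sdf",
    "cluster_regions",
    "identify_laa",
    "extract_submesh",
]


@dataclass
class SDFField:
    values: np.ndarray          # per-face local diameter, cm
    cone_half_angle: float      # radians
    n_rays: int
    seed: int


@dataclass
class RegionLabels:
    labels: np.ndarray          # per-face region id (edge-connected regions)
    chamber_id: int             # modal region id


def _cone_directions(n_rays: int, half_angle: float, seed: int):
    """Canonical unit directions in a cone about +z, plus their axis angles.

    The same canonical set is rotated into each face's intrinsic frame, so
    the field is exactly pose-invariant for a given seed.
    """
    rng = np.random.default_rng(seed)
    if half_angle <= 0:
        d = np.tile(np.array([0.0, 0.0, 1.0]), (n_rays, 1))
        return d, np.zeros(n_rays)
    u = rng.random(n_rays)
    cos_t = 1.0 - u * (1.0 - np.cos(half_angle))  # uniform on the spherical cap
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    phi = rng.random(n_rays) * 2.0 * np.pi
    d = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return d, np.arccos(np.clip(cos_t, -1.0, 1.0))


def face_adjacency(mesh: TriSurfaceMesh) -> np.ndarray:
    """(E, 2) pairs of faces sharing an edge."""
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key = np.sort(e, axis=1)
    fid = np.tile(np.arange(len(f)), 3)
    order = np.lexsort((key[:, 1], key[:, 0]))
    sk = key[order]
    sf = fid[order]
    same = np.all(sk[1:] == sk[:-1], axis=1)
    return np.column_stack([sf[:-1][same], sf[1:][same]])


def compute_sdf(
    mesh: TriSurfaceMesh,
    cone_half_angle: float = np.pi / 3,
    n_rays: int = 30,
    seed: int = 0,
) -> SDFField:
    """Per-face shape diameter values for a closed outward-oriented mesh."""
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    if cone_half_angle > 0 and n_rays < 4:
        raise ValueError("n_rays must be >= 4 for a non-degenerate cone")
    normals = mesh.face_normals()
    centroids = mesh.face_centroids()
    scale = float(np.linalg.norm(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)))

    # intrinsic per-face frame: first edge direction co-rotates with the mesh
    t1 = mesh.vertices[mesh.faces[:, 1]] - mesh.vertices[mesh.faces[:, 0]]
    t1 -= np.einsum("ij,ij->i", t1, normals)[:, None] * normals
    t1 /= np.maximum(np.linalg.norm(t1, axis=1, keepdims=True), 1e-300)
    t2 = np.cross(normals, t1)

    local_dirs, angles = _cone_directions(n_rays, cone_half_angle, seed)
    n_faces = len(mesh.faces)
    # world direction of ray r from face f: axis is -normal
    dirs = (
        local_dirs[None, :, 0, None] * t1[:, None, :]
        + local_dirs[None, :, 1, None] * t2[:, None, :]
        - local_dirs[None, :, 2, None] * normals[:, None, :]
    ).reshape(-1, 3)
    origins = np.repeat(centroids, n_rays, axis=0)
    exclude = np.repeat(np.arange(n_faces), n_rays)

    t_hit, f_hit = _ray.raycast_nearest(
        origins, dirs, mesh.vertices, mesh.faces, exclude_face=exclude,
        t_min=1e-9 * scale,
    )
    t_hit = t_hit.reshape(n_faces, n_rays)
    f_hit = f_hit.reshape(n_faces, n_rays)

    # drop misses and false intersections (hit normal facing like the source)
    valid = f_hit >= 0
    hit_dot = np.full_like(t_hit, -1.0)
    hit_dot[valid] = np.einsum(
        "ij,ij->i", normals[f_hit[valid]], normals[np.repeat(np.arange(n_faces), n_rays).reshape(n_faces, n_rays)[valid]]
    )
    valid &= hit_dot <= 0.0

    values = np.full(n_faces, np.nan)
    w_all = 1.0 / np.maximum(angles, 1e-3)
    lengths = np.where(valid, t_hit, np.nan)
    med = np.nanmedian(lengths, axis=1)
    std = np.nanstd(lengths, axis=1)
    keep = valid & (np.abs(lengths - med[:, None]) <= std[:, None] + 1e-300)
    wsum = (keep * w_all[None, :]).sum(axis=1)
    ok = wsum > 0
    values[ok] = (np.where(keep, t_hit, 0.0) * w_all[None, :]).sum(axis=1)[ok] / wsum[ok]

    if np.any(~ok):
        # fallback: breadth-first copy from the nearest valued neighbor
        logger.warning("SDF: %d faces had no surviving rays; using neighbor values",
                       int((~ok).sum()))
        adj_pairs = face_adjacency(mesh)
        nbrs: dict[int, list[int]] = {}
        for a, b in adj_pairs:
            nbrs.setdefault(int(a), []).append(int(b))
            nbrs.setdefault(int(b), []).append(int(a))
        missing = list(np.flatnonzero(~ok))
        guard = 0
        while missing and guard < 100:
            still = []
            for fidx in missing:
                vals = [values[j] for j in nbrs.get(fidx, []) if np.isfinite(values[j])]
                if vals:
                    values[fidx] = float(np.mean(vals))
                else:
                    still.append(fidx)
            missing = still
            guard += 1
        if missing:
            raise ValueError("SDF undefined on an entire connected component")
    return SDFField(values=values, cone_half_angle=cone_half_angle, n_rays=n_rays, seed=seed)


def cluster_regions(
    sdf: SDFField,
    mesh: TriSurfaceMesh,
    k_clusters: int = 4,
    spatial_weight: float = 1.0,
    vote_iterations: int = 10,
    seed: int = 0,
) -> RegionLabels:
    """Semantic clusterization of the SDF field.

    1-D k-means on log-SDF gives initial labels; iterated neighbor majority
    voting (neighbors weighted by ``spatial_weight`` against a self-weight
    of 1) regularizes cluster boundaries; finally labels are split into
    edge-connected regions.
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    vals = np.log(np.maximum(sdf.values, 1e-12))
    if k_clusters > len(np.unique(vals)):
        raise ValueError("k_clusters exceeds the number of distinct SDF values")
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(vals[:, None])

    pairs = face_adjacency(mesh)
    if spatial_weight > 0 and len(pairs):
        for _ in range(vote_iterations):
            votes = np.zeros((len(labels), k_clusters))
            votes[np.arange(len(labels)), labels] += 1.0
            np.add.at(votes, (pairs[:, 0], labels[pairs[:, 1]]), spatial_weight)
            np.add.at(votes, (pairs[:, 1], labels[pairs[:, 0]]), spatial_weight)
            new = np.argmax(votes, axis=1)
            if np.array_equal(new, labels):
                break
            labels = new

    # split into edge-connected regions
    same = labels[pairs[:, 0]] == labels[pairs[:, 1]] if len(pairs) else np.zeros(0, bool)
    g = coo_matrix(
        (np.ones(int(same.sum())), (pairs[same, 0], pairs[same, 1])),
        shape=(len(labels), len(labels)),
    )
    _, comp = connected_components(g, directed=False)
    chamber = int(np.bincount(comp).argmax())
    return RegionLabels(labels=comp, chamber_id=chamber)


def _regions_adjacent_to(labels: np.ndarray, pairs: np.ndarray, region: int) -> set[int]:
    a, b = labels[pairs[:, 0]], labels[pairs[:, 1]]
    touch = set()
    touch.update(b[(a == region) & (b != region)].tolist())
    touch.update(a[(b == region) & (a != region)].tolist())
    return touch


def identify_laa(
    labels: RegionLabels,
    mesh: TriSurfaceMesh,
    hint: np.ndarray | None = None,
) -> np.ndarray:
    """Face set of the appendage.

    The chamber is the modal region; regions containing a tagged PV or MV
    port boundary are merged into it.  The appendage is then the region
    containing the hint point (if given) or the largest remaining region
    adjacent to the chamber.  The cut is regularized so that the selected
    face set is edge-connected with an edge-connected complement.
    """
    lab = labels.labels.copy()
    pairs = face_adjacency(mesh)
    chamber = labels.chamber_id

    # faces touching a tagged port (open rims) or carrying a port cap label
    # anchor their regions to the chamber
    port_vertices: set[int] = set()
    for name, loop in mesh.port_loops.items():
        port_vertices.update(int(v) for v in loop)
    on_port = np.zeros(len(mesh.faces), dtype=bool)
    if port_vertices:
        on_port |= np.array(
            [any(int(v) in port_vertices for v in f) for f in mesh.faces], dtype=bool
        )
    if mesh.face_labels is not None:
        port_ids = [
            lid for lname, lid in mesh.label_names.items()
            if lname.startswith("PV") or lname in ("MV", "CAP0", "CAP1")
        ]
        if port_ids:
            on_port |= np.isin(mesh.face_labels, port_ids)
    if np.any(on_port):
        for r in np.unique(lab[on_port]):
            lab[lab == r] = chamber

    remaining = [r for r in np.unique(lab) if r != chamber]
    if not remaining:
        raise ValueError("no appendage candidate: all regions merged into the chamber")

    if hint is not None:
        hint = np.asarray(hint, dtype=float)
        d = np.linalg.norm(mesh.face_centroids() - hint[None, :], axis=1)
        r_hint = int(lab[np.argmin(d)])
        if r_hint == chamber:
            raise ValueError("hint point resolves to the chamber region")
        target = r_hint
    else:
        adj = _regions_adjacent_to(lab, pairs, chamber)
        cands = [r for r in remaining if r in adj]
        if not cands:
            raise ValueError("no appendage candidate adjacent to the chamber")
        sizes = {r: int((lab == r).sum()) for r in cands}
        target = max(cands, key=sizes.get)

    face_set = lab == target
    # regularization: absorb islands so both sides are edge-connected and the
    # cut is a single simple loop
    face_set = _largest_component(face_set, pairs, len(lab))
    comp_out = _largest_component(~face_set, pairs, len(lab))
    face_set = ~comp_out
    face_set = _largest_component(face_set, pairs, len(lab))
    return np.flatnonzero(face_set)


def _largest_component(mask: np.ndarray, pairs: np.ndarray, n: int) -> np.ndarray:
    sel = mask[pairs[:, 0]] & mask[pairs[:, 1]]
    g = coo_matrix((np.ones(int(sel.sum())), (pairs[sel, 0], pairs[sel, 1])), shape=(n, n))
    _, comp = connected_components(g, directed=False)
    comp_ids = comp[mask]
    if len(comp_ids) == 0:
        return mask
    big = np.bincount(comp_ids).argmax()
    return mask & (comp == big)


def extract_submesh(
    mesh: TriSurfaceMesh, face_set: np.ndarray
) -> tuple[TriSurfaceMesh, TriSurfaceMesh]:
    """Split a mesh along a face set; both halves tag the cut loop OSTIUM.

    Raises if the face set is not edge-connected or the cut is not a single
    simple loop.
    """
    face_mask = np.zeros(mesh.n_faces, dtype=bool)
    face_mask[np.asarray(face_set)] = True
    if not face_mask.any():
        raise ValueError("empty face set")
    pairs = face_adjacency(mesh)
    comp = _largest_component(face_mask, pairs, mesh.n_faces)
    if comp.sum() != face_mask.sum():
        raise ValueError("face set is not edge-connected")

    def build(mask: np.ndarray) -> TriSurfaceMesh:
        fidx = np.flatnonzero(mask)
        used = np.unique(mesh.faces[fidx])
        remap = -np.ones(mesh.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = TriSurfaceMesh(mesh.vertices[used], remap[mesh.faces[fidx]])
        if mesh.face_labels is not None:
            sub.face_labels = mesh.face_labels[fidx]
            sub.label_names = dict(mesh.label_names)
        # carry over port tags whose loops survive intact
        for name, loop in mesh.port_loops.items():
            if np.all(remap[loop] >= 0):
                sub.port_loops[name] = remap[loop]
        return sub

    sub = build(face_mask)
    rem = build(~face_mask)
    pre_existing = len(boundary_loops(mesh))
    sub_loops = boundary_loops(sub)
    if len(sub_loops) != 1:
        raise ValueError(
            f"non-simple cut: appendage submesh has {len(sub_loops)} boundary loops, expected 1"
        )
    rem_loops = boundary_loops(rem)
    if len(rem_loops) != pre_existing + 1:
        raise ValueError(
            f"non-simple cut: remainder has {len(rem_loops)} boundary loops, "
            f"expected {pre_existing + 1}"
        )
    sub.port_loops["OSTIUM"] = sub_loops[0]
    # the remainder's new loop is the one matching the submesh cut (compare
    # barycenters; port loops were carried over by tag)
    cut_bary = sub.vertices[sub_loops[0]].mean(axis=0)
    best = min(rem_loops, key=lambda l: np.linalg.norm(rem.vertices[l].mean(axis=0) - cut_bary))
    rem.port_loops["OSTIUM"] = best
    return sub, rem
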