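"""Surface and tetrahedral mesh containers, I/O and elementary operators.

All coordinates are in centimetres.  Triangulated surfaces are stored as
plain vertex/face arrays with optional per-face integer labels and named
boundary *port* loops (pulmonary veins, mitral valve, appendage ostium).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.spatial import Delaunay, cKDTree

from . import _ray

__all__ = [
    "TriSurfaceMesh",
    "TetMesh",
    "MeshIOError",
    "read_mesh",
    "write_mesh",
    "surface_area",
    "enclosed_volume",
    "boundary_loops",
    "laplacian_smooth",
    "cap_ports",
    "tetrahedralize",
    "stitch",
]


class MeshIOError(ValueError):
    """Raised when a mesh file cannot be parsed."""


@dataclass
class TriSurfaceMesh:
    """Triangle surface mesh with optional labels and named port loops.

    ``port_loops`` maps a port name (e.g. ``"PV1"``, ``"MV"``, ``"OSTIUM"``)
    to an ordered array of vertex indices tracing that boundary loop.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray | None = None
    label_names: dict[str, int] = field(default_factory=dict)
    port_loops: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, dtype=np.int64)
            if self.face_labels.shape != (len(self.faces),):
                raise ValueError("face_labels must have one entry per face")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriSurfaceMesh":
        return TriSurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.face_labels is None else self.face_labels.copy(),
            dict(self.label_names),
            {k: v.copy() for k, v in self.port_loops.items()},
        )

    def face_normals(self) -> np.ndarray:
        n = np.cross(
            self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]],
            self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]],
        )
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_areas(self) -> np.ndarray:
        n = np.cross(
            self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]],
            self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]],
        )
        return 0.5 * np.linalg.norm(n, axis=1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-in-mesh parity test; the surface must be closed."""
        return _ray.points_inside(points, self.vertices, self.faces)


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with labelled boundary patches."""

    vertices: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_labels: np.ndarray
    label_names: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(self.boundary_faces, dtype=np.int64)
        self.boundary_labels = np.asarray(self.boundary_labels, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tets
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def patch_faces(self, name: str) -> np.ndarray:
        lab = self.label_names[name]
        return self.boundary_faces[self.boundary_labels == lab]

    def patch_area(self, name: str) -> float:
        f = self.patch_faces(name)
        n = np.cross(
            self.vertices[f[:, 1]] - self.vertices[f[:, 0]],
            self.vertices[f[:, 2]] - self.vertices[f[:, 0]],
        )
        return float(0.5 * np.linalg.norm(n, axis=1).sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {"stl", "ply", "off", "vtk", "vtp"}


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    fmt = fmt.lower().lstrip(".")
    if fmt not in _FORMATS:
        raise MeshIOError(f"unsupported mesh format '{fmt}' (supported: {sorted(_FORMATS)})")
    return fmt


def write_mesh(mesh: TriSurfaceMesh, path: str, fmt: str | None = None) -> None:
    fmt = _detect_format(path, fmt)
    if fmt in ("stl", "off"):
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(path)
    elif fmt == "ply":
        _write_ply(mesh, path)
    else:  # legacy vtk / vtp written as legacy polydata ASCII
        _write_vtk_polydata(mesh, path)


def read_mesh(path: str, fmt: str | None = None) -> TriSurfaceMesh:
    fmt = _detect_format(path, fmt)
    if fmt in ("stl", "off"):
        tm = trimesh.load(str(path), force="mesh")
        if fmt == "stl":
            tm.merge_vertices()
        return TriSurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    if fmt == "ply":
        return _read_ply(path)
    return _read_vtk_polydata(path)


def _write_ply(mesh: TriSurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        if mesh.face_labels is not None:
            fh.write("property int label\n")
        fh.write("end_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        if mesh.face_labels is None:
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        else:
            for f, lab in zip(mesh.faces, mesh.face_labels):
                fh.write(f"3 {f[0]} {f[1]} {f[2]} {lab}\n")


def _read_ply(path: str) -> TriSurfaceMesh:
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header != b"ply":
            raise MeshIOError(f"{path}: not a PLY file (first line {header!r})")
        fmt_line = fh.readline().strip()
        if b"ascii" not in fmt_line:
            tm = trimesh.load(str(path), force="mesh")
            return TriSurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    n_vert = n_face = 0
    face_props: list[str] = []
    current = None
    with open(path) as fh:
        line_no = 0
        for line in fh:
            line_no += 1
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "element":
                current = tok[1]
                if tok[1] == "vertex":
                    n_vert = int(tok[2])
                elif tok[1] == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and current == "face" and tok[1] != "list":
                face_props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        else:
            raise MeshIOError(f"{path}: missing end_header")
        verts = np.empty((n_vert, 3))
        for i in range(n_vert):
            line = fh.readline()
            line_no += 1
            try:
                verts[i] = [float(x) for x in line.split()[:3]]
            except (ValueError, IndexError) as exc:
                raise MeshIOError(f"{path}:{line_no}: bad vertex line {line!r}") from exc
        faces = np.empty((n_face, 3), dtype=np.int64)
        labels = np.empty(n_face, dtype=np.int64) if "label" in face_props else None
        for i in range(n_face):
            line = fh.readline()
            line_no += 1
            tok = line.split()
            try:
                cnt = int(tok[0])
                if cnt != 3:
                    raise MeshIOError(f"{path}:{line_no}: only triangles supported (got {cnt}-gon)")
                faces[i] = [int(x) for x in tok[1:4]]
                if labels is not None:
                    labels[i] = int(tok[4])
            except (ValueError, IndexError) as exc:
                raise MeshIOError(f"{path}:{line_no}: bad face line {line!r}") from exc
    return TriSurfaceMesh(verts, faces, labels)


def _write_vtk_polydata(mesh: TriSurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natriflow surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if mesh.face_labels is not None:
            fh.write(f"CELL_DATA {mesh.n_faces}\nSCALARS label int 1\nLOOKUP_TABLE default\n")
            for lab in mesh.face_labels:
                fh.write(f"{lab}\n")


def _read_vtk_polydata(path: str) -> TriSurfaceMesh:
    with open(path) as fh:
        lines = fh.read().split("\n")
    verts = faces = labels = None
    i = 0
    try:
        while i < len(lines):
            tok = lines[i].split()
            if tok and tok[0] == "POINTS":
                n = int(tok[1])
                flat: list[float] = []
                i += 1
                while len(flat) < 3 * n:
                    flat.extend(float(x) for x in lines[i].split())
                    i += 1
                verts = np.array(flat).reshape(n, 3)
                continue
            if tok and tok[0] == "POLYGONS":
                n = int(tok[1])
                faces = np.empty((n, 3), dtype=np.int64)
                for j in range(n):
                    row = lines[i + 1 + j].split()
                    if row[0] != "3":
                        raise MeshIOError(f"{path}:{i + 2 + j}: only triangles supported")
                    faces[j] = [int(x) for x in row[1:4]]
                i += n + 1
                continue
            if tok and tok[0] == "SCALARS" and tok[1] == "label":
                i += 2  # skip LOOKUP_TABLE
                labels = np.array([int(lines[i + 1 + j]) for j in range(len(faces))])
                i += len(faces) + 1
                continue
            i += 1
    except (ValueError, IndexError) as exc:
        raise MeshIOError(f"{path}:{i + 1}: malformed VTK polydata near {lines[i]!r}") from exc
    if verts is None or faces is None:
        raise MeshIOError(f"{path}: no POINTS/POLYGONS section found")
    return TriSurfaceMesh(verts, faces, labels)


def write_vtu(tet: TetMesh, path: str, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a tet mesh (plus optional nodal fields) as legacy unstructured VTK."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natriflow volume\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {tet.n_vertices} double\n")
        np.savetxt(fh, tet.vertices, fmt="%.17g")
        fh.write(f"CELLS {tet.n_tets} {5 * tet.n_tets}\n")
        cells = np.column_stack([np.full(tet.n_tets, 4, dtype=np.int64), tet.tets])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {tet.n_tets}\n")
        np.savetxt(fh, np.full(tet.n_tets, 10, dtype=np.int64), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {tet.n_vertices}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")


# ---------------------------------------------------------------------------
# Elementary measures
# ---------------------------------------------------------------------------


def surface_area(mesh: TriSurfaceMesh) -> float:
    """Total surface area in cm^2 (sum of triangle areas)."""
    return float(mesh.face_areas().sum())


def enclosed_volume(mesh: TriSurfaceMesh) -> float:
    """Enclosed volume of a closed orientable surface (divergence theorem), cm^3."""
    loops = boundary_loops(mesh)
    if loops:
        lens = [len(l) for l in loops]
        raise ValueError(
            f"enclosed_volume requires a closed surface; found {len(loops)} "
            f"open boundary loop(s) with vertex counts {lens}"
        )
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", np.cross(v[f[:, 0]], v[f[:, 1]]), v[f[:, 2]]) / 6.0
    return float(abs(signed.sum()))


def _edge_face_table(mesh: TriSurfaceMesh):
    f = mesh.faces
    # directed edges per face: (0,1), (1,2), (2,0)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key = np.sort(e, axis=1)
    return e, key


def boundary_loops(mesh: TriSurfaceMesh) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary, longest first.

    Loop direction follows the winding of the adjacent faces.  Raises on
    non-manifold boundary configurations.
    """
    if mesh.n_faces == 0:
        return []
    directed, key = _edge_face_table(mesh)
    order = np.lexsort((key[:, 1], key[:, 0]))
    sk = key[order]
    new_grp = np.any(np.diff(sk, axis=0) != 0, axis=1)
    grp_id = np.concatenate([[0], np.cumsum(new_grp)])
    counts = np.bincount(grp_id)
    if counts.max(initial=0) > 2:
        bad = sk[np.searchsorted(grp_id, np.argmax(counts))]
        raise ValueError(f"non-manifold edge {tuple(bad)} shared by {counts.max()} faces")
    first_of_grp = np.concatenate([[True], new_grp])
    single = first_of_grp & (counts[grp_id] == 1)
    bnd = directed[order][single]
    if len(bnd) == 0:
        return []
    nxt: dict[int, int] = {}
    for a, b in bnd:
        if int(a) in nxt:
            raise ValueError(f"non-manifold boundary at vertex {int(a)}")
        nxt[int(a)] = int(b)
    loops: list[np.ndarray] = []
    seen: set[int] = set()
    for start in nxt:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in seen or cur not in nxt:
                raise ValueError("open boundary chain does not close into a loop")
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(np.array(loop, dtype=np.int64))

    def loop_length(loop: np.ndarray) -> float:
        p = mesh.vertices[loop]
        return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())

    loops.sort(key=loop_length, reverse=True)
    return loops


def _vertex_adjacency(mesh: TriSurfaceMesh):
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    n = mesh.n_vertices
    data = np.ones(len(e))
    adj = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
    adj = adj + adj.T
    adj.data[:] = 1.0
    return adj


def laplacian_smooth(
    mesh: TriSurfaceMesh,
    iterations: int = 10,
    relaxation: float = 0.5,
    free: np.ndarray | None = None,
) -> TriSurfaceMesh:
    """Umbrella-operator Laplacian smoothing with boundary vertices held fixed.

    ``free`` optionally restricts smoothing to a vertex subset (used for
    seam-band smoothing after grafting).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    adj = _vertex_adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    movable = deg > 0
    for loop in boundary_loops(mesh):
        movable[loop] = False
    if free is not None:
        mask = np.zeros(mesh.n_vertices, dtype=bool)
        mask[free] = True
        movable &= mask
    v = out.vertices
    for _ in range(iterations):
        mean = adj @ v / np.maximum(deg, 1)[:, None]
        v[movable] += relaxation * (mean[movable] - v[movable])
    out.vertices = v
    return out


# ---------------------------------------------------------------------------
# Port capping
# ---------------------------------------------------------------------------


def cap_ports(
    mesh: TriSurfaceMesh,
    ports: list[str] | None = None,
    wall_label_name: str = "WALL",
) -> TriSurfaceMesh:
    """Close the named port loops with barycentric triangle fans.

    Every existing face gets (or keeps) a label; each cap's faces are
    labelled with the port name.  With ``ports=None`` all open boundary
    loops are capped: tagged ports under their names, untagged loops under
    ``CAP<i>``.
    """
    out = mesh.copy()
    names = dict(out.label_names)
    if wall_label_name not in names:
        names[wall_label_name] = (max(names.values()) + 1) if names else 0
    labels = (
        out.face_labels
        if out.face_labels is not None
        else np.full(out.n_faces, names[wall_label_name], dtype=np.int64)
    )
    loops = boundary_loops(out)
    if ports is None:
        tagged = {id(None): None}
        port_items: list[tuple[str, np.ndarray]] = []
        claimed: set[frozenset] = set()
        for name, loop in out.port_loops.items():
            port_items.append((name, np.asarray(loop)))
            claimed.add(frozenset(int(x) for x in loop))
        k = 0
        for loop in loops:
            if frozenset(int(x) for x in loop) not in claimed:
                port_items.append((f"CAP{k}", loop))
                k += 1
    else:
        port_items = [(name, np.asarray(out.port_loops[name])) for name in ports]

    verts = out.vertices
    new_faces = [out.faces]
    new_labels = [labels]
    loop_sets = {frozenset(int(x) for x in l): l for l in loops}
    for name, loop in port_items:
        actual = loop_sets.get(frozenset(int(x) for x in loop))
        if actual is None:
            raise ValueError(f"port '{name}' is not an open boundary loop of this mesh")
        if name not in names:
            names[name] = max(names.values()) + 1
        bary = verts[actual].mean(axis=0)
        m = len(actual)
        mean_edge = float(np.linalg.norm(
            verts[np.roll(actual, -1)] - verts[actual], axis=1).mean())
        mean_rad = float(np.linalg.norm(verts[actual] - bary, axis=1).mean())
        # concentric rings keep cap facet size close to the rim edge length;
        # a single long-spoke fan would let volume meshing sag below the cap
        n_rings = max(1, int(round(mean_rad / max(mean_edge, 1e-12))))
        cap_faces = []
        prev = actual
        for k in range(1, n_rings):
            f = k / n_rings
            ring = verts[actual] * (1 - f) + bary[None, :] * f
            base = len(verts)
            verts = np.vstack([verts, ring])
            idx = base + np.arange(m)
            a, b = prev, np.roll(prev, -1)
            c, d = idx, np.roll(idx, -1)
            # boundary edge (a -> b) follows face winding; the cap reverses it
            cap_faces.append(np.column_stack([b, a, c]))
            cap_faces.append(np.column_stack([b, c, d]))
            prev = idx
        bidx = len(verts)
        verts = np.vstack([verts, bary[None, :]])
        a, b = prev, np.roll(prev, -1)
        cap_faces.append(np.column_stack([b, a, np.full(m, bidx, dtype=np.int64)]))
        cap_faces = np.vstack(cap_faces)
        new_faces.append(cap_faces)
        new_labels.append(np.full(len(cap_faces), names[name], dtype=np.int64))
    return TriSurfaceMesh(
        verts,
        np.vstack(new_faces),
        np.concatenate(new_labels),
        names,
        {},
    )


def stitch(a: TriSurfaceMesh, b: TriSurfaceMesh, tol: float = 1e-12) -> TriSurfaceMesh:
    """Merge two surfaces, fusing vertices with identical coordinates.

    Inverse of submesh extraction: re-stitching the two halves of a cut
    reproduces the original composite.
    """
    tree = cKDTree(a.vertices)
    d, idx = tree.query(b.vertices)
    remap = np.empty(b.n_vertices, dtype=np.int64)
    new_pts = []
    nxt = a.n_vertices
    for i in range(b.n_vertices):
        if d[i] <= tol:
            remap[i] = idx[i]
        else:
            remap[i] = nxt
            new_pts.append(b.vertices[i])
            nxt += 1
    verts = np.vstack([a.vertices] + ([np.array(new_pts)] if new_pts else []))
    faces = np.vstack([a.faces, remap[b.faces]])
    return TriSurfaceMesh(verts, faces)


# ---------------------------------------------------------------------------
# Closest point on surface
# ---------------------------------------------------------------------------


def _point_triangle_closest(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Vectorized closest point on triangle (Ericson, Real-Time Collision
    Detection).  All inputs broadcast over the leading axes."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    v = np.where(np.abs(denom) > 1e-300, vb / np.where(denom == 0, 1, denom), 0.0)
    w = np.where(np.abs(denom) > 1e-300, vc / np.where(denom == 0, 1, denom), 0.0)
    res = a + v[..., None] * ab + w[..., None] * ac

    # edge/vertex regions override the interior solution
    t_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0), 0, 1)
    res = np.where((vb <= 0)[..., None] & (d2 >= 0)[..., None] & (d6 <= 0)[..., None],
                   a + t_ac[..., None] * ac, res)
    t_bc = np.clip(np.where((d4 - d3) + (d5 - d6) != 0,
                            (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1,
                                                 (d4 - d3) + (d5 - d6)), 0), 0, 1)
    res = np.where((va <= 0)[..., None] & ((d4 - d3) >= 0)[..., None] & ((d5 - d6) >= 0)[..., None],
                   b + t_bc[..., None] * (c - b), res)
    t_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0), 0, 1)
    res = np.where((vc <= 0)[..., None] & (d1 >= 0)[..., None] & (d3 <= 0)[..., None],
                   a + t_ab[..., None] * ab, res)
    res = np.where((d1 <= 0)[..., None] & (d2 <= 0)[..., None], a, res)
    res = np.where((d3 >= 0)[..., None] & (d4 <= d3)[..., None], b, res)
    res = np.where((d6 >= 0)[..., None] & (d5 <= d6)[..., None], c, res)
    return res


def closest_surface_face(
    surface: TriSurfaceMesh, points: np.ndarray, k: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest surface face (and distance) for each query point.

    Candidate faces come from the k nearest face centroids plus all faces
    incident to the 4 nearest mesh vertices, which keeps large skinny
    triangles (port-cap fans) competitive with dense wall facets.
    """
    points = np.asarray(points, dtype=float)
    verts = surface.vertices
    faces = surface.faces
    cent_tree = cKDTree(surface.face_centroids())
    vert_tree = cKDTree(verts)
    kc = min(k, len(faces))
    _, cand_c = cent_tree.query(points, k=kc)
    if kc == 1:
        cand_c = cand_c[:, None]
    kv = min(4, len(verts))
    _, near_v = vert_tree.query(points, k=kv)
    if kv == 1:
        near_v = near_v[:, None]
    # vertex -> incident faces table (padded)
    order = np.argsort(faces.ravel(), kind="stable")
    vsort = faces.ravel()[order]
    fsort = order // 3
    starts = np.searchsorted(vsort, np.arange(len(verts)))
    ends = np.searchsorted(vsort, np.arange(len(verts)), side="right")
    max_deg = int((ends - starts).max(initial=1))
    incid = np.full((len(verts), max_deg), -1, dtype=np.int64)
    for vi in range(len(verts)):
        incid[vi, : ends[vi] - starts[vi]] = fsort[starts[vi]:ends[vi]]

    cand_v = incid[near_v].reshape(len(points), -1)
    cand = np.concatenate([cand_c, cand_v], axis=1)
    cand[cand < 0] = cand_c[:, [0]].repeat(cand.shape[1], axis=1)[cand < 0]
    a = verts[faces[cand, 0]]
    b = verts[faces[cand, 1]]
    c = verts[faces[cand, 2]]
    cp = _point_triangle_closest(points[:, None, :], a, b, c)
    d2 = np.einsum("pck,pck->pc", cp - points[:, None, :], cp - points[:, None, :])
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return cand[rows, best], np.sqrt(d2[rows, best])


# ---------------------------------------------------------------------------
# Tetrahedralization
# ---------------------------------------------------------------------------


def _face_interior_samples(surface: TriSurfaceMesh, h: float) -> np.ndarray:
    """Barycentric-grid samples in the interior of faces larger than h,
    with the grid resolution set per edge so skinny faces are not
    oversampled across their thin direction."""
    out = []
    v = surface.vertices
    for f in surface.faces:
        a, b, c = v[f[0]], v[f[1]], v[f[2]]
        n1 = int(np.floor(np.linalg.norm(b - a) / h)) + 1
        n2 = int(np.floor(np.linalg.norm(c - a) / h)) + 1
        if n1 < 2 and n2 < 2:
            continue
        for i in range(1, n1):
            for j in range(1, n2):
                u, w = i / n1, j / n2
                if u + w < 1.0 - 1e-12:
                    out.append(a + u * (b - a) + w * (c - a))
    return np.array(out) if out else np.zeros((0, 3))


def tetrahedralize(
    surface: TriSurfaceMesh,
    max_cell_size: float,
    interior_margin: float = 0.45,
    refine_regions: list[tuple["TriSurfaceMesh", float]] | None = None,
) -> TetMesh:
    """Fill a watertight labelled surface with tetrahedra.

    Strategy: Delaunay triangulation of the surface vertices plus an interior
    cubic lattice (spacing ``max_cell_size``), keeping tetrahedra whose
    centroid lies inside the surface.  Boundary faces of the kept set are
    labelled from the nearest input surface face, so port caps become
    boundary patches.

    ``refine_regions`` lists (closed_region_surface, local_size) pairs:
    inside each region the lattice is resampled at the finer local size,
    which is how a narrow appendage stays resolved while the chamber keeps
    the coarse background spacing.

    Exact for convex domains; for the smooth atrial composites the boundary
    is recovered to within one cell size.
    """
    loops = boundary_loops(surface)
    if loops:
        raise ValueError(
            f"tetrahedralize requires a watertight surface; found {len(loops)} open loop(s)"
        )
    if surface.face_labels is None:
        surface = replace(surface.copy(), face_labels=np.zeros(surface.n_faces, dtype=np.int64))
        surface.label_names = {"WALL": 0}
    h = float(max_cell_size)
    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    axes = [np.arange(lo[k] + 0.5 * h, hi[k], h) for k in range(3)]
    if all(len(ax) for ax in axes):
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        # tiny deterministic jitter breaks co-spherical lattice degeneracies
        rng = np.random.default_rng(12345)
        grid = grid + (rng.random(grid.shape) - 0.5) * (0.02 * h)
        inside = _ray.points_inside(grid, surface.vertices, surface.faces)
        grid = grid[inside]
        if len(grid):
            tree = cKDTree(surface.vertices)
            dist, _ = tree.query(grid)
            grid = grid[dist > interior_margin * h]
    else:
        grid = np.zeros((0, 3))
    refine_pts = []
    if refine_regions:
        tree = cKDTree(surface.vertices)
        for region, h_loc in refine_regions:
            # drop coarse lattice points inside the region, resample finer
            if len(grid):
                in_region = _ray.points_inside(grid, region.vertices, region.faces)
                grid = grid[~in_region]
            rlo = region.vertices.min(axis=0)
            rhi = region.vertices.max(axis=0)
            raxes = [np.arange(rlo[k] + 0.5 * h_loc, rhi[k], h_loc) for k in range(3)]
            if not all(len(ax) for ax in raxes):
                continue
            rgrid = np.stack(
                np.meshgrid(*raxes, indexing="ij"), axis=-1).reshape(-1, 3)
            rng = np.random.default_rng(54321)
            rgrid = rgrid + (rng.random(rgrid.shape) - 0.5) * (0.02 * h_loc)
            keep = _ray.points_inside(rgrid, region.vertices, region.faces)
            keep &= _ray.points_inside(rgrid, surface.vertices, surface.faces)
            rgrid = rgrid[keep]
            if len(rgrid):
                dist, _ = tree.query(rgrid)
                rgrid = rgrid[dist > interior_margin * h_loc]
            if len(rgrid):
                refine_pts.append(rgrid)
    # large flat faces (port caps) need on-surface samples at the lattice
    # spacing, otherwise the Delaunay boundary sags below them
    extra = _face_interior_samples(surface, h)
    points = np.vstack([surface.vertices, extra, grid] + refine_pts)
    dela = Delaunay(points)
    tets = dela.simplices.astype(np.int64)
    cent = points[tets].mean(axis=1)
    keep = _ray.points_inside(cent, surface.vertices, surface.faces)
    tets = tets[keep]
    # consistent positive orientation
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    vol = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    vol = np.abs(vol)
    tets = tets[vol > 1e-9 * h**3]
    if len(tets) == 0:
        raise ValueError("tetrahedralization produced no interior tetrahedra; refine max_cell_size")

    # compact vertex numbering
    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = points[used]
    tets = remap[tets]

    # boundary faces: those appearing in exactly one tet
    face_idx = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    tri = tets[:, face_idx].reshape(-1, 3)
    key = np.sort(tri, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    sk = key[order]
    new_grp = np.any(np.diff(sk, axis=0) != 0, axis=1)
    grp_id = np.concatenate([[0], np.cumsum(new_grp)])
    counts = np.bincount(grp_id)
    first = np.concatenate([[True], new_grp])
    single = first & (counts[grp_id] == 1)
    bfaces = tri[order][single]
    # orient boundary faces outward (normal away from owning tet centroid)
    tet_of = (order[single] // 4)
    own_cent = verts[tets[tet_of]].mean(axis=1)
    fn = np.cross(
        verts[bfaces[:, 1]] - verts[bfaces[:, 0]],
        verts[bfaces[:, 2]] - verts[bfaces[:, 0]],
    )
    fcent = verts[bfaces].mean(axis=1)
    inward = np.einsum("ij,ij->i", fn, fcent - own_cent) < 0
    bfaces[inward] = bfaces[inward][:, [0, 2, 1]]

    # transfer patch labels from the closest point on the input surface,
    # requiring normal agreement so ragged stair-step faces near a port rim
    # fall back to the wall instead of inflating the port patch
    src_norm = surface.face_normals()
    bcent = verts[bfaces].mean(axis=1)
    bnorm = np.cross(
        verts[bfaces[:, 1]] - verts[bfaces[:, 0]],
        verts[bfaces[:, 2]] - verts[bfaces[:, 0]],
    )
    bnorm /= np.maximum(np.linalg.norm(bnorm, axis=1, keepdims=True), 1e-300)
    tri_id, _ = closest_surface_face(surface, bcent)
    agree = np.einsum("bk,bk->b", bnorm, src_norm[tri_id])
    blabels = surface.face_labels[tri_id].copy()
    wall_id = surface.label_names.get("WALL")
    if wall_id is not None:
        blabels[agree < 0.5] = wall_id
    return TetMesh(verts, tets, bfaces, blabels, dict(surface.label_names))
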