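"""Parametric left-atrium and appendage generator with analytic ground truth.

The appendage is a circle swept along a cubic spline with rotation-minimizing
frames; the distal end is rounded by driving the tube radius to zero along a
circular profile over the last ``r_end`` of arclength, so the swept surface
closes with a hemispherical cap *at the spline endpoint*.  The generator
therefore knows exactly the centerline length L, the endpoint distance D and
the tortuosity chi = L/D - 1 of every appendage it emits, along with
quadrature values for its volume and lateral surface area.

The template atrium is an ellipsoidal chamber with four pulmonary-vein tubes,
a mitral-valve port and an appendage ostium port.  It is a stand-in geometry
whose enclosed volume (~100 ml) and port calibres are physiologic; it makes
no claim to patient-specific atrial shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline

from .mesh_core import TriSurfaceMesh, boundary_loops

__all__ = [
    "LAACurveSpec",
    "PortSpec",
    "TemplateLASpec",
    "GroundTruth",
    "make_parametric_laa",
    "make_template_la",
    "make_study_set",
]


@dataclass
class LAACurveSpec:
    """Swept-tube appendage specification.

    control_points : (k, 3) spline control points in cm, ostium end first.
    radius : base tube radius in cm, or a callable of normalized arclength
        s/L in [0, 1] returning the radius.
    taper : linear distal narrowing factor in [0, 1); radius is multiplied
        by (1 - taper * s/L).  Mimics appendages shrunk toward the tip.
    samples : rings along the axis; n_theta : vertices per ring.
    """

    control_points: np.ndarray
    radius: float | object = 0.5
    taper: float = 0.0
    samples: int = 120
    n_theta: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be (k, 3)")
        if len(self.control_points) < 2:
            raise ValueError("need at least 2 control points")
        if not (0.0 <= self.taper < 1.0):
            raise ValueError("taper must be in [0, 1)")
        if self.samples < 8 or self.n_theta < 6:
            raise ValueError("resolution too coarse (samples >= 8, n_theta >= 6)")

    def base_radius(self, s_norm: np.ndarray) -> np.ndarray:
        if callable(self.radius):
            r = np.asarray(self.radius(s_norm), dtype=float)
        else:
            r = np.full_like(np.asarray(s_norm, float), float(self.radius))
        r = r * (1.0 - self.taper * np.asarray(s_norm))
        if np.any(r <= 0):
            raise ValueError("radius profile must be strictly positive")
        return r


@dataclass
class GroundTruth:
    """Analytic descriptors of a generated appendage."""

    L: float
    D: float
    chi: float
    volume: float
    lateral_area: float


@dataclass
class PortSpec:
    direction: np.ndarray  # unit vector from chamber centre
    radius: float          # port radius in cm
    length: float = 0.0    # tube length (0 for plain holes: MV, ostium)

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("port direction must be non-zero")
        self.direction = self.direction / n
        if self.radius <= 0:
            raise ValueError("port radius must be positive")


@dataclass
class TemplateLASpec:
    """Ellipsoid chamber + 4 PV tubes + MV port + ostium port."""

    semi_axes: tuple[float, float, float] = (3.4, 2.8, 2.5)
    pv_ports: dict[str, PortSpec] = field(default_factory=lambda: {
        "PV1": PortSpec(np.array([0.55, 0.65, 0.52]), 0.55, 1.2),
        "PV2": PortSpec(np.array([-0.50, 0.70, 0.50]), 0.55, 1.2),
        "PV3": PortSpec(np.array([0.60, 0.62, -0.55]), 0.55, 1.2),
        "PV4": PortSpec(np.array([-0.55, 0.66, -0.52]), 0.55, 1.2),
    })
    mv_port: PortSpec = field(default_factory=lambda: PortSpec(np.array([0.0, -1.0, 0.1]), 1.2))
    # the appendage ostium sits between the left PVs and the mitral
    # annulus, inside the transiting E-wave flow path
    ostium_port: PortSpec = field(default_factory=lambda: PortSpec(np.array([-0.85, -0.38, 0.25]), 0.68))
    subdivisions: int = 4

    def all_ports(self) -> dict[str, PortSpec]:
        return {**self.pv_ports, "MV": self.mv_port, "OSTIUM": self.ostium_port}

    def validate(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        ports = self.all_ports()
        names = list(ports)
        scale = np.asarray(self.semi_axes)
        centers = {n: ports[n].direction * scale for n in names}
        for i, ni in enumerate(names):
            for nj in names[i + 1:]:
                d = np.linalg.norm(centers[ni] - centers[nj])
                if d < 1.35 * (ports[ni].radius + ports[nj].radius):
                    raise ValueError(f"ports {ni} and {nj} overlap on the chamber surface")


# ---------------------------------------------------------------------------
# Swept-tube appendage
# ---------------------------------------------------------------------------


def _spline_through(points: np.ndarray, n_dense: int = 2000):
    """Arclength-parameterized cubic spline through the control points."""
    if len(points) == 2:
        # degenerate: straight segment
        t = np.array([0.0, 1.0])
        cs = CubicSpline(t, points, bc_type="natural")
    else:
        chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(chord)])
        t /= t[-1]
        cs = CubicSpline(t, points, bc_type="natural")
    td = np.linspace(0.0, 1.0, n_dense)
    p = cs(td)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return cs, td, s


def _sample_by_arclength(cs, td, s, n: int):
    """Sample the spline at n points uniform in arclength; returns points,
    unit tangents and arclength values."""
    s_targets = np.linspace(0.0, s[-1], n)
    t_of_s = np.interp(s_targets, s, td)
    p = cs(t_of_s)
    tan = cs(t_of_s, 1)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return p, tan, s_targets


def _rmf_frames(points: np.ndarray, tangents: np.ndarray) -> np.ndarray:
    """Rotation-minimizing frames via the double-reflection method."""
    n = len(points)
    normals = np.empty((n, 3))
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    r0 = ref - np.dot(ref, t0) * t0
    normals[0] = r0 / np.linalg.norm(r0)
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-30:
            normals[i + 1] = normals[i]
            continue
        rl = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tl = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tl
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            normals[i + 1] = rl
        else:
            normals[i + 1] = rl - (2.0 / c2) * np.dot(v2, rl) * v2
        normals[i + 1] /= np.linalg.norm(normals[i + 1])
    return normals


def _effective_radius(spec: LAACurveSpec, s: np.ndarray, L: float) -> np.ndarray:
    """Radius profile with the distal spherical rounding applied."""
    r = spec.base_radius(s / L)
    r_end = float(spec.base_radius(np.array([1.0]))[0])
    # radius at the start of the rounding zone sets the cap radius
    s_c = L - r_end
    out = r.copy()
    zone = s > s_c
    if np.any(zone):
        r_cap = float(np.interp(s_c, s, r)) if s.ndim else r_end
        frac = np.clip((s[zone] - s_c) / r_cap, 0.0, 1.0)
        out[zone] = r_cap * np.sqrt(np.maximum(1.0 - frac**2, 0.0))
    return out


def _check_clearance(points: np.ndarray, s: np.ndarray, radii: np.ndarray) -> None:
    """Reject self-intersecting tubes: non-adjacent centerline samples must
    stay farther apart than the sum of their tube radii."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    ds = np.abs(s[:, None] - s[None, :])
    rsum = radii[:, None] + radii[None, :]
    # only pairs far apart along the curve can collide
    mask = ds > 2.0 * rsum
    bad = mask & (d < rsum)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"self-intersecting tube: centerline samples at s={s[i]:.2f} and "
            f"s={s[j]:.2f} cm are {d[i, j]:.3f} cm apart but tube radii sum to {rsum[i, j]:.3f} cm"
        )


def make_parametric_laa(spec: LAACurveSpec) -> tuple[TriSurfaceMesh, GroundTruth]:
    """Build an open-rim appendage tube; the only boundary loop is the ostium.

    Returns the mesh plus ground truth: L (spline arclength), D (endpoint
    distance), chi = L/D - 1, and quadrature volume / lateral area of the
    swept solid.
    """
    cs, td, s_dense = _spline_through(spec.control_points)
    L = float(s_dense[-1])
    p0 = cs(0.0)
    p1 = cs(1.0)
    D = float(np.linalg.norm(p1 - p0))
    if D < 1e-12:
        raise ValueError("curve endpoints coincide; tortuosity undefined")
    chi = L / D - 1.0

    # ground-truth volume / lateral area by fine quadrature of the profile
    s_fine = np.linspace(0.0, L, 4000)
    r_fine = _effective_radius(spec, s_fine, L)
    volume = float(np.trapezoid(np.pi * r_fine**2, s_fine))
    drds = np.gradient(r_fine, s_fine)
    lateral = float(np.trapezoid(2.0 * np.pi * r_fine * np.sqrt(1.0 + drds**2), s_fine))

    pts, tans, s_ax = _sample_by_arclength(cs, td, s_dense, spec.samples)
    radii = _effective_radius(spec, s_ax, L)
    _check_clearance(pts, s_ax, np.maximum(radii, 1e-6))
    normals = _rmf_frames(pts, tans)
    binormals = np.cross(tans, normals)

    m = spec.n_theta
    theta = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    # rings: skip the final (zero-radius) sample; close with an apex vertex
    n_rings = spec.samples - 1
    ring_pts = (
        pts[:n_rings, None, :]
        + radii[:n_rings, None, None] * (ct[None, :, None] * normals[:n_rings, None, :]
                                         + st[None, :, None] * binormals[:n_rings, None, :])
    )
    verts = ring_pts.reshape(-1, 3)
    apex = pts[-1]
    verts = np.vstack([verts, apex[None, :]])
    apex_idx = len(verts) - 1

    faces = []
    for i in range(n_rings - 1):
        a = i * m + np.arange(m)
        b = i * m + (np.arange(m) + 1) % m
        c = (i + 1) * m + np.arange(m)
        d = (i + 1) * m + (np.arange(m) + 1) % m
        faces.append(np.column_stack([a, c, b]))
        faces.append(np.column_stack([b, c, d]))
    last = (n_rings - 1) * m
    a = last + np.arange(m)
    b = last + (np.arange(m) + 1) % m
    faces.append(np.column_stack([a, np.full(m, apex_idx), b]))
    faces = np.vstack(faces)
    # outward orientation (positive signed volume once the rim is capped)
    faces = faces[:, [0, 2, 1]]

    mesh = TriSurfaceMesh(verts, faces)
    loops = boundary_loops(mesh)
    if len(loops) != 1:
        raise ValueError(f"generated tube has {len(loops)} boundary loops, expected 1")
    mesh.port_loops["OSTIUM"] = loops[0]
    return mesh, GroundTruth(L=L, D=D, chi=chi, volume=volume, lateral_area=lateral)


# ---------------------------------------------------------------------------
# Template atrium
# ---------------------------------------------------------------------------


def _orthonormal_frame(n: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, n)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def _order_loop(loop_edges: np.ndarray) -> np.ndarray:
    nxt = {int(a): int(b) for a, b in loop_edges}
    start = int(loop_edges[0, 0])
    out = [start]
    cur = nxt[start]
    while cur != start:
        out.append(cur)
        cur = nxt[cur]
    return np.array(out, dtype=np.int64)


def make_template_la(spec: TemplateLASpec | None = None) -> TriSurfaceMesh:
    """Ellipsoidal chamber with six open ports (PV1-4 tubes, MV, OSTIUM).

    PV holes are extruded into open tubes; the MV and ostium are plain
    circular apertures.  Rim vertices of every port are projected onto an
    exact circle so grafting and capping operate on clean loops.
    """
    spec = spec or TemplateLASpec()
    spec.validate()
    scale = np.asarray(spec.semi_axes, dtype=float)
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float) * scale
    faces = np.asarray(ico.faces, dtype=np.int64)

    ports = spec.all_ports()
    port_center = {}
    port_normal = {}
    for name, p in ports.items():
        # point on the ellipsoid surface along the port direction
        c = p.direction * (1.0 / np.linalg.norm(p.direction / scale))
        port_center[name] = c
        n = c / scale**2  # ellipsoid outward normal direction
        port_normal[name] = n / np.linalg.norm(n)

    # punch holes: drop faces whose centroid is within hole radius of the center
    keep = np.ones(len(faces), dtype=bool)
    for name, p in ports.items():
        cdist = np.linalg.norm(verts[faces].mean(axis=1) - port_center[name], axis=1)
        hole = cdist < p.radius
        keep &= ~hole
    faces = faces[keep]

    mesh = TriSurfaceMesh(verts, faces)
    loops = boundary_loops(mesh)
    if len(loops) != len(ports):
        raise ValueError(
            f"port punching produced {len(loops)} holes for {len(ports)} ports; "
            "ports too close or chamber resolution too coarse"
        )
    # associate each loop with the nearest port center
    assign = {}
    for loop in loops:
        lc = verts[loop].mean(axis=0)
        name = min(ports, key=lambda n: np.linalg.norm(lc - port_center[n]))
        if name in assign:
            raise ValueError("two holes mapped to the same port; ports overlap")
        assign[name] = loop

    # circularize rims and extrude PV tubes
    verts = mesh.vertices.copy()
    faces = [mesh.faces]
    port_loops: dict[str, np.ndarray] = {}
    for name, p in ports.items():
        loop = assign[name]
        n = port_normal[name]
        t1, t2 = _orthonormal_frame(n)
        ring = verts[loop]
        center = ring.mean(axis=0)
        rel = ring - center
        ang = np.arctan2(rel @ t2, rel @ t1)
        verts[loop] = center + p.radius * (
            np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2
        )
        if p.length > 0:
            # extrude rings toward +n ending with a perfect circle
            m = len(loop)
            k_rings = max(3, int(np.ceil(p.length / (0.5 * p.radius))))
            prev = loop
            for k in range(1, k_rings + 1):
                f = k / k_rings
                ring_k = (
                    center + f * p.length * n
                    + p.radius * (np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2)
                )
                base = len(verts)
                verts = np.vstack([verts, ring_k])
                idx = base + np.arange(m)
                a, b = prev, np.roll(prev, -1)
                c, d = idx, np.roll(idx, -1)
                # rim loop direction follows face winding of the hole boundary;
                # extruded band must continue that winding
                faces.append(np.column_stack([b, a, c]))
                faces.append(np.column_stack([b, c, d]))
                prev = idx
            port_loops[name] = prev
        else:
            port_loops[name] = loop

    out = TriSurfaceMesh(verts, np.vstack(faces))
    # re-derive loop ordering from the final connectivity so directions are
    # consistent with face winding
    final_loops = boundary_loops(out)
    sets = {frozenset(int(x) for x in l): l for l in final_loops}
    for name, loop in port_loops.items():
        out.port_loops[name] = sets[frozenset(int(x) for x in loop)]
    if len(out.port_loops) != 6:
        raise ValueError("template must end up with exactly 6 tagged ports")
    return out


def make_straight_vessel(
    radius: float = 0.5,
    length: float = 5.0,
    n_theta: int = 32,
    axial_spacing: float = 0.15,
    inlet_name: str = "PV1",
    outlet_name: str = "MV",
) -> TriSurfaceMesh:
    """Open straight tube along +z with tagged inlet (z=0) and outlet rims.

    A verification geometry for the flow solver (steady duct flow has the
    analytic Poiseuille solution); cap the ports before volume meshing.
    """
    n_rings = max(2, int(round(length / axial_spacing)) + 1)
    z = np.linspace(0.0, length, n_rings)
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rings = np.stack([
        np.repeat(radius * np.cos(th)[None, :], n_rings, axis=0),
        np.repeat(radius * np.sin(th)[None, :], n_rings, axis=0),
        np.repeat(z[:, None], n_theta, axis=1),
    ], axis=-1)
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n_rings - 1):
        a = i * n_theta + np.arange(n_theta)
        b = i * n_theta + (np.arange(n_theta) + 1) % n_theta
        c = a + n_theta
        d = b + n_theta
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([b, d, c]))
    mesh = TriSurfaceMesh(verts, np.vstack(faces))
    loops = boundary_loops(mesh)
    z_means = [mesh.vertices[l][:, 2].mean() for l in loops]
    mesh.port_loops[inlet_name] = loops[int(np.argmin(z_means))]
    mesh.port_loops[outlet_name] = loops[int(np.argmax(z_means))]
    return mesh


# ---------------------------------------------------------------------------
# Study set
# ---------------------------------------------------------------------------


def _solve_bend_angle(chi: float) -> float:
    """Arc bend angle phi with L/D = (phi/2)/sin(phi/2) = 1 + chi."""
    target = 1.0 + chi
    lo_a, hi_a = 1e-6, 2.0 * np.pi - 1e-3
    for _ in range(80):
        mid = 0.5 * (lo_a + hi_a)
        val = (mid / 2.0) / np.sin(mid / 2.0)
        if val < target:
            lo_a = mid
        else:
            hi_a = mid
    return 0.5 * (lo_a + hi_a)


def _arc_control_points(L: float, chi: float, n_ctrl: int, rng: np.random.Generator,
                        out_of_plane: float) -> np.ndarray:
    """Control points of a circular arc of length L with bend set by chi,
    plus a small seeded out-of-plane perturbation."""
    if chi < 5e-3:
        t = np.linspace(0.0, L, n_ctrl)
        pts = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
    else:
        phi = _solve_bend_angle(chi)
        r = L / phi
        ang = np.linspace(0.0, phi, n_ctrl)
        pts = np.column_stack([r * np.sin(ang), r * (1.0 - np.cos(ang)), np.zeros(n_ctrl)])
    if out_of_plane > 0:
        z = out_of_plane * np.sin(np.linspace(0, np.pi, n_ctrl)) * (rng.random() - 0.5) * 2.0
        pts[:, 2] += z
    return pts


def make_study_set(
    n_variants: int = 5,
    seed: int = 0,
    template_spec: TemplateLASpec | None = None,
) -> tuple[TriSurfaceMesh, list[tuple[TriSurfaceMesh, GroundTruth, LAACurveSpec]]]:
    """Template atrium plus ``n_variants`` appendages spanning the study's
    geometric ranges: tortuosity at least [0.03, 0.46] and centerline length
    at least [2.3, 3.5] cm, with monotonically increasing tortuosity.
    """
    if n_variants < 2:
        raise ValueError("n_variants must be >= 2")
    rng = np.random.default_rng(seed)
    template = make_template_la(template_spec)
    chi_targets = np.linspace(0.015, 0.50, n_variants)
    L_targets = np.linspace(2.3, 3.5, n_variants)
    volumes = rng.uniform(2.0, 2.6, size=n_variants)
    tapers = np.linspace(0.0, 0.35, n_variants)
    out = []
    for i in range(n_variants):
        sub = np.random.default_rng(seed * 100003 + i)
        ctrl = _arc_control_points(
            L_targets[i], chi_targets[i], n_ctrl=7, rng=sub,
            out_of_plane=0.15 * chi_targets[i] * L_targets[i],
        )
        # base radius set so the swept volume hits the target (V scales r^2
        # up to the cap correction; two fixed-point passes suffice)
        r0 = 0.5
        for _ in range(3):
            spec = LAACurveSpec(ctrl, radius=r0, taper=tapers[i], seed=seed)
            cs, td, s_dense = _spline_through(spec.control_points)
            L = s_dense[-1]
            s_f = np.linspace(0, L, 2000)
            v = np.trapezoid(np.pi * _effective_radius(spec, s_f, L) ** 2, s_f)
            r0 = r0 * np.sqrt(volumes[i] / v)
            r0 = float(np.clip(r0, 0.30, 0.62))
        spec = LAACurveSpec(ctrl, radius=r0, taper=tapers[i], seed=seed)
        mesh, gt = make_parametric_laa(spec)
        out.append((mesh, gt, spec))
    chis = [gt.chi for _, gt, _ in out]
    if any(np.diff(chis) <= 0):
        raise RuntimeError("study-set tortuosity not monotone; adjust targets")
    return template, out
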