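"""Geometric descriptors of an appendage: V, A_s, A_o, P_o, L and tortuosity.

The centerline runs from the ostium-rim barycenter to the apex through the
lumen: a marching tracer steps along the tube in increments of the local
wall clearance, relaxing each point onto the medial axis (maximum-clearance
channel) in the plane perpendicular to the heading, and closes the line on
the distal wall.  Tortuosity is chi = L/D - 1 with D the Euclidean distance
between the centerline endpoints; a straight duct has chi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _ray
from .mesh_core import TriSurfaceMesh, boundary_loops, cap_ports, enclosed_volume, surface_area

__all__ = [
    "Centerline",
    "LAAGeometryReport",
    "compute_centerline",
    "tortuosity",
    "orifice_metrics",
    "geometry_report",
]


@dataclass
class Centerline:
    points: np.ndarray   # ordered polyline, first point = ostium barycenter
    L: float             # arclength, cm
    D: float             # endpoint Euclidean distance, cm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.D <= 0:
            raise ValueError("degenerate centerline: endpoint distance must be positive")


@dataclass
class LAAGeometryReport:
    V: float       # volume, cm^3
    A_s: float     # lateral surface area (ostium aperture excluded), cm^2
    A_o: float     # orifice area, cm^2
    P_o: float     # orifice perimeter, cm
    L: float       # centerline length, cm
    chi: float     # tortuosity, dimensionless

    def validate(self) -> None:
        vals = [self.V, self.A_s, self.A_o, self.P_o, self.L]
        if any(v <= 0 for v in vals):
            raise ValueError("all geometric descriptors must be positive")
        if self.chi < 0:
            raise ValueError("tortuosity cannot be negative")
        if self.P_o**2 < 4.0 * np.pi * self.A_o * (1.0 - 1e-9):
            raise ValueError("isoperimetric inequality violated for the orifice rim")


def tortuosity(c: Centerline) -> float:
    """chi = L/D - 1."""
    if c.D <= 0:
        raise ValueError("closed-loop centerline: D = 0")
    return c.L / c.D - 1.0


def _rim_loop(laa: TriSurfaceMesh) -> np.ndarray:
    if "OSTIUM" in laa.port_loops:
        return laa.port_loops["OSTIUM"]
    loops = boundary_loops(laa)
    if len(loops) != 1:
        raise ValueError(f"appendage must have exactly one rim (found {len(loops)})")
    return loops[0]


def orifice_metrics(rim_points: np.ndarray) -> tuple[float, float]:
    """(A_o, P_o) of a simple closed rim loop.

    Perimeter is the polygon length; area is the shoelace area of the loop
    projected onto its least-squares plane.  If the projection
    self-intersects, the cross-product fan area about the barycenter is
    used instead.
    """
    p = np.asarray(rim_points, dtype=float)
    if len(p) < 3:
        raise ValueError("rim loop needs at least 3 points")
    per = float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())
    c = p.mean(axis=0)
    _, _, Vt = np.linalg.svd(p - c, full_matrices=False)
    u = (p - c) @ Vt[0]
    v = (p - c) @ Vt[1]
    if _polygon_self_intersects(u, v):
        fan = 0.5 * np.linalg.norm(
            np.cross(p - c, np.roll(p, -1, axis=0) - c).sum(axis=0))
        return float(fan), per
    area = 0.5 * abs(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))
    return float(area), per


def _polygon_self_intersects(u: np.ndarray, v: np.ndarray) -> bool:
    n = len(u)
    x1, y1 = u, v
    x2, y2 = np.roll(u, -1), np.roll(v, -1)

    def ccw(ax, ay, bx, by, cx, cy):
        return (by - ay) * (cx - ax) - (bx - ax) * (cy - ay)

    for i in range(n):
        js = np.arange(i + 2, n if i > 0 else n - 1)
        if len(js) == 0:
            continue
        d1 = ccw(x1[i], y1[i], x2[i], y2[i], x1[js], y1[js])
        d2 = ccw(x1[i], y1[i], x2[i], y2[i], x2[js], y2[js])
        d3 = ccw(x1[js], y1[js], x2[js], y2[js], x1[i], y1[i])
        d4 = ccw(x1[js], y1[js], x2[js], y2[js], x2[i], y2[i])
        if np.any((d1 * d2 < 0) & (d3 * d4 < 0)):
            return True
    return False


def compute_centerline(
    laa: TriSurfaceMesh,
    spacing: float | None = None,
    smooth_passes: int = 4,
) -> Centerline:
    """Lumen centerline from the ostium barycenter to the apex.

    A channel tracer marches from the ostium into the lumen: each step
    advances by a fraction of the local wall clearance and is recentered
    onto the medial axis in the plane perpendicular to the heading.  The
    march ends when the distal cap is reached (wall directly ahead, abrupt
    clearance drop, or heading reversal), and the polyline is closed on the
    wall, lightly smoothed and re-parameterized by arclength.
    """
    rim = _rim_loop(laa)
    capped = cap_ports(laa, ports=None)
    rim_pts = laa.vertices[rim]
    rim_bary = rim_pts.mean(axis=0)

    a_o = orifice_metrics(rim_pts)[0]
    r_o = float(np.sqrt(a_o / np.pi))

    # dense wall samples for clearance queries (the open rim is an
    # aperture, not wall, so only the lateral surface contributes)
    surf_samples = np.vstack([laa.vertices, laa.face_centroids()])
    tree = cKDTree(surf_samples)

    # initial heading: into the lumen, perpendicular to the rim plane
    _, _, Vt = np.linalg.svd(rim_pts - rim_bary, full_matrices=False)
    n = Vt[-1]
    body_side = laa.vertices.mean(axis=0) - rim_bary
    if np.dot(n, body_side) < 0:
        n = -n

    def clearance(p: np.ndarray) -> float:
        return float(tree.query(p)[0])

    def recenter(p: np.ndarray, t: np.ndarray, iters: int = 8) -> np.ndarray:
        for _ in range(iters):
            d, j = tree.query(p)
            g = p - tree.data[j]
            gn = np.linalg.norm(g)
            if gn < 1e-12:
                break
            g /= gn
            g_perp = g - np.dot(g, t) * t
            step = 0.3 * d * g_perp
            if np.linalg.norm(step) < 1e-5:
                break
            p = p + step
        return p

    def wall_ahead(p: np.ndarray, t: np.ndarray) -> float:
        th, fh = _ray.raycast_nearest(
            p[None, :], t[None, :], capped.vertices, capped.faces)
        return float(th[0]) if fh[0] >= 0 else np.inf

    poly = [rim_bary]
    t = n
    p = rim_bary + 0.25 * r_o * t
    p = recenter(p, t)
    poly.append(p)
    for _ in range(400):
        c = clearance(p)
        ahead = wall_ahead(p, t)
        if ahead <= max(c, 0.05):
            break  # the cap is ahead: close the line on the wall
        delta = min(0.4 * max(c, 0.02), 0.5 * ahead)
        q = p + delta * t
        q = recenter(q, t)
        if clearance(q) < 0.7 * c:
            break  # abrupt narrowing: inside the distal cap
        t_new = q - p
        nrm = np.linalg.norm(t_new)
        if nrm < 1e-9:
            break
        t_new /= nrm
        if np.dot(t_new, t) < 0.2:
            break  # heading reversal: the channel has ended (cap region)
        # limit turning to suppress recentering jitter
        t = 0.8 * t_new + 0.2 * t
        t /= np.linalg.norm(t)
        p = q
        poly.append(p)
    # close the line on the cap along the local path tangent
    if len(poly) >= 3:
        t_loc = poly[-1] - poly[-3]
        t_loc /= max(np.linalg.norm(t_loc), 1e-300)
    else:
        t_loc = t
    ahead = wall_ahead(p, t_loc)
    if np.isfinite(ahead) and ahead <= 4.0 * clearance(p):
        poly.append(p + ahead * t_loc)
    poly = np.asarray(poly)
    if len(poly) < 3:
        raise ValueError("centerline tracing failed: lumen too shallow")

    poly = _resample_polyline(poly, max(24, len(poly)))
    for _ in range(smooth_passes):
        poly[1:-1] = 0.6 * poly[1:-1] + 0.2 * (poly[:-2] + poly[2:])

    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    L = float(seg.sum())
    D = float(np.linalg.norm(poly[-1] - poly[0]))
    return Centerline(points=poly, L=L, D=D)


def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return poly
    st = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(st, s, poly[:, k])
    return out


def geometry_report(laa: TriSurfaceMesh, centerline: Centerline | None = None) -> LAAGeometryReport:
    """Assemble the full descriptor set for an open-rim appendage mesh."""
    rim = _rim_loop(laa)
    a_o, p_o = orifice_metrics(laa.vertices[rim])
    capped = cap_ports(laa, ports=None)
    vol = enclosed_volume(capped)
    lateral = surface_area(laa)   # the open mesh has no cap: lateral only
    c = centerline if centerline is not None else compute_centerline(laa)
    chi = tortuosity(c)
    rep = LAAGeometryReport(V=vol, A_s=lateral, A_o=a_o, P_o=p_o, L=c.L, chi=max(chi, 0.0))
    rep.validate()
    return rep
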