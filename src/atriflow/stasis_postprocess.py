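"""Stasis indicators derived from a flow series: vortices, ostium velocity
and Lagrangian particle residence.

Q-criterion
    Computed per cell from the P1 velocity gradient.  The *printed*
    convention uses S_ij = du_i/dx_j + du_j/dx_i and W_ij = du_i/dx_j -
    du_j/dx_i without the usual 1/2 factors, so Q = (W:W - S:S)/2 evaluates
    to 4 omega^2 for solid-body rotation at rate omega; the *standard*
    convention (with the 1/2 factors) gives exactly one quarter of that.
    The sign pattern — rotation-dominated Q > 0 — is identical, so vortex
    regions do not depend on the convention.

Ostium velocity
    Area-averaged normal velocity through the best-fit disc of the grafted
    rim, oriented so that emptying (flow from appendage to chamber) is
    positive.  A peak emptying velocity below 20 cm/s flags poor washout.

Particle residence
    Passive tracers seeded in a sphere about the centerline midpoint are
    integrated through the stored velocity fields (RK4, linear
    interpolation in space and time).  Wall encounters are resolved by
    snapping back into the nearest cell; particles leaving through the
    mitral outlet are frozen as departed.  Residence counts at cycle ends
    use instantaneous membership in the closed appendage region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import _ray
from .hemodynamics import FlowFieldSeries
from .laa_geometry import Centerline
from .mesh_core import TetMesh, TriSurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "QCriterionField",
    "OstiumTrace",
    "ParticleEnsemble",
    "q_criterion",
    "vortex_regions",
    "ostium_velocity",
    "seed_particles",
    "advect",
    "residence_counts",
    "residual_fraction",
]

LOW_WASHOUT_THRESHOLD = 20.0  # cm/s peak emptying velocity


@dataclass
class QCriterionField:
    values: np.ndarray     # per-cell Q, 1/s^2
    convention: str        # "printed" or "standard"


@dataclass
class OstiumTrace:
    times: np.ndarray
    velocity: np.ndarray   # cm/s; positive = emptying
    peak_emptying: float
    low_washout: bool      # peak below the 20 cm/s threshold


@dataclass
class ParticleEnsemble:
    initial: np.ndarray                 # (n0, 3)
    positions: np.ndarray               # (T, n0, 3) trajectory snapshots
    times: np.ndarray
    departed: np.ndarray                # (n0,) bool: left through the outlet
    seed: int = 0

    @property
    def n0(self) -> int:
        return len(self.initial)


# ---------------------------------------------------------------------------
# Vortex identification
# ---------------------------------------------------------------------------


def _velocity_gradients(mesh: TetMesh, u: np.ndarray) -> np.ndarray:
    """Per-cell velocity gradient tensors G_ij = du_i/dx_j from P1 fields."""
    v = mesh.vertices
    t = mesh.tets
    x0 = v[t[:, 0]]
    J = np.stack([v[t[:, 1]] - x0, v[t[:, 2]] - x0, v[t[:, 3]] - x0], axis=1)
    Jinv = np.linalg.inv(J)
    g = np.empty((len(t), 4, 3))
    g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return np.einsum("kvi,kvj->kij", u[t], g)


def q_criterion(mesh: TetMesh, u: np.ndarray, convention: str = "printed") -> QCriterionField:
    """Per-cell Q-criterion of a nodal velocity field.

    ``printed`` evaluates Q = (W_ij W_ij - S_ij S_ij)/2 with S and W taken
    without 1/2 factors; ``standard`` uses the conventional halved tensors
    (values exactly 4x smaller).
    """
    if convention not in ("printed", "standard"):
        raise ValueError("convention must be 'printed' or 'standard'")
    G = _velocity_gradients(mesh, np.asarray(u, dtype=float))
    S = G + np.transpose(G, (0, 2, 1))
    W = G - np.transpose(G, (0, 2, 1))
    q = 0.5 * (np.einsum("kij,kij->k", W, W) - np.einsum("kij,kij->k", S, S))
    if convention == "standard":
        q = q / 4.0
    return QCriterionField(values=q, convention=convention)


def vortex_regions(
    q: QCriterionField, mesh: TetMesh, u: np.ndarray | None = None
) -> list[dict]:
    """Connected cell regions with Q > 0, largest volume first.

    Each region dict carries ``cells``, ``volume`` and, when a velocity
    field is supplied, ``mean_speed``.
    """
    pos = q.values > 0.0
    n_cells = mesh.n_tets
    if not np.any(pos):
        return []
    # face-adjacency of tets: shared triangles
    face_idx = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    tri = np.sort(mesh.tets[:, face_idx].reshape(-1, 3), axis=1)
    owner = np.repeat(np.arange(n_cells), 4)
    order = np.lexsort((tri[:, 2], tri[:, 1], tri[:, 0]))
    ts, to = tri[order], owner[order]
    same = np.all(ts[1:] == ts[:-1], axis=1)
    a, b = to[:-1][same], to[1:][same]
    keep = pos[a] & pos[b]
    g = coo_matrix((np.ones(int(keep.sum())), (a[keep], b[keep])), shape=(n_cells, n_cells))
    _, comp = connected_components(g, directed=False)
    vols = _tet_volumes(mesh)
    out = []
    for rid in np.unique(comp[pos]):
        cells = np.flatnonzero(pos & (comp == rid))
        region = {"cells": cells, "volume": float(vols[cells].sum())}
        if u is not None:
            speeds = np.linalg.norm(np.asarray(u)[mesh.tets[cells]].mean(axis=1), axis=1)
            region["mean_speed"] = float(speeds.mean())
        out.append(region)
    out.sort(key=lambda r: r["volume"], reverse=True)
    return out


def _tet_volumes(mesh: TetMesh) -> np.ndarray:
    v = mesh.vertices
    t = mesh.tets
    return np.abs(np.einsum(
        "ij,ij->i",
        np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]),
        v[t[:, 3]] - v[t[:, 0]])) / 6.0


# ---------------------------------------------------------------------------
# Ostium section and velocity trace
# ---------------------------------------------------------------------------


@dataclass
class OstiumSection:
    """Triangulated best-fit disc spanning the grafted rim."""

    points: np.ndarray      # sample points on the disc
    weights: np.ndarray     # area weights of the samples
    normal: np.ndarray      # unit normal, oriented appendage -> chamber
    center: np.ndarray


def ostium_section(
    rim_points: np.ndarray, chamber_side_point: np.ndarray, n_radial: int = 6
) -> OstiumSection:
    """Build the sampling disc of the ostium plane.

    ``chamber_side_point`` (e.g. the chamber centroid) orients the normal
    so that emptying velocities come out positive.
    """
    rim = np.asarray(rim_points, dtype=float)
    c = rim.mean(axis=0)
    _, _, Vt = np.linalg.svd(rim - c, full_matrices=False)
    nrm = Vt[-1]
    if np.dot(nrm, np.asarray(chamber_side_point) - c) < 0:
        nrm = -nrm
    r = float(np.linalg.norm(rim - c, axis=1).mean())
    t1, t2 = Vt[0], Vt[1]
    pts, wts = [], []
    for i in range(1, n_radial + 1):
        ri = r * (i - 0.5) / n_radial
        m = max(6, int(np.ceil(2 * np.pi * i)))
        th = np.linspace(0, 2 * np.pi, m, endpoint=False)
        ring = c + ri * (np.cos(th)[:, None] * t1 + np.sin(th)[:, None] * t2)
        area = np.pi * r**2 * ((i / n_radial) ** 2 - ((i - 1) / n_radial) ** 2) / m
        pts.append(ring)
        wts.append(np.full(m, area))
    return OstiumSection(
        points=np.vstack(pts), weights=np.concatenate(wts), normal=nrm, center=c)


class CellLocator:
    """Point-in-tet lookup via nearest-centroid candidates."""

    def __init__(self, mesh: TetMesh, k: int = 24):
        self.mesh = mesh
        v = mesh.vertices
        t = mesh.tets
        self.centroids = v[t].mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(t))
        x0 = v[t[:, 0]]
        J = np.stack([v[t[:, 1]] - x0, v[t[:, 2]] - x0, v[t[:, 3]] - x0], axis=1)
        self.Jinv = np.linalg.inv(J)
        self.x0 = x0

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(cell index or -1, barycentric coords of the last 3 vertices)."""
        points = np.asarray(points, dtype=float)
        npts = len(points)
        _, cand = self.tree.query(points, k=self.k)
        if self.k == 1:
            cand = cand[:, None]
        lam = np.einsum(
            "pck,pckd->pcd",
            points[:, None, :] - self.x0[cand],
            self.Jinv[cand])
        lam0 = 1.0 - lam.sum(axis=2)
        ok = (lam >= -1e-9).all(axis=2) & (lam0 >= -1e-9)
        first = np.argmax(ok, axis=1)
        found = ok[np.arange(npts), first]
        cells = np.where(found, cand[np.arange(npts), first], -1)
        bary = lam[np.arange(npts), first]
        return cells, bary

    def interpolate(self, u: np.ndarray, points: np.ndarray):
        """Linear interpolation of a nodal field; also returns the miss mask."""
        cells, bary = self.locate(points)
        miss = cells < 0
        safe = np.where(miss, 0, cells)
        tets = self.mesh.tets[safe]
        w = np.concatenate([(1.0 - bary.sum(axis=1))[:, None], bary], axis=1)
        vals = np.einsum("pv,pvd->pd", w, np.asarray(u)[tets])
        vals[miss] = 0.0
        return vals, miss


def ostium_velocity(
    series: FlowFieldSeries,
    section: OstiumSection,
    locator: CellLocator | None = None,
) -> OstiumTrace:
    """Area-averaged normal velocity through the ostium section over time."""
    locator = locator or CellLocator(series.mesh)
    cells, _ = locator.locate(section.points)
    if np.all(cells < 0):
        raise ValueError("ostium section lies outside the mesh")
    wts = section.weights.copy()
    wts[cells < 0] = 0.0
    wsum = wts.sum()
    if wsum <= 0:
        raise ValueError("ostium section has no interior sample points")
    trace = np.empty(len(series.times))
    for k in range(len(series.times)):
        u, _ = locator.interpolate(series.velocities[k].astype(float), section.points)
        un = u @ section.normal
        trace[k] = float((wts * un).sum() / wsum)
    peak = float(trace.max()) if len(trace) else 0.0
    return OstiumTrace(
        times=series.times.copy(),
        velocity=trace,
        peak_emptying=peak,
        low_washout=peak < LOW_WASHOUT_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# Particles
# ---------------------------------------------------------------------------


def seed_particles(
    laa_region: TriSurfaceMesh,
    centerline: Centerline,
    n: int = 500,
    seed: int = 0,
    max_radius_factor: float = 0.8,
) -> np.ndarray:
    """Initial particle positions: uniform in the largest sphere centred at
    the centerline midpoint that fits inside the appendage lumen.

    ``laa_region`` must be the closed appendage surface (rim capped).
    Returns an (n, 3) array; all points are strictly inside.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    pts = centerline.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    c = np.empty(3)
    for k in range(3):
        c[k] = np.interp(0.5 * s[-1], s, pts[:, k])

    samples = np.vstack([laa_region.vertices, laa_region.face_centroids()])
    clearance = float(cKDTree(samples).query(c)[0])
    radius = max_radius_factor * clearance
    if radius < 1e-3:
        raise ValueError("degenerate lumen: inscribed seeding ball is too small")

    rng = np.random.default_rng(seed)
    out = np.empty((n, 3))
    have = 0
    guard = 0
    while have < n and guard < 200:
        m = 2 * (n - have) + 16
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = radius * rng.random(m) ** (1.0 / 3.0)
        cand = c + u * r[:, None]
        inside = _ray.points_inside(cand, laa_region.vertices, laa_region.faces)
        take = min(int(inside.sum()), n - have)
        out[have:have + take] = cand[inside][:take]
        have += take
        guard += 1
    if have < n:
        raise ValueError("could not place all particles inside the lumen")
    return out


def advect(
    series: FlowFieldSeries,
    positions0: np.ndarray,
    outlet_patch: str = "MV",
    record_every: int = 4,
    seed: int = 0,
) -> ParticleEnsemble:
    """RK4 advection of passive tracers through the stored velocity series.

    Particles whose step leaves the mesh are snapped back to the nearest
    cell centroid offset (wall encounter) unless the exit is through the
    outlet patch, in which case they are frozen as departed.
    """
    mesh = series.mesh
    locator = CellLocator(mesh)
    times = series.times
    dt = float(times[1] - times[0]) if len(times) > 1 else series.config.dt
    pos = np.array(positions0, dtype=float)
    npart = len(pos)
    departed = np.zeros(npart, dtype=bool)

    out_faces = mesh.patch_faces(outlet_patch)
    out_nodes = np.unique(out_faces)
    out_center = mesh.vertices[out_nodes].mean(axis=0)
    fn = np.cross(
        mesh.vertices[out_faces[:, 1]] - mesh.vertices[out_faces[:, 0]],
        mesh.vertices[out_faces[:, 2]] - mesh.vertices[out_faces[:, 0]])
    out_normal = fn.sum(axis=0)
    out_normal /= max(np.linalg.norm(out_normal), 1e-300)
    out_radius = 2.0 * float(
        np.linalg.norm(mesh.vertices[out_nodes] - out_center, axis=1).max())

    snap_count = 0
    rec_pos = [pos.copy()]
    rec_t = [float(times[0])]

    def field_at(t: float) -> np.ndarray:
        return series.velocity_at(t)

    for k in range(len(times) - 1):
        t0 = float(times[k])
        u_a = field_at(t0)
        u_m = field_at(t0 + 0.5 * dt)
        u_b = field_at(t0 + dt)
        alive = ~departed
        if np.any(alive):
            p = pos[alive]
            k1, _ = locator.interpolate(u_a, p)
            k2, _ = locator.interpolate(u_m, p + 0.5 * dt * k1)
            k3, _ = locator.interpolate(u_m, p + 0.5 * dt * k2)
            k4, _ = locator.interpolate(u_b, p + dt * k3)
            newp = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            cells, _ = locator.locate(newp)
            lost = cells < 0
            if np.any(lost):
                lp = newp[lost]
                # exit through the outlet: near its plane and disc
                d_out = (lp - out_center) @ out_normal
                r_out = np.linalg.norm(
                    lp - out_center - np.outer(d_out, out_normal), axis=1)
                exit_mv = (d_out > -0.25) & (r_out < out_radius)
                # otherwise: wall encounter, snap to nearest cell interior
                snap = lp[~exit_mv]
                if len(snap):
                    _, near = locator.tree.query(snap)
                    lp[~exit_mv] = 0.5 * (snap + locator.centroids[near])
                    snap_count += len(snap)
                newp[lost] = lp
                alive_idx = np.flatnonzero(alive)
                departed[alive_idx[np.flatnonzero(lost)[exit_mv]]] = True
            pos[alive] = newp
        if (k + 1) % record_every == 0 or k == len(times) - 2:
            rec_pos.append(pos.copy())
            rec_t.append(float(times[k + 1]))
    if snap_count:
        logger.info("advect: %d wall-snap events", snap_count)
    return ParticleEnsemble(
        initial=np.array(positions0, dtype=float),
        positions=np.array(rec_pos),
        times=np.array(rec_t),
        departed=departed,
        seed=seed,
    )


def residence_counts(
    ensemble: ParticleEnsemble,
    laa_region: TriSurfaceMesh,
    cycle_ends: list[float],
    mode: str = "membership",
) -> dict[float, int]:
    """Particles inside the closed appendage region at each cycle end.

    ``membership`` counts instantaneous containment (a particle may leave
    and re-enter); ``first_exit`` counts particles that have never left the
    region up to that time.
    """
    if mode not in ("membership", "first_exit"):
        raise ValueError("mode must be 'membership' or 'first_exit'")
    out: dict[float, int] = {}
    ever_left = np.zeros(ensemble.n0, dtype=bool)
    checked = 0
    for t_end in sorted(cycle_ends):
        j = int(np.argmin(np.abs(ensemble.times - t_end)))
        if mode == "first_exit":
            for jj in range(checked, j + 1):
                inside_now = _ray.points_inside(
                    ensemble.positions[jj], laa_region.vertices, laa_region.faces)
                ever_left |= ~inside_now
            checked = j + 1
            out[t_end] = int((~ever_left).sum())
        else:
            inside = _ray.points_inside(
                ensemble.positions[j], laa_region.vertices, laa_region.faces)
            out[t_end] = int(inside.sum())
    return out


def residual_fraction(count: int, n0: int) -> float:
    """Residual particle percentage, rounded to one decimal."""
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if not (0 <= count <= n0):
        raise ValueError("count must lie in [0, n0]")
    return round(100.0 * count / n0, 1)
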