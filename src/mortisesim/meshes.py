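"""Minimal triangle-mesh container and geometric predicates.

Everything downstream (synthetic anatomy, collision resolution, virtual
radiography) works on plain indexed triangle meshes.  This module provides
the small set of exact geometric operations the pipeline needs --
watertightness and orientation checks, signed volume, plane sections, point
containment by ray parity, surface-intersection tests with broad-phase
pruning -- plus STL/OBJ round-tripping, all vectorised with numpy/scipy.

Conventions: vertices are float64 in millimetres; faces are CCW-wound with
outward normals (signed volume positive).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "GeometryError",
    "make_uv_sphere",
    "make_tube",
    "mesh_overlap",
    "surfaces_intersect",
    "read_stl",
    "write_stl",
    "read_obj",
    "write_obj",
]

_EPS = 1e-12

# fixed, irrational-ish parity-ray direction: avoids axis-aligned edge grazing
_PARITY_DIR = np.array([0.2135436353, 0.5528656301, 0.8054892341])
_PARITY_DIR /= np.linalg.norm(_PARITY_DIR)


class GeometryError(ValueError):
    """Raised when a mesh does not satisfy a geometric precondition."""


@dataclass
class TriMesh:
    """Indexed triangle mesh (vertices in mm, CCW winding, outward normals)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise GeometryError("face index out of range")

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalized:
            lng = np.linalg.norm(n, axis=1, keepdims=True)
            lng[lng == 0] = 1.0
            n = n / lng
        return n

    def area(self) -> float:
        return float(np.linalg.norm(self.face_normals(normalized=False), axis=1).sum() / 2)

    def volume(self) -> float:
        """Signed volume by the divergence theorem (positive when outward-wound)."""
        tri = self.triangles()
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def edges_directed(self) -> np.ndarray:
        """(3m, 2) directed edges in winding order."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)

    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.edges_directed(), axis=1)
        return np.unique(e, axis=0)

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two faces of opposite orientation."""
        e = self.edges_directed()
        undirected = np.sort(e, axis=1)
        uniq, counts = np.unique(undirected, axis=0, return_counts=True)
        if not np.all(counts == 2):
            return False
        # orientation consistency: each directed edge must occur exactly once
        _, dcounts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(dcounts == 1))

    # -- transforms -------------------------------------------------------

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, float), self.faces.copy(), self.name)

    def transformed(self, matrix: np.ndarray) -> "TriMesh":
        """Apply a 4x4 homogeneous transform."""
        m = np.asarray(matrix, float)
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return TriMesh(v, self.faces.copy(), self.name)

    def mirrored(self, axis: int = 0) -> "TriMesh":
        """Reflect across the plane ``coord[axis] = 0`` (winding re-flipped)."""
        v = self.vertices.copy()
        v[:, axis] = -v[:, axis]
        f = self.faces[:, [0, 2, 1]].copy()
        return TriMesh(v, f, self.name)

    # -- queries ----------------------------------------------------------

    def contains(self, points) -> np.ndarray:
        """Point-in-mesh test by ray-crossing parity (mesh must be watertight)."""
        pts = np.atleast_2d(np.asarray(points, float))
        hits = _ray_hit_counts(pts, _PARITY_DIR, self.triangles())
        inside = (hits % 2) == 1
        return inside if np.asarray(points).ndim == 2 else inside

    def plane_section(self, point, normal) -> np.ndarray:
        """Intersect with a plane; returns (k, 2, 3) crossing segments."""
        p = np.asarray(point, float)
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        d = (self.vertices - p) @ n
        return _plane_cross_segments(self.vertices, self.faces, d)

    def self_intersects(self, exclude_shared_vertices: bool = True) -> bool:
        """Expensive all-pairs edge/triangle test (KD-tree pruned)."""
        return _edges_cross_triangles(
            self, self, exclude_shared=exclude_shared_vertices
        )


# ---------------------------------------------------------------------------
# constructors


def make_uv_sphere(center=(0.0, 0.0, 0.0), radii=1.0, n_theta: int = 24, n_phi: int = 48,
                   name: str = "") -> TriMesh:
    """Latitude/longitude sphere or axis-aligned ellipsoid (watertight)."""
    c = np.asarray(center, float)
    r = np.broadcast_to(np.asarray(radii, float), (3,)).astype(float)
    thetas = np.linspace(0.0, np.pi, n_theta + 1)[1:-1]  # exclude poles
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    rings = []
    for t in thetas:
        ring = np.stack(
            [r[0] * np.sin(t) * np.cos(phis), r[1] * np.sin(t) * np.sin(phis),
             np.full(n_phi, r[2] * np.cos(t))], axis=1)
        rings.append(c + ring)
    top = c + np.array([0.0, 0.0, r[2]])
    bottom = c - np.array([0.0, 0.0, r[2]])
    return mesh_from_rings(rings, cap_top_point=top, cap_bottom_point=bottom, name=name)


def make_tube(p0, p1, radius: float, n_phi: int = 48, name: str = "") -> TriMesh:
    """Capped circular cylinder from p0 to p1 (watertight)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < _EPS:
        raise GeometryError("degenerate cylinder axis")
    w = axis / length
    u = np.cross(w, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(w, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    circle = radius * (np.outer(np.cos(phis), u) + np.outer(np.sin(phis), v))
    rings = [p1 + circle, p0 + circle]      # top ring first
    return mesh_from_rings(rings, cap_top_point=p1, cap_bottom_point=p0, name=name)


def mesh_from_rings(rings, cap_top_point=None, cap_bottom_point=None, name: str = "",
                    cap_facet_mm: float = 1.5) -> TriMesh:
    """Stitch a stack of same-length rings into a watertight generalized cylinder.

    ``rings[0]`` is the *top* ring; rings must be wound CCW when viewed from
    the top (+z looking down) so that side faces come out outward-oriented
    when the stack proceeds top-to-bottom in decreasing z.  End caps are
    subdivided into concentric rings so facet size stays below
    ``cap_facet_mm`` (large cap fans would poison collision broad-phases).
    """
    rings = [np.asarray(r, float) for r in rings]
    if cap_top_point is not None:
        apex = np.asarray(cap_top_point, float)
        first = rings[0]
        rmax = float(np.linalg.norm(first - apex, axis=1).max())
        n_extra = max(int(np.ceil(rmax / cap_facet_mm)) - 1, 0)
        fracs = np.linspace(0.0, 1.0, n_extra + 2)[1:-1]
        rings = [apex + f * (first - apex) for f in fracs] + rings
    if cap_bottom_point is not None:
        apex = np.asarray(cap_bottom_point, float)
        last = rings[-1]
        rmax = float(np.linalg.norm(last - apex, axis=1).max())
        n_extra = max(int(np.ceil(rmax / cap_facet_mm)) - 1, 0)
        fracs = np.linspace(1.0, 0.0, n_extra + 2)[1:-1]
        rings = rings + [apex + f * (last - apex) for f in fracs]
    k = len(rings[0])
    if any(len(r) != k for r in rings):
        raise GeometryError("all rings must have the same number of points")
    nr = len(rings)
    verts = [np.concatenate(rings, axis=0)]
    faces = []
    for i in range(nr - 1):
        a = i * k + np.arange(k)
        b = i * k + (np.arange(k) + 1) % k
        c = (i + 1) * k + np.arange(k)
        d = (i + 1) * k + (np.arange(k) + 1) % k
        # two triangles per quad; winding chosen for outward normals
        faces.append(np.stack([a, c, b], axis=1))
        faces.append(np.stack([b, c, d], axis=1))
    n_base = nr * k
    extra = []
    if cap_top_point is not None:
        extra.append(np.asarray(cap_top_point, float)[None, :])
        top_idx = n_base + len(extra) - 1
        a = np.arange(k)
        b = (np.arange(k) + 1) % k
        faces.append(np.stack([a, b, np.full(k, top_idx)], axis=1))
    if cap_bottom_point is not None:
        extra.append(np.asarray(cap_bottom_point, float)[None, :])
        bot_idx = n_base + len(extra) - 1
        a = (nr - 1) * k + np.arange(k)
        b = (nr - 1) * k + (np.arange(k) + 1) % k
        faces.append(np.stack([b, a, np.full(k, bot_idx)], axis=1))
    verts.extend(extra)
    mesh = TriMesh(np.concatenate(verts, axis=0), np.concatenate(faces, axis=0), name)
    if mesh.volume() < 0:  # flip winding if rings were wound the other way
        mesh = TriMesh(mesh.vertices, mesh.faces[:, [0, 2, 1]], name)
    return mesh


# ---------------------------------------------------------------------------
# intersection machinery


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product (faster than np.cross for (n, 3) arrays)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _ray_hit_counts(origins: np.ndarray, direction: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Number of ray/triangle crossings (t > 0) per origin, Moller-Trumbore."""
    d = np.asarray(direction, float)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = _cross(np.broadcast_to(d, e2.shape), e2)  # (m,3)
    det = np.einsum("ij,ij->i", e1, pvec)        # (m,)
    ok = np.abs(det) > 1e-12
    counts = np.zeros(len(origins), dtype=np.int64)
    if not ok.any():
        return counts
    v0, e1, e2, pvec, det = v0[ok], e1[ok], e2[ok], pvec[ok], det[ok]
    inv = 1.0 / det
    # broadcast origins (n,1,3) against triangles (m,3)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("nmj,mj->nm", tvec, pvec) * inv
    qvec = _cross(tvec, e1[None, :, :])
    v = np.einsum("nmj,j->nm", qvec, d) * inv
    t = np.einsum("nmj,mj->nm", qvec, e2) * inv
    hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 1e-9)
    return hit.sum(axis=1)


def _plane_cross_segments(verts: np.ndarray, faces: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Crossing segments of the faces against the level set d == 0.

    Vertices lying exactly on the plane are nudged to the positive side so
    that sections through mesh rings resolve consistently.
    """
    d = np.where(np.abs(d) < 1e-9, 1e-9, d)
    fd = d[faces]                               # (m,3) signed distances
    sign = np.sign(fd)
    crossing = (sign.max(axis=1) > 0) & (sign.min(axis=1) < 0)
    segs = []
    for fi in np.nonzero(crossing)[0]:
        idx = faces[fi]
        dv = fd[fi]
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = dv[a], dv[b]
            if (da > 0 > db) or (da < 0 < db):
                t = da / (da - db)
                pts.append(verts[idx[a]] + t * (verts[idx[b]] - verts[idx[a]]))
        if len(pts) >= 2:
            segs.append(np.stack(pts[:2], axis=0))
    if not segs:
        return np.zeros((0, 2, 3))
    return np.stack(segs, axis=0)


def _segment_triangle_hit(p0: np.ndarray, p1: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Boolean per (segment, triangle) pair (arrays already paired row-wise)."""
    d = p1 - p0
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = _cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    res = np.zeros(len(p0), dtype=bool)
    if not ok.any():
        return res
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = p0 - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = _cross(tvec, e1)
    v = np.einsum("ij,ij->i", qvec, d) * inv
    t = np.einsum("ij,ij->i", qvec, e2) * inv
    res = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t >= 0.0) & (t <= 1.0)
    return res


def _candidate_pairs(seg_mid: np.ndarray, seg_rad: np.ndarray,
                     tri_mid: np.ndarray, tri_rad: float,
                     tree: cKDTree | None = None,
                     radius: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Broad-phase pairs of (segment index, triangle index) via KD-tree."""
    if len(seg_mid) == 0 or len(tri_mid) == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    if tree is None:
        tree = cKDTree(tri_mid)
    if radius is None:
        radius = seg_rad + tri_rad          # per-segment radii
    neighbors = tree.query_ball_point(seg_mid, r=radius)
    return _flatten_neighbor_lists(neighbors)


def _knn_pairs(tree: cKDTree, pts: np.ndarray, r: np.ndarray,
               k: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """All (point, tree-item) pairs within per-point radius ``r``.

    Vectorised k-NN with a ball-query fallback for the rare points whose
    neighbourhood saturates k (soundness is preserved).
    """
    k = min(k, tree.n)
    dist, idx = tree.query(pts, k=k, distance_upper_bound=float(np.max(r)))
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    within = dist <= np.asarray(r)[:, None]
    saturated = within[:, -1]
    pi, slot = np.nonzero(within & ~saturated[:, None])
    ti = idx[pi, slot]
    if saturated.any():
        sat = np.nonzero(saturated)[0]
        lists = tree.query_ball_point(pts[sat], r=np.asarray(r)[sat])
        si2, ti2 = _flatten_neighbor_lists(lists)
        pi = np.concatenate([pi, sat[si2]])
        ti = np.concatenate([ti, ti2])
    return pi, ti


def _flatten_neighbor_lists(neighbors) -> tuple[np.ndarray, np.ndarray]:
    if len(neighbors) == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    lengths = np.fromiter((len(n) for n in neighbors), np.int64, count=len(neighbors))
    si = np.repeat(np.arange(len(neighbors), dtype=np.int64), lengths)
    if lengths.sum() == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    ti = np.concatenate([np.asarray(n, np.int64).reshape(-1) for n in neighbors])
    return si, ti


def _box_mask(points_lo, points_hi, lo, hi):
    return np.all(points_hi >= lo, axis=1) & np.all(points_lo <= hi, axis=1)


def _edges_cross_triangles(mesh_a: TriMesh, mesh_b: TriMesh, exclude_shared: bool = False,
                           box=None) -> bool:
    """Does any edge of A cross any face of B (optionally within a focus box)?"""
    edges = mesh_a.edges_unique()
    ev0 = mesh_a.vertices[edges[:, 0]]
    ev1 = mesh_a.vertices[edges[:, 1]]
    tri = mesh_b.triangles()
    if box is not None:
        lo, hi = box
        em = _box_mask(np.minimum(ev0, ev1), np.maximum(ev0, ev1), lo, hi)
        tm = _box_mask(tri.min(axis=1), tri.max(axis=1), lo, hi)
        edges, ev0, ev1 = edges[em], ev0[em], ev1[em]
        tri_idx = np.nonzero(tm)[0]
        tri = tri[tm]
    else:
        tri_idx = np.arange(len(tri))
    if len(ev0) == 0 or len(tri) == 0:
        return False
    seg_mid = (ev0 + ev1) / 2
    seg_rad = np.linalg.norm(ev1 - ev0, axis=1) / 2
    tri_mid = tri.mean(axis=1)
    tri_rad = np.linalg.norm(tri - tri_mid[:, None, :], axis=2).max() if len(tri) else 0.0
    si, ti = _candidate_pairs(seg_mid, seg_rad, tri_mid, tri_rad)
    if len(si) == 0:
        return False
    if exclude_shared:
        fv = mesh_b.faces[tri_idx[ti]]
        shared = (
            (edges[si, 0, None] == fv).any(axis=1) | (edges[si, 1, None] == fv).any(axis=1)
        )
        si, ti = si[~shared], ti[~shared]
        if len(si) == 0:
            return False
    # chunk to bound memory
    for start in range(0, len(si), 200_000):
        sl = slice(start, start + 200_000)
        if _segment_triangle_hit(ev0[si[sl]], ev1[si[sl]], tri[ti[sl]]).any():
            return True
    return False


def surfaces_intersect(mesh_a: TriMesh, mesh_b: TriMesh) -> bool:
    """True when the two surfaces cross each other (not mere containment)."""
    lo_a, hi_a = mesh_a.aabb()
    lo_b, hi_b = mesh_b.aabb()
    margin = 1e-9
    if np.any(hi_a < lo_b - margin) or np.any(hi_b < lo_a - margin):
        return False
    lo = np.maximum(lo_a, lo_b) - 0.5
    hi = np.minimum(hi_a, hi_b) + 0.5
    box = (lo, hi)
    return (_edges_cross_triangles(mesh_a, mesh_b, box=box)
            or _edges_cross_triangles(mesh_b, mesh_a, box=box))


def mesh_overlap(mesh_a: TriMesh, mesh_b: TriMesh, check: bool = True) -> bool:
    """True iff the watertight solids overlap (surface crossing or containment)."""
    if check:
        for m in (mesh_a, mesh_b):
            if not m.is_watertight():
                raise GeometryError(f"mesh {m.name!r} is not watertight")
    lo_a, hi_a = mesh_a.aabb()
    lo_b, hi_b = mesh_b.aabb()
    if np.any(hi_a < lo_b) or np.any(hi_b < lo_a):
        return False
    if surfaces_intersect(mesh_a, mesh_b):
        return True
    # containment without surface crossing
    if bool(mesh_b.contains(mesh_a.vertices[:1])[0]):
        return True
    return bool(mesh_a.contains(mesh_b.vertices[:1])[0])


class PairCollider:
    """Fast repeated overlap queries: one rigidly moving mesh vs one static mesh.

    Topology, KD-trees and bound radii are cached at construction; each
    query only needs the moving mesh's current vertex array.  Pruning is by
    vertex proximity: if two watertight surfaces cross, some vertex of the
    moving mesh lies within one moving edge length of the static surface,
    hence within (moving max edge + static max edge) of a static vertex.
    """

    def __init__(self, moving: TriMesh, static: TriMesh):
        self.m_faces = moving.faces
        self.m_edges = moving.edges_unique()
        mv = moving.vertices
        edge_len = np.linalg.norm(mv[self.m_edges[:, 0]] - mv[self.m_edges[:, 1]], axis=1)
        # per-vertex bound: longest incident edge (rigid motion invariant)
        self.m_vert_reach = np.zeros(len(mv))
        np.maximum.at(self.m_vert_reach, self.m_edges[:, 0], edge_len)
        np.maximum.at(self.m_vert_reach, self.m_edges[:, 1], edge_len)
        self.m_edge_half = edge_len / 2.0
        tri = moving.triangles()
        self.m_tri_rad = np.linalg.norm(
            tri - tri.mean(axis=1, keepdims=True), axis=2).max(axis=1)
        self.s_verts = static.vertices
        self.s_tree = cKDTree(self.s_verts)
        self.s_tri = static.triangles()
        s_mid = self.s_tri.mean(axis=1)
        self.s_tri_tree = cKDTree(s_mid)
        self.s_tri_rad = float(np.linalg.norm(
            self.s_tri - s_mid[:, None, :], axis=2).max())
        s_edges = static.edges_unique()
        self.s_e0 = self.s_verts[s_edges[:, 0]]
        self.s_e1 = self.s_verts[s_edges[:, 1]]
        self.s_edge_mid_tree = cKDTree((self.s_e0 + self.s_e1) / 2.0)
        self.s_edge_half = float(np.linalg.norm(self.s_e1 - self.s_e0, axis=1).max()) / 2.0
        self.s_lo, self.s_hi = static.aabb()
        self.q_margin = float(self.m_vert_reach.max() + self.s_tri_rad + 0.1)

    def overlap(self, mverts: np.ndarray) -> bool:
        if np.any(mverts.min(axis=0) > self.s_hi) or np.any(mverts.max(axis=0) < self.s_lo):
            return False
        # a crossing implies a moving vertex within (incident edge + static
        # triangle radius) of a static vertex; prefilter by the static box
        in_box = (np.all(mverts >= self.s_lo - self.q_margin, axis=1)
                  & np.all(mverts <= self.s_hi + self.q_margin, axis=1))
        near = np.zeros(len(mverts), dtype=bool)
        cand = np.nonzero(in_box)[0]
        if cand.size:
            dist, _ = self.s_tree.query(mverts[cand], k=1,
                                        distance_upper_bound=self.q_margin)
            near[cand] = dist <= self.m_vert_reach[cand] + self.s_tri_rad + 0.1
        if near.any():
            if self._edges_vs_static_tris(mverts, near):
                return True
            if self._static_edges_vs_tris(mverts, near):
                return True
        # no surface crossing: containment tests
        if _ray_hit_counts(mverts[:1], _PARITY_DIR, self.s_tri)[0] % 2 == 1:
            return True
        m_tri = mverts[self.m_faces]
        return bool(_ray_hit_counts(self.s_verts[:1], _PARITY_DIR, m_tri)[0] % 2 == 1)

    def _edges_vs_static_tris(self, mverts, near) -> bool:
        sel = near[self.m_edges[:, 0]] | near[self.m_edges[:, 1]]
        if not sel.any():
            return False
        e0 = mverts[self.m_edges[sel, 0]]
        e1 = mverts[self.m_edges[sel, 1]]
        mid = (e0 + e1) / 2.0
        r = self.m_edge_half[sel] + self.s_tri_rad + 1e-9     # per-edge radii
        si, ti = _knn_pairs(self.s_tri_tree, mid, r)
        if len(si) == 0:
            return False
        return bool(_segment_triangle_hit(e0[si], e1[si], self.s_tri[ti]).any())

    def _static_edges_vs_tris(self, mverts, near) -> bool:
        fsel = (near[self.m_faces[:, 0]] | near[self.m_faces[:, 1]]
                | near[self.m_faces[:, 2]])
        if not fsel.any():
            return False
        m_tri = mverts[self.m_faces[fsel]]
        mid = m_tri.mean(axis=1)
        r = self.s_edge_half + self.m_tri_rad[fsel] + 1e-9    # per-triangle radii
        # query the (few) candidate moving-triangle centres against the
        # cached static-edge tree: pairs of (moving tri, static edge)
        tij, sei = _knn_pairs(self.s_edge_mid_tree, mid, r)
        if sei.size == 0:
            return False
        return bool(_segment_triangle_hit(self.s_e0[sei], self.s_e1[sei],
                                          m_tri[tij]).any())


# ---------------------------------------------------------------------------
# IO (binary STL preferred; ASCII STL and OBJ also supported)


def write_stl(mesh: TriMesh, path, binary: bool = True) -> None:
    tri = mesh.triangles().astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tri)))
            rec = np.zeros(len(tri), dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                            ("attr", "<u2")])
            rec["n"] = normals
            rec["v"] = tri
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(f"solid {mesh.name}\n")
            for n, t in zip(normals, tri):
                fh.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n outer loop\n")
                for p in t:
                    fh.write(f"  vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write(f"endsolid {mesh.name}\n")


def read_stl(path, name: str = "") -> TriMesh:
    with open(path, "rb") as fh:
        head = fh.read(80)
        rest = fh.read()
    if head.lstrip().startswith(b"solid") and b"facet" in rest[:1000] + head:
        text = (head + rest).decode("ascii", errors="replace")
        coords = []
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("vertex"):
                coords.append([float(x) for x in line.split()[1:4]])
        tri = np.asarray(coords, float).reshape(-1, 3, 3)
    else:
        (n_tri,) = struct.unpack("<I", rest[:4])
        rec = np.frombuffer(rest[4:4 + n_tri * 50],
                            dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
        tri = rec["v"].astype(np.float64)
    return _mesh_from_triangle_soup(tri, name)


def _mesh_from_triangle_soup(tri: np.ndarray, name: str = "") -> TriMesh:
    flat = tri.reshape(-1, 3)
    # weld vertices exactly (synthetic/exported meshes share identical floats)
    uniq, inverse = np.unique(flat.round(7), axis=0, return_inverse=True)
    return TriMesh(uniq, inverse.reshape(-1, 3), name)


def write_obj(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"o {mesh.name or 'mesh'}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def read_obj(path, name: str = "") -> TriMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64), name)
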