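"""Fibular rotation kinematics and overlap resolution.

The rotation axis is the fibular medullary canal: a least-squares line
through the area centroids of evenly spaced transverse shaft sections (the
distal 40 % of the bone is excluded so the malleolar flare cannot bias the
fit).  Poses are proper rigid motions -- a rotation about that axis
(positive = internal rotation of a right fibula, i.e. the anterior surface
swings medially) optionally followed by a lateral translation.  When a
rotated fibula interpenetrates the tibia or talus it is translated
laterally, as happens mechanically in vivo, by the minimal shift that
clears both bones (doubling search then bisection).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .anatomy import AnkleSpecimen, ParameterError
from .meshes import GeometryError, PairCollider, TriMesh, mesh_overlap

__all__ = [
    "Axis3D",
    "FibulaPose",
    "PROTOCOL_ANGLES",
    "fit_longitudinal_axis",
    "rotate_fibula",
    "meshes_intersect",
    "resolve_overlap",
    "minimal_clearance_shift",
    "apply_pose",
    "specimen_axis",
]

#: the standard rotation protocol: 30 deg external ... 30 deg internal, step 5
PROTOCOL_ANGLES = tuple(range(-30, 35, 5))


@dataclass(frozen=True)
class Axis3D:
    """A 3D line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, float))
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise GeometryError("axis direction must be a unit vector")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class FibulaPose:
    """Rigid fibular pose: rotation about the longitudinal axis + lateral shift."""

    angle_deg: float
    axis: Axis3D
    lateral_shift_mm: float = 0.0
    side: str = "right"

    @property
    def lateral_direction(self) -> np.ndarray:
        return np.array([1.0 if self.side == "right" else -1.0, 0.0, 0.0])

    @property
    def transform(self) -> np.ndarray:
        """4x4 proper rigid motion (rotation about the axis, then the shift)."""
        sign = 1.0 if self.side == "right" else -1.0
        rot = Rotation.from_rotvec(
            np.radians(sign * self.angle_deg) * self.axis.direction).as_matrix()
        t = np.eye(4)
        t[:3, :3] = rot
        t[:3, 3] = self.axis.point - rot @ self.axis.point \
            + self.lateral_shift_mm * self.lateral_direction
        return t


def _section_centroid(points2d: np.ndarray) -> np.ndarray | None:
    """Area centroid of an unordered star-shaped section polygon."""
    if len(points2d) < 3:
        return None
    c = points2d.mean(axis=0)
    ang = np.arctan2(points2d[:, 1] - c[1], points2d[:, 0] - c[0])
    p = points2d[np.argsort(ang)]
    q = np.roll(p, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    area = cross.sum() / 2.0
    if abs(area) < 1e-9:
        return None
    cx = ((p[:, 0] + q[:, 0]) * cross).sum() / (6.0 * area)
    cy = ((p[:, 1] + q[:, 1]) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def fit_longitudinal_axis(fibula_mesh: TriMesh, n_sections: int = 10,
                          distal_exclusion: float = 0.40) -> Axis3D:
    """Least-squares medullary-axis fit from transverse shaft sections.

    Sections are taken perpendicular to the principal direction of the
    mesh, restricted to the shaft (the distal ``distal_exclusion`` fraction
    of the length is skipped); the axis is the total-least-squares line
    through their area centroids, oriented proximally (+z hemisphere).
    """
    if n_sections < 3:
        raise ParameterError("n_sections must be >= 3")
    v = fibula_mesh.vertices
    center = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - center, full_matrices=False)
    d0 = vt[0]
    if d0[2] < 0:
        d0 = -d0
    t = (v - center) @ d0
    lo, hi = t.min(), t.max()
    span = hi - lo
    t_start = lo + distal_exclusion * span
    t_end = hi - 0.03 * span
    if t_end <= t_start:
        raise GeometryError("shaft region is empty")
    # in-plane basis for 2D centroids
    u_b = np.cross(d0, [1.0, 0.0, 0.0])
    if np.linalg.norm(u_b) < 1e-8:
        u_b = np.cross(d0, [0.0, 1.0, 0.0])
    u_b /= np.linalg.norm(u_b)
    w_b = np.cross(d0, u_b)
    centroids = []
    for ti in np.linspace(t_start, t_end, n_sections):
        point = center + ti * d0
        segs = fibula_mesh.plane_section(point, d0)
        if len(segs) == 0:
            continue
        pts = segs.reshape(-1, 3) - point
        c2 = _section_centroid(np.stack([pts @ u_b, pts @ w_b], axis=1))
        if c2 is None:
            continue
        centroids.append(point + c2[0] * u_b + c2[1] * w_b)
    if len(centroids) < 3:
        raise GeometryError(
            f"only {len(centroids)} valid shaft sections; need at least 3")
    pts = np.asarray(centroids)
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
    d = vt[0]
    if d[2] < 0:
        d = -d
    return Axis3D(mean, d / np.linalg.norm(d))


def specimen_axis(specimen: AnkleSpecimen) -> Axis3D:
    """Fitted longitudinal axis of the specimen's fibula (cached)."""
    cache = getattr(specimen, "_axis_cache", None)
    if cache is None:
        cache = fit_longitudinal_axis(specimen.fibula_mesh)
        specimen._axis_cache = cache
    return cache


def rotate_fibula(specimen: AnkleSpecimen, angle_deg: float) -> FibulaPose:
    """Pose rotating the fibula about its longitudinal axis (no shift yet).

    Positive angles are internal rotation; the convention is side-aware so
    mirrored (left) specimens rotate consistently.
    """
    if abs(angle_deg) > 90.0:
        raise ParameterError(
            f"|angle_deg| must be <= 90 (modelled regime), got {angle_deg}")
    return FibulaPose(angle_deg=float(angle_deg), axis=specimen_axis(specimen),
                      side=specimen.side)


def apply_pose(mesh: TriMesh, pose: FibulaPose) -> TriMesh:
    return mesh.transformed(pose.transform)


def meshes_intersect(mesh_a: TriMesh, mesh_b: TriMesh) -> bool:
    """Do two watertight solids overlap (surface crossing or containment)?"""
    return mesh_overlap(mesh_a, mesh_b, check=True)


def minimal_clearance_shift(moving: TriMesh, obstacles: list[TriMesh],
                            direction, step_mm: float = 0.25, tol_mm: float = 0.01,
                            max_shift_mm: float = 50.0) -> float:
    """Minimal non-negative translation along ``direction`` clearing all obstacles.

    Doubling search to bracket, then bisection to ``tol_mm``; returns the
    clear upper end of the final bracket (0 exactly when already clear).
    """
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    obstacles = [o for o in obstacles if o is not None]
    colliders = [PairCollider(moving, o) for o in obstacles]
    base = moving.vertices

    def overlapping(shift: float) -> bool:
        mv = base + shift * direction
        return any(c.overlap(mv) for c in colliders)

    return _shift_search(overlapping, step_mm, tol_mm, max_shift_mm)


def _shift_search(overlapping, step_mm: float, tol_mm: float,
                  max_shift_mm: float) -> float:
    """Doubling bracket + bisection on a boolean overlap predicate."""
    if tol_mm <= 0:
        raise ParameterError("tol_mm must be > 0")
    if not overlapping(0.0):
        return 0.0
    lo, hi = 0.0, step_mm
    while overlapping(hi):
        lo = hi
        hi *= 2.0
        if hi > max_shift_mm:
            raise GeometryError(
                f"no clearance found within {max_shift_mm} mm; malformed scene")
    while hi - lo > tol_mm:
        mid = (lo + hi) / 2.0
        if overlapping(mid):
            lo = mid
        else:
            hi = mid
    return hi


def resolve_overlap(specimen: AnkleSpecimen, pose: FibulaPose,
                    step_mm: float = 0.25, tol_mm: float = 0.01) -> FibulaPose:
    """Resolve fibula/tibia/talus interpenetration by a lateral translation.

    Returns a pose whose ``lateral_shift_mm`` is the minimal non-negative
    shift along the canonical lateral direction (perpendicular to the
    tibial long axis) at which the posed fibula intersects neither the
    tibia nor the talus.  Deterministic, hence idempotent.
    """
    colliders = getattr(specimen, "_collider_cache", None)
    if colliders is None:
        for mesh in (specimen.fibula_mesh, specimen.tibia_mesh, specimen.talus_mesh):
            if not mesh.is_watertight():
                raise GeometryError(f"mesh {mesh.name!r} is not watertight")
        # static trees + moving topology are pose-independent: cache them
        colliders = [PairCollider(specimen.fibula_mesh, specimen.tibia_mesh),
                     PairCollider(specimen.fibula_mesh, specimen.talus_mesh)]
        specimen._collider_cache = colliders
    t = replace(pose, lateral_shift_mm=0.0).transform
    base = specimen.fibula_mesh.vertices @ t[:3, :3].T + t[:3, 3]
    direction = pose.lateral_direction

    def overlapping(shift: float) -> bool:
        mv = base + shift * direction
        return any(c.overlap(mv) for c in colliders)

    shift = _shift_search(overlapping, step_mm, tol_mm, 50.0)
    return replace(pose, lateral_shift_mm=shift)


def pose_log_frame(poses: list[FibulaPose]):
    """Tabular pose log (angle, shift, row-major 3x4 transform)."""
    import pandas as pd

    rows = []
    for p in poses:
        t = p.transform[:3, :].reshape(-1)
        rows.append({"angle_deg": p.angle_deg, "lateral_shift_mm": p.lateral_shift_mm,
                     **{f"t{i}": t[i] for i in range(12)}})
    return pd.DataFrame(rows)
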