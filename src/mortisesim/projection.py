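"""Parallel-beam virtual radiography (mortise view) and landmark projection.

The mortise view is simulated by internally rotating the whole scene by the
mortise angle (default 15 degrees) about the tibial long axis and casting
parallel anteroposterior rays (along -y).  A pixel records the total
ray-mesh chord length in mm of bone traversed (uniform density; only edge
and shadow *positions* are meaningful, and any monotone intensity transform
preserves them).  For a watertight, outward-oriented mesh the chord length
through a pixel equals ``sum(sign(n_y) * y_hit)`` over the triangles whose
projection covers the pixel centre, so rendering reduces to a scanline
rasterisation accumulating that signed quantity -- exact per pixel, no ray
sorting needed.

Image axes: u is lateral in mm (rightward = lateral for a right ankle;
left ankles are mirrored into the canonical frame first), v is proximal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anatomy import AnkleSpecimen
from .kinematics import FibulaPose, apply_pose
from .measurement import Line2D, reference_line
from .meshes import GeometryError, TriMesh

__all__ = [
    "ViewParams",
    "Radiograph",
    "LandmarkSet2D",
    "render_mortise_view",
    "project_landmarks",
    "project_points",
    "render_meshes",
    "save_radiograph",
    "load_radiograph",
]


@dataclass(frozen=True)
class ViewParams:
    """Mortise-view geometry (parallel beam)."""

    mortise_internal_rotation_deg: float = 15.0
    pixel_spacing_mm: float = 0.2
    image_extent: tuple | None = None    # ((umin, umax), (vmin, vmax)) in mm, or auto
    margin_mm: float = 2.0

    def __post_init__(self):
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")

    @property
    def ray_direction(self) -> np.ndarray:
        """Anteroposterior, in view coordinates (after the mortise rotation)."""
        return np.array([0.0, -1.0, 0.0])

    def rotation(self) -> np.ndarray:
        a = np.radians(self.mortise_internal_rotation_deg)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class Radiograph:
    """2D parallel-projection attenuation image (mm of bone per ray)."""

    pixels: np.ndarray               # (nv, nu), v increases proximally with row index
    spacing: float                   # mm / pixel
    origin: np.ndarray               # (u, v) of the pixel (0, 0) centre, mm
    view: ViewParams
    channels: dict = field(default_factory=dict)   # per-bone attenuation

    @property
    def u_coords(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.pixels.shape[1])

    @property
    def v_coords(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.pixels.shape[0])


@dataclass
class LandmarkSet2D:
    """Projected landmarks (u, v in mm) with explicit missing markers."""

    points: dict
    missing: set = field(default_factory=set)
    view: ViewParams | None = None

    REQUIRED = ("medial_malleolus_tip", "plafond_medial", "plafond_lateral",
                "fibula_medial_edge_at_line", "fossa_wall_at_line",
                "fibula_lateral_edge_at_line")

    def __getitem__(self, key):
        return self.points[key]


# ---------------------------------------------------------------------------
# rasterisation


def _raster_chord(vertices: np.ndarray, faces: np.ndarray, origin, spacing: float,
                  shape: tuple[int, int]) -> np.ndarray:
    """Accumulate per-pixel chord length for one watertight mesh."""
    nv, nu = shape
    img = np.zeros((nv, nu))
    u = vertices[:, 0]
    y = vertices[:, 1]
    v = vertices[:, 2]
    # tiny deterministic sub-pixel bias dodges exact edge-through-centre ties
    u0 = origin[0] + 1e-6 * spacing
    v0 = origin[1] + 1e-6 * spacing
    tu = u[faces]
    tv = v[faces]
    ty = y[faces]
    e1u = tu[:, 1] - tu[:, 0]
    e1v = tv[:, 1] - tv[:, 0]
    e2u = tu[:, 2] - tu[:, 0]
    e2v = tv[:, 2] - tv[:, 0]
    area2 = e1u * e2v - e1v * e2u        # signed, = -2A * sign(normal_y)
    # outward 3D normal y-component shares the sign of -(area2): a CCW (u,v)
    # footprint means the normal points along -y.  Work it out explicitly:
    # n = cross(p1-p0, p2-p0); n_y = (z1-z0)(x2-x0) - (x1-x0)(z2-z0)
    n_y = e1v * e2u - e1u * e2v
    keep = np.abs(n_y) > 1e-12
    sign = np.sign(n_y)
    lo_u = np.ceil((np.minimum.reduce([tu[:, 0], tu[:, 1], tu[:, 2]]) - u0) / spacing)
    hi_u = np.floor((np.maximum.reduce([tu[:, 0], tu[:, 1], tu[:, 2]]) - u0) / spacing)
    lo_v = np.ceil((np.minimum.reduce([tv[:, 0], tv[:, 1], tv[:, 2]]) - v0) / spacing)
    hi_v = np.floor((np.maximum.reduce([tv[:, 0], tv[:, 1], tv[:, 2]]) - v0) / spacing)
    lo_u = np.clip(lo_u, 0, nu - 1).astype(int)
    hi_u = np.clip(hi_u, -1, nu - 1).astype(int)
    lo_v = np.clip(lo_v, 0, nv - 1).astype(int)
    hi_v = np.clip(hi_v, -1, nv - 1).astype(int)
    keep &= (hi_u >= lo_u) & (hi_v >= lo_v)
    for f in np.nonzero(keep)[0]:
        us = u0 + spacing * np.arange(lo_u[f], hi_u[f] + 1)
        vs = v0 + spacing * np.arange(lo_v[f], hi_v[f] + 1)
        pu = us[None, :] - tu[f, 0]
        pv = vs[:, None] - tv[f, 0]
        a2 = area2[f]
        w1 = (pu * e2v[f] - pv * e2u[f]) / a2
        w2 = (e1u[f] * pv - e1v[f] * pu) / a2
        w0 = 1.0 - w1 - w2
        inside = (w0 >= 0.0) & (w1 >= 0.0) & (w2 >= 0.0)
        if not inside.any():
            continue
        yhit = w0 * ty[f, 0] + w1 * ty[f, 1] + w2 * ty[f, 2]
        block = img[lo_v[f]:hi_v[f] + 1, lo_u[f]:hi_u[f] + 1]
        block += np.where(inside, sign[f] * yhit, 0.0)
    return img


def render_meshes(meshes: dict[str, TriMesh], view: ViewParams,
                  check_watertight: bool = True) -> Radiograph:
    """Render already view-rotated meshes (scene coordinates = view coordinates)."""
    for name, m in meshes.items():
        if check_watertight and m.n_faces and not m.is_watertight():
            raise GeometryError(f"mesh {name!r} is not watertight")
    spacing = view.pixel_spacing_mm
    if view.image_extent is not None:
        (umin, umax), (vmin, vmax) = view.image_extent
    else:
        if not meshes or all(m.n_faces == 0 for m in meshes.values()):
            umin, umax, vmin, vmax = 0.0, 1.0, 0.0, 1.0
        else:
            los, his = zip(*(m.aabb() for m in meshes.values() if m.n_faces))
            lo = np.min(los, axis=0)
            hi = np.max(his, axis=0)
            umin, umax = lo[0] - view.margin_mm, hi[0] + view.margin_mm
            vmin, vmax = lo[2] - view.margin_mm, hi[2] + view.margin_mm
    nu = max(int(np.ceil((umax - umin) / spacing)) + 1, 2)
    nv = max(int(np.ceil((vmax - vmin) / spacing)) + 1, 2)
    origin = np.array([umin, vmin])
    channels = {}
    for name, m in meshes.items():
        img = _raster_chord(m.vertices, m.faces, origin, spacing, (nv, nu))
        img[np.abs(img) < 1e-9] = 0.0
        channels[name] = np.maximum(img, 0.0)
    combined = np.sum(list(channels.values()), axis=0) if channels \
        else np.zeros((nv, nu))
    return Radiograph(pixels=combined, spacing=spacing, origin=origin,
                      view=view, channels=channels)


def _posed_canonical(specimen: AnkleSpecimen, pose: FibulaPose | None):
    """Apply the pose in the specimen's own frame, then mirror lefts into the
    canonical right frame.  Returns (meshes dict, landmark dict)."""
    fib = specimen.fibula_mesh
    landmarks = {k: np.array(v, float, copy=True) for k, v in specimen.landmarks.items()}
    if pose is not None:
        t = pose.transform
        fib = apply_pose(fib, pose)
        ring = np.atleast_2d(landmarks["fossa_wall_ring"])
        landmarks["fossa_wall_ring"] = ring @ t[:3, :3].T + t[:3, 3]
        for key in ("fossa_rim_anterior",):
            if key in landmarks:
                landmarks[key] = t[:3, :3] @ landmarks[key] + t[:3, 3]
    meshes = {"tibia": specimen.tibia_mesh, "fibula": fib, "talus": specimen.talus_mesh}
    if specimen.side == "left":
        meshes = {k: m.mirrored(0) for k, m in meshes.items()}
        for k, v in landmarks.items():
            v[..., 0] = -v[..., 0]
    return meshes, landmarks


def render_mortise_view(specimen: AnkleSpecimen, pose: FibulaPose | None = None,
                        view: ViewParams | None = None) -> Radiograph:
    """Virtual mortise-view radiograph of the posed ankle."""
    view = view if view is not None else ViewParams()
    meshes, _ = _posed_canonical(specimen, pose)
    rot4 = np.eye(4)
    rot4[:3, :3] = view.rotation()
    meshes = {k: m.transformed(rot4) for k, m in meshes.items()}
    return render_meshes(meshes, view)


# ---------------------------------------------------------------------------
# landmark projection


def project_points(points: np.ndarray, view: ViewParams) -> np.ndarray:
    """Orthographic (u, v) of 3D points already in the canonical frame."""
    q = np.atleast_2d(np.asarray(points, float)) @ view.rotation().T
    return np.stack([q[:, 0], q[:, 2]], axis=1)


def project_landmarks(specimen: AnkleSpecimen, pose: FibulaPose | None = None,
                      view: ViewParams | None = None) -> LandmarkSet2D:
    """Project the named 3D landmarks with the renderer's view geometry.

    Fibular edge points are the extreme positions of the posed fibula
    silhouette on the reference line; the fossa wall is the crossing of the
    stored wall ring with the line level.  Landmarks that do not exist at
    this pose (line off the silhouette, wall ring not crossing the line)
    are marked missing, never fabricated.
    """
    view = view if view is not None else ViewParams()
    meshes, landmarks = _posed_canonical(specimen, pose)
    rot = view.rotation()
    pts: dict[str, np.ndarray] = {}
    missing: set[str] = set()
    for name in ("medial_malleolus_tip", "plafond_medial", "plafond_lateral"):
        q = rot @ landmarks[name]
        pts[name] = np.array([q[0], q[2]])
    line = reference_line(pts)
    fib = meshes["fibula"]
    fib = TriMesh(fib.vertices @ rot.T, fib.faces, fib.name)
    ring = np.atleast_2d(landmarks["fossa_wall_ring"]) @ rot.T
    # preimage of the reference line: a plane spanned by the line direction
    # (lifted to 3D) and the ray direction
    n2 = np.array([-line.direction[1], line.direction[0]])   # 2D normal
    plane_normal = np.array([n2[0], 0.0, n2[1]])
    plane_point = np.array([line.point[0], 0.0, line.point[1]])
    segs = fib.plane_section(plane_point, plane_normal)
    if len(segs) == 0:
        missing |= {"fibula_medial_edge_at_line", "fibula_lateral_edge_at_line",
                    "fossa_wall_at_line"}
        return LandmarkSet2D(points=pts, missing=missing, view=view)
    sp = segs.reshape(-1, 3)
    uv = np.stack([sp[:, 0], sp[:, 2]], axis=1)
    t_par = (uv - line.point) @ line.direction
    pts["fibula_medial_edge_at_line"] = line.at(float(t_par.min()))
    pts["fibula_lateral_edge_at_line"] = line.at(float(t_par.max()))
    wall = _ring_line_crossing(ring, line)
    if wall is None:
        missing.add("fossa_wall_at_line")
    else:
        pts["fossa_wall_at_line"] = wall
    return LandmarkSet2D(points=pts, missing=missing, view=view)


def _ring_line_crossing(ring_view: np.ndarray, line: Line2D) -> np.ndarray | None:
    """Medial crossing of the (view-rotated) wall ring with the reference line."""
    uv = np.stack([ring_view[:, 0], ring_view[:, 2]], axis=1)
    n2 = np.array([-line.direction[1], line.direction[0]])
    d = (uv - line.point) @ n2
    nxt = np.roll(np.arange(len(d)), -1)
    crossings = []
    for i in range(len(d)):
        j = nxt[i]
        if (d[i] > 0 >= d[j]) or (d[i] <= 0 < d[j]):
            frac = d[i] / (d[i] - d[j])
            p = uv[i] + frac * (uv[j] - uv[i])
            crossings.append(line.param_of(p))
    if not crossings:
        return None
    return line.at(float(min(crossings)))     # medial branch = the cortical wall


# ---------------------------------------------------------------------------
# IO: 16-bit TIFF + JSON sidecar

_TIFF_GAIN = 100.0   # counts per mm of bone


def save_radiograph(rad: Radiograph, path) -> None:
    import tifffile

    path = Path(path)
    data = np.clip(rad.pixels * _TIFF_GAIN, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "spacing_mm": rad.spacing,
        "origin_mm": list(map(float, rad.origin)),
        "gain_counts_per_mm": _TIFF_GAIN,
        "mortise_internal_rotation_deg": rad.view.mortise_internal_rotation_deg,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_radiograph(path) -> Radiograph:
    import tifffile

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    data = tifffile.imread(path).astype(np.float64) / sidecar["gain_counts_per_mm"]
    view = ViewParams(
        mortise_internal_rotation_deg=sidecar["mortise_internal_rotation_deg"],
        pixel_spacing_mm=sidecar["spacing_mm"])
    return Radiograph(pixels=data, spacing=sidecar["spacing_mm"],
                      origin=np.asarray(sidecar["origin_mm"]), view=view)
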