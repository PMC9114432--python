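"""Radiographic and cross-sectional measurements.

Two bespoke measurements:

* **Incisura depth** -- on the transverse tibial section 1 cm proximal to
  the plafond, the incisura is the concavity of the lateral contour; its
  depth is the maximal perpendicular distance from the tangent chord
  (joining the anterior and posterior rims) to the contour, and >= 4 mm
  classifies the incisura as concave, < 4 mm as shallow.

* **Ratio alpha** -- on the mortise view, a reference line through the tip
  of the medial malleolus parallel to the distal tibial plafond crosses
  the medial fibular edge at A, the fossa-cortex shadow at B and the
  lateral fibular edge at C; alpha = |AB| / |AC|.  It is dimensionless and
  invariant to image scale, which is what makes it usable on uncalibrated
  intraoperative fluoroscopy.

Point B can be read in two modes: *landmark* mode uses the projected fossa
wall (exact for synthetic anatomy); *image* mode detects the wall's
tangential-ray shadow on the rendered attenuation profile as the strongest
descending gradient between the fibular edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull

from .anatomy import ParameterError
from .meshes import GeometryError, TriMesh

__all__ = [
    "CONCAVE_THRESHOLD_MM",
    "Line2D",
    "IncisuraMetrics",
    "RatioMeasurement",
    "MeasurementError",
    "measure_incisura_depth",
    "classify_incisura",
    "reference_line",
    "locate_ABC",
    "compute_ratio_alpha",
    "simulate_observer",
]

CONCAVE_THRESHOLD_MM = 4.0


class MeasurementError(ValueError):
    """A measurement precondition failed (line misses the bone, etc.)."""


@dataclass(frozen=True)
class Line2D:
    """2D line: point + unit direction (direction oriented toward +u)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, float)
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise GeometryError("degenerate line direction")
        d = d / n
        if d[0] < 0 or (d[0] == 0 and d[1] < 0):
            d = -d
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)

    def at(self, t):
        t = np.asarray(t, float)
        return self.point + t[..., None] * self.direction

    def param_of(self, q) -> float:
        return float((np.asarray(q, float) - self.point) @ self.direction)


@dataclass(frozen=True)
class IncisuraMetrics:
    depth_mm: float
    chord_mm: float
    section_level_mm: float
    type: str                      # "concave" | "shallow"
    warning: bool = False          # no clear notch detected

    def __post_init__(self):
        if self.type != classify_incisura(self.depth_mm):
            raise MeasurementError("type inconsistent with the 4 mm rule")


@dataclass(frozen=True)
class RatioMeasurement:
    """The three points on the reference line and ratio alpha."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    alpha: float
    angle_deg: float = float("nan")
    specimen_id: str = ""
    observer_id: str = ""
    valid: bool = True
    flags: tuple = ()


def classify_incisura(depth_mm: float) -> str:
    """Concave iff depth >= 4 mm (closed lower bound)."""
    return "concave" if depth_mm >= CONCAVE_THRESHOLD_MM else "shallow"


# ---------------------------------------------------------------------------
# incisura depth


def measure_incisura_depth(tibia_mesh: TriMesh, plafond_z: float,
                           section_offset_mm: float = 10.0,
                           sector_halfangle_deg: float = 60.0) -> IncisuraMetrics:
    """Chord-to-floor depth of the fibular incisura on a transverse section.

    The section contour is cut at ``plafond_z + section_offset_mm``; the
    notch is found as the convex-hull deficiency of the lateral contour
    sector: the hull edge spanning the concavity is the tangent chord, and
    the depth is the maximal inward deviation of contour points under it.
    """
    z = plafond_z + section_offset_mm
    segs = tibia_mesh.plane_section([0.0, 0.0, z], [0.0, 0.0, 1.0])
    if len(segs) == 0:
        raise GeometryError(f"section plane z={z} misses the tibia")
    pts = np.unique(segs.reshape(-1, 3)[:, :2].round(9), axis=0)
    centroid = pts.mean(axis=0)
    # order the contour by azimuth (sections of the tibial shaft are
    # star-shaped about their centroid)
    order = np.argsort(np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0]))
    pts = pts[order]
    hull = ConvexHull(pts)
    hv = np.sort(hull.vertices)          # indices into the azimuth-ordered contour
    best_depth, best_chord = 0.0, 0.0
    half = np.radians(sector_halfangle_deg)
    n = len(pts)
    for a, b in zip(hv, np.roll(hv, -1)):
        p, q = pts[a], pts[b]
        mid = (p + q) / 2.0 - centroid
        if abs(np.arctan2(mid[1], mid[0])) > half:   # lateral sector only (+x)
            continue
        # contour points cyclically between the two hull vertices = the pocket
        idx = np.arange(a + 1, b) if b > a else np.arange(a + 1, b + n) % n
        if len(idx) == 0:
            continue
        ab = q - p
        lng = float(np.linalg.norm(ab))
        if lng < 1e-9:
            continue
        ab = ab / lng
        rel = pts[idx] - p
        # inward deviation: the pocket lies toward the centroid side
        inward = np.sign((centroid - p) @ np.array([-ab[1], ab[0]]))
        dev = (rel[:, 0] * -ab[1] + rel[:, 1] * ab[0]) * inward
        d = float(dev.max())
        if d > best_depth:
            best_depth, best_chord = d, lng
    best_depth = max(best_depth, 0.0)
    warning = best_depth < 0.3
    return IncisuraMetrics(depth_mm=best_depth, chord_mm=best_chord,
                           section_level_mm=section_offset_mm,
                           type=classify_incisura(best_depth), warning=warning)


def _hull_orientation(hull_pts: np.ndarray) -> float:
    p = hull_pts
    q = np.roll(p, -1, axis=0)
    area2 = np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1])
    return 1.0 if area2 > 0 else -1.0


# ---------------------------------------------------------------------------
# reference line and the A/B/C construction


def reference_line(landmarks) -> Line2D:
    """Line through the medial malleolar tip, parallel to the distal plafond."""
    pts = getattr(landmarks, "points", landmarks)
    try:
        tip = np.asarray(pts["medial_malleolus_tip"], float)
        pm = np.asarray(pts["plafond_medial"], float)
        pl = np.asarray(pts["plafond_lateral"], float)
    except KeyError as exc:
        raise MeasurementError(f"missing landmark {exc} for the reference line")
    d = pl - pm
    if np.linalg.norm(d) < 1e-9:
        raise GeometryError("plafond landmarks coincide; reference line undefined")
    return Line2D(tip, d)


@dataclass(frozen=True)
class ABCPoints:
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    valid: bool = True
    flags: tuple = ()

    def __iter__(self):
        return iter((self.A, self.B, self.C))


def locate_ABC(source, line: Line2D, *, edge_threshold_mm: float = 0.5,
               edge_margin_mm: float = 3.5, min_wall_slope: float = 0.5) -> ABCPoints:
    """Locate A (medial fibular edge), B (fossa-cortex shadow), C (lateral edge).

    ``source`` is either a projected landmark set (landmark mode) or a
    rendered radiograph (image mode).  In image mode the fibula is the
    most lateral attenuation-support component on the line; B is the
    strongest descending attenuation gradient between the edges -- the
    shadow cast by rays tangential to the fossa's medial cortical wall.
    When no distinct shadow exists (it fades at large rotations) the
    measurement is flagged invalid and B is reported at the nearest edge.
    """
    if hasattr(source, "pixels"):
        return _locate_abc_image(source, line, edge_threshold_mm,
                                 edge_margin_mm, min_wall_slope)
    return _locate_abc_landmarks(source, line)


def _locate_abc_landmarks(lms, line: Line2D) -> ABCPoints:
    pts = getattr(lms, "points", lms)
    missing = getattr(lms, "missing", set())
    for key in ("fibula_medial_edge_at_line", "fibula_lateral_edge_at_line"):
        if key in missing or key not in pts:
            raise MeasurementError("reference line does not cross the fibula")
    a = np.asarray(pts["fibula_medial_edge_at_line"], float)
    c = np.asarray(pts["fibula_lateral_edge_at_line"], float)
    flags: list[str] = []
    valid = True
    if "fossa_wall_at_line" in missing or "fossa_wall_at_line" not in pts:
        valid = False
        flags.append("fossa_shadow_missing")
        b = c.copy()
    else:
        b = np.asarray(pts["fossa_wall_at_line"], float)
    ta, tb, tc = line.param_of(a), line.param_of(b), line.param_of(c)
    if tb < ta:
        tb, valid = ta, False
        flags.append("fossa_clamped_medial")
    elif tb > tc:
        tb, valid = tc, False
        flags.append("fossa_clamped_lateral")
    return ABCPoints(line.at(ta), line.at(tb), line.at(tc), valid, tuple(flags))


def _locate_abc_image(rad, line: Line2D, edge_threshold_mm: float,
                      edge_margin_mm: float, min_wall_slope: float) -> ABCPoints:
    du = rad.spacing / 2.0
    t0, t1 = _line_span(rad, line)
    ts = np.arange(t0, t1, du)
    if len(ts) < 8:
        raise MeasurementError("reference line misses the image")
    pts = line.at(ts)
    rows = (pts[:, 1] - rad.origin[1]) / rad.spacing
    cols = (pts[:, 0] - rad.origin[0]) / rad.spacing
    # virtual radiographs carry per-bone channels: read the fibula channel
    # when present (a line crossing only other bones must fail, not detect)
    pixels = getattr(rad, "channels", {}).get("fibula", rad.pixels)
    prof = map_coordinates(pixels, np.stack([rows, cols]), order=1,
                           mode="constant", cval=0.0)
    support = prof > edge_threshold_mm
    runs = _runs(support)
    runs = [r for r in runs if (ts[r[1] - 1] - ts[r[0]]) >= 3.0]
    if not runs:
        raise MeasurementError("reference line does not cross the fibula")
    i0, i1 = runs[-1]                      # most lateral component = the fibula
    t_a = _cross_subpixel(ts, prof, i0, edge_threshold_mm, rising=True)
    t_c = _cross_subpixel(ts, prof, i1 - 1, edge_threshold_mm, rising=False)
    sm = gaussian_filter1d(prof, sigma=max(rad.spacing / du, 1.0))
    grad = np.gradient(sm, du)
    interior = (ts >= t_a + edge_margin_mm) & (ts <= t_c - edge_margin_mm)
    flags: list[str] = []
    valid = True
    idx = np.nonzero(interior)[0]
    peak_k = None
    if idx.size >= 3:
        # the wall's tangential-ray shadow is a dip in the attenuation
        # gradient: the most prominent peak of -dL/du between the edges
        peaks, props = find_peaks(-grad[idx], prominence=min_wall_slope)
        if peaks.size:
            peak_k = idx[peaks[np.argmax(props["prominences"])]]
    if peak_k is None:
        valid = False
        flags.append("fossa_shadow_missing")
        mid = (t_a + t_c) / 2.0
        t_b = t_c if idx.size == 0 or ts[idx].mean() > mid else t_a
    else:
        t_b = _parabolic_refine(ts, -grad, peak_k)
    t_b = min(max(t_b, t_a), t_c)
    return ABCPoints(line.at(t_a), line.at(t_b), line.at(t_c), valid, tuple(flags))


def _line_span(rad, line: Line2D) -> tuple[float, float]:
    nv, nu = rad.pixels.shape
    corners = np.array([
        [rad.origin[0], rad.origin[1]],
        [rad.origin[0] + (nu - 1) * rad.spacing, rad.origin[1] + (nv - 1) * rad.spacing],
    ])
    ts = [line.param_of(c) for c in corners]
    return min(ts) - rad.spacing, max(ts) + rad.spacing


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _cross_subpixel(ts, prof, idx, level, rising: bool):
    j = idx - 1 if rising else idx + 1
    if j < 0 or j >= len(ts) or prof[j] == prof[idx]:
        return float(ts[idx])
    frac = (level - prof[j]) / (prof[idx] - prof[j])
    return float(ts[j] + frac * (ts[idx] - ts[j]))


def _parabolic_refine(ts, y, k):
    if k <= 0 or k >= len(ts) - 1:
        return float(ts[k])
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if abs(denom) < 1e-12:
        return float(ts[k])
    delta = 0.5 * (y[k - 1] - y[k + 1]) / denom
    return float(ts[k] + np.clip(delta, -1, 1) * (ts[1] - ts[0]))


# ---------------------------------------------------------------------------
# ratio alpha


def compute_ratio_alpha(A, B, C) -> float:
    """alpha = |AB| / |AC| for collinear, ordered points on the reference line."""
    a = np.asarray(A, float)
    b = np.asarray(B, float)
    c = np.asarray(C, float)
    ac = c - a
    lng = np.linalg.norm(ac)
    if lng < 1e-9:
        raise MeasurementError("A and C coincide; ratio alpha undefined")
    cross = (b[0] - a[0]) * ac[1] - (b[1] - a[1]) * ac[0]
    if abs(cross) / lng > 1e-6:
        raise MeasurementError("A, B, C are not collinear")
    t = float((b - a) @ ac) / (lng * lng)
    if t < -1e-9 or t > 1.0 + 1e-9:
        raise MeasurementError("B lies outside the segment AC")
    return float(np.clip(t, 0.0, 1.0))


def measurement_from_points(abc: ABCPoints, angle_deg: float = float("nan"),
                            specimen_id: str = "", observer_id: str = "") -> RatioMeasurement:
    return RatioMeasurement(
        A=abc.A, B=abc.B, C=abc.C, alpha=compute_ratio_alpha(abc.A, abc.B, abc.C),
        angle_deg=angle_deg, specimen_id=specimen_id, observer_id=observer_id,
        valid=abc.valid, flags=abc.flags)


def simulate_observer(true_measurement: RatioMeasurement,
                      edge_jitter_sd_mm: float = 0.2,
                      seed: int | np.random.Generator = 0,
                      observer_id: str = "observer") -> RatioMeasurement:
    """A human reading of A/B/C: independent zero-mean jitter of each point
    along the reference line, ordering re-enforced by clamping."""
    if edge_jitter_sd_mm < 0:
        raise ParameterError("edge_jitter_sd_mm must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(true_measurement.A, float)
    c = np.asarray(true_measurement.C, float)
    b = np.asarray(true_measurement.B, float)
    d = c - a
    lng = np.linalg.norm(d)
    if lng < 1e-9:
        raise MeasurementError("degenerate measurement")
    d = d / lng
    ea, eb, ec = rng.normal(0.0, edge_jitter_sd_mm, 3) if edge_jitter_sd_mm > 0 \
        else (0.0, 0.0, 0.0)
    a2 = a + ea * d
    c2 = c + ec * d
    if (c2 - a2) @ d <= 1e-9:          # pathological jitter collapsed the width
        a2, c2 = a, c
    b2 = b + eb * d
    tb = float((b2 - a2) @ d)
    tb = min(max(tb, 0.0), float((c2 - a2) @ d))
    b2 = a2 + tb * d
    return replace(true_measurement, A=a2, B=b2, C=c2,
                   alpha=compute_ratio_alpha(a2, b2, c2), observer_id=observer_id)
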